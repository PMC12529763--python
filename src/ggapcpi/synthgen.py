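"""Deterministic synthetic fixtures for every pipeline stage.

Congeneric ligand series are built from ring-system templates with growing
alkyl chains, so members of one series share a Bemis–Murcko scaffold (their
scaffold-fingerprint Tanimoto is 1) while distinct series use distinct ring
systems and stay below the 0.9 similarity threshold — both properties are
verified at generation time with the package's own similarity computation.
Bioactivities are smooth within a series (±0.1 log jitter around a series
base) except for planted cliff members offset by ±(2.5–3.5) log, which keeps
every planted cliff pair strictly above the >2-log rule and every flat pair
strictly below it.  A fraction of records is duplicated with a >1-log
discrepancy to plant conflict groups that curation must drop.  Everything is a
pure function of the spec (seed included).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import (
    ActivityType,
    AuxStats,
    BioactivityRecord,
    ProteinEntry,
    Relation,
    Source,
    one_hot_embedding,
)
from .standardize import StandardizedMolecule, similarity_triple, standardize_molecule

# one ring system per template (Murcko scaffolds must differ across series)
# and varied linkers/decorations (canonical-SMILES edit distance must stay
# above the 0.9 similarity threshold across series)
_SERIES_TEMPLATES = [
    "{R}OC(=O)c1ccc(N)cc1",      # benzene
    "{R}NC(=O)c1ccnc(Cl)c1",     # pyridine
    "{R}Oc1ccc2ccccc2c1",        # naphthalene
    "{R}NC(=O)C1CCOCC1",         # oxane
    "{R}Sc1nc(N)cc(C)n1",        # pyrimidine
    "{R}OC(=O)c1ccc(C)o1",       # furan
    "{R}N(C)C(=O)c1cccs1",       # thiophene
    "{R}Oc1ccc(Br)c2ncccc12",    # quinoline
    "{R}NC(=O)C1CCN(C)CC1",      # piperidine
    "{R}Cc1cc(C#N)on1",          # isoxazole
    "{R}OC(=O)C1(C)CCCCC1",      # cyclohexane
    "{R}Nc1nc2ccccc2s1",         # benzothiazole
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    n_series: int = 6
    series_size: int = 6
    cliff_rate: float = 0.15
    conflict_rate: float = 0.1
    activity_types: tuple[tuple[ActivityType, float], ...] = (
        (ActivityType.Ki, 0.4),
        (ActivityType.IC50, 0.3),
        (ActivityType.Kd, 0.15),
        (ActivityType.EC50, 0.15),
    )
    n_proteins: int = 3
    protein_length_range: tuple[int, int] = (50, 200)
    pocket_size_range: tuple[int, int] = (8, 15)
    base_activity_range: tuple[float, float] = (5.0, 9.0)
    jitter: float = 0.1
    cliff_offset_range: tuple[float, float] = (2.5, 3.5)
    conflict_gap_range: tuple[float, float] = (1.2, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cliff_rate", "conflict_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way the pipeline reports it."""

    cliff_pairs: dict[tuple, set[tuple[str, str]]] = field(default_factory=dict)
    ac_molecules: dict[tuple, set[str]] = field(default_factory=dict)
    conflict_groups: list[tuple] = field(default_factory=list)
    cliff_members: list[tuple[str, str, float]] = field(default_factory=list)
    clean_values: dict[tuple, float] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    records: list[BioactivityRecord]
    proteins: list[ProteinEntry]
    molecules: dict[str, StandardizedMolecule]  # canonical smiles -> molecule
    series_of: dict[str, int]                   # canonical smiles -> series id
    truth: GroundTruth


def generate_ligand_series(spec: SyntheticSpec) -> tuple[
    list[list[str]], dict[str, StandardizedMolecule]
]:
    """Canonical SMILES per series, verified against the similarity contract.

    Within a series, adjacent members must reach a similarity above 0.9 (their
    shared scaffold guarantees it); across series every similarity must stay
    below 0.9.  Violations raise, as does a spec larger than the template
    vocabulary.
    """
    if spec.n_series > len(_SERIES_TEMPLATES):
        raise ValueError(
            f"at most {len(_SERIES_TEMPLATES)} series are supported, "
            f"got n_series={spec.n_series}"
        )
    series: list[list[str]] = []
    molecules: dict[str, StandardizedMolecule] = {}
    for template in _SERIES_TEMPLATES[: spec.n_series]:
        members = []
        for i in range(spec.series_size):
            smiles = template.format(R="C" * (i + 1))
            std = standardize_molecule(smiles)
            if not isinstance(std, StandardizedMolecule):
                raise ValueError(f"template produced invalid SMILES: {smiles}")
            members.append(std.canonical_smiles)
            molecules[std.canonical_smiles] = std
        series.append(members)
    # generate-and-check: the similarity contract is verified, not assumed
    for members in series:
        for a, b in zip(members, members[1:]):
            if similarity_triple(molecules[a], molecules[b]).max() <= 0.9:
                raise ValueError(f"adjacent members {a} / {b} not similar enough")
    for sa, sb in itertools.combinations(series, 2):
        for a in sa:
            for b in sb:
                if similarity_triple(molecules[a], molecules[b]).max() >= 0.9:
                    raise ValueError(f"cross-series members {a} / {b} too similar")
    return series, molecules


def generate_proteins(spec: SyntheticSpec) -> list[ProteinEntry]:
    """Random toy sequences with a contiguous synthetic pocket annotation."""
    rng = np.random.default_rng(spec.seed + 1)
    entries = []
    lo, hi = spec.protein_length_range
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AA20), size=length))
        psize = int(rng.integers(spec.pocket_size_range[0], spec.pocket_size_range[1] + 1))
        psize = min(psize, length - 1)
        start = int(rng.integers(0, length - psize + 1))
        entries.append(
            ProteinEntry(
                target_id=f"SYNP{i}",
                sequence=seq,
                embedding=one_hot_embedding(seq),
                pocket_residues=tuple(range(start, start + psize)),
            )
        )
    return entries


def generate_bioactivities(
    series: Sequence[Sequence[str]],
    molecules: dict[str, StandardizedMolecule],
    proteins: Sequence[ProteinEntry],
    spec: SyntheticSpec,
) -> tuple[list[BioactivityRecord], GroundTruth]:
    """Planted-signal bioactivity records plus the exact ground truth.

    Cliff pairs are enumerated on the post-curation values (conflict-planted
    molecules drop out entirely), with similarity implied by series membership
    — the construction guarantees it and generation verifies it.
    """
    rng = np.random.default_rng(spec.seed + 2)
    types, weights = zip(*spec.activity_types)
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()
    truth = GroundTruth()
    records: list[BioactivityRecord] = []
    clean: dict[tuple, tuple[str, float]] = {}  # key -> (series member smiles, value)

    for prot in proteins:
        for si, members in enumerate(series):
            a_type = types[rng.choice(len(types), p=weights)]
            base = rng.uniform(*spec.base_activity_range)
            for mi, smi in enumerate(members):
                value = base + rng.uniform(-spec.jitter, spec.jitter)
                if rng.random() < spec.cliff_rate:
                    offset = rng.uniform(*spec.cliff_offset_range)
                    offset *= 1 if rng.random() < 0.5 else -1
                    value += offset
                    truth.cliff_members.append((smi, prot.target_id, offset))
                rec = BioactivityRecord(
                    molecule_id=f"S{si}M{mi}",
                    smiles=smi,
                    target_id=prot.target_id,
                    activity_type=a_type,
                    relation=Relation.eq,
                    value=round(value, 6),
                    source=Source.user,
                    aux=AuxStats(),
                )
                records.append(rec)
                key = (smi, prot.target_id, a_type)
                if rng.random() < spec.conflict_rate:
                    gap = rng.uniform(*spec.conflict_gap_range)
                    gap *= 1 if rng.random() < 0.5 else -1
                    records.append(rec.with_value(round(value + gap, 6)))
                    truth.conflict_groups.append(key)
                else:
                    clean[key] = (smi, rec.value)

    truth.clean_values = {k: v for k, (_, v) in clean.items()}
    series_of = {smi: si for si, members in enumerate(series) for smi in members}
    # enumerate planted cliffs among surviving (non-conflicted) molecules
    by_group: dict[tuple, list[tuple[str, float]]] = {}
    for (smi, target, a_type), (_, value) in clean.items():
        by_group.setdefault((target, a_type), []).append((smi, value))
    for gkey, items in by_group.items():
        pairs: set[tuple[str, str]] = set()
        acs: set[str] = set()
        for (a, va), (b, vb) in itertools.combinations(sorted(items), 2):
            if series_of[a] == series_of[b] and abs(va - vb) > 2.0:
                pairs.add((min(a, b), max(a, b)))
                acs.update((a, b))
        truth.cliff_pairs[gkey] = pairs
        truth.ac_molecules[gkey] = acs
    return records, truth


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """One call for the full fixture: ligands, proteins, records, ground truth."""
    spec = spec or SyntheticSpec()
    series, molecules = generate_ligand_series(spec)
    proteins = generate_proteins(spec)
    records, truth = generate_bioactivities(series, molecules, proteins, spec)
    series_of = {smi: si for si, members in enumerate(series) for smi in members}
    return SyntheticDataset(
        spec=spec,
        records=records,
        proteins=proteins,
        molecules=molecules,
        series_of=series_of,
        truth=truth,
    )


def write_fixtures(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Emit the fixture as plain-text files: CSV, FASTA, pockets, truth JSON."""
    from .records import write_bioactivity_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_bioactivity_table(dataset.records, directory / "bioactivity.csv")
    with open(directory / "proteins.fasta", "w") as fh:
        for p in dataset.proteins:
            fh.write(f">{p.target_id}\n{p.sequence}\n")
    with open(directory / "pockets.tsv", "w") as fh:
        for p in dataset.proteins:
            for r in p.pocket_residues or ():
                fh.write(f"{p.target_id}\t{r}\n")
    truth = {
        "cliff_pairs": {
            f"{t}|{a.value}": sorted(map(list, pairs))
            for (t, a), pairs in dataset.truth.cliff_pairs.items()
        },
        "conflict_groups": [
            [smi, target, a.value] for smi, target, a in dataset.truth.conflict_groups
        ],
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))
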