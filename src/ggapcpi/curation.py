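"""Multistep cleaning and integration of bioactivity tables.

The workflow keeps only reliable assay endpoints (Ki/Kd/EC50/IC50), keeps only
"=" / "<=" relations, keeps replicate-consistent records (std < 0.1), maps
standardized molecules, and resolves conflicting measurements of the same
(molecule, target, type) group: groups spanning more than one log unit
(a 10-fold disagreement) are dropped outright, smaller conflicts collapse to
their arithmetic mean.  Every input record ends up either in the output table
or in exactly one drop bucket of the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .records import BENCHMARK_TYPES, BioactivityRecord, Relation
from .standardize import RejectionRecord, StandardizedMolecule, standardize_batch

logger = logging.getLogger("ggapcpi")

KEPT_RELATIONS = frozenset({Relation.eq, Relation.le})


@dataclass
class StageCount:
    stage: str
    n_input: int
    n_kept: int
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class CurationReport:
    stages: list[StageCount] = field(default_factory=list)
    overlap: dict[str, int] = field(default_factory=dict)
    drop_groups: list[tuple] = field(default_factory=list)  # conflict keys dropped

    def add(self, stage: str, n_input: int, n_kept: int, dropped: Mapping[str, int]) -> None:
        sc = StageCount(stage, n_input, n_kept, dict(dropped))
        if sc.n_kept + sc.n_dropped != sc.n_input:
            raise AssertionError(f"stage {stage}: kept+dropped != input")
        self.stages.append(sc)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "input": s.n_input,
                    "kept": s.n_kept,
                    "dropped": s.dropped,
                }
                for s in self.stages
            ],
            "overlap": self.overlap,
        }


def filter_activity_types(
    records: Sequence[BioactivityRecord],
    allowed: frozenset = BENCHMARK_TYPES,
    report: CurationReport | None = None,
) -> list[BioactivityRecord]:
    """Keep records whose activity type is in ``allowed`` (order-preserving)."""
    if not allowed:
        raise ValueError("allowed activity types must be non-empty")
    kept = [r for r in records if r.activity_type in allowed]
    if report is not None:
        report.add(
            "activity_type_filter",
            len(records),
            len(kept),
            {"disallowed activity type": len(records) - len(kept)},
        )
    return kept


def filter_relations(
    records: Sequence[BioactivityRecord],
    report: CurationReport | None = None,
) -> list[BioactivityRecord]:
    """Keep relations "=" and "<="; missing annotations get their own bucket."""
    kept, n_missing, n_other = [], 0, 0
    for r in records:
        if r.relation in KEPT_RELATIONS:
            kept.append(r)
        elif r.relation is Relation.missing:
            n_missing += 1
        else:
            n_other += 1
    if report is not None:
        report.add(
            "relation_filter",
            len(records),
            len(kept),
            {"missing relation annotation": n_missing, "unreliable relation": n_other},
        )
    return kept


def filter_by_std(
    records: Sequence[BioactivityRecord],
    max_std: float = 0.1,
    report: CurationReport | None = None,
) -> list[BioactivityRecord]:
    """Keep replicate-consistent records: aux.std < max_std (strict).

    Records without a replicate std pass unchanged (the rule is inapplicable).
    """
    kept, dropped = [], 0
    for r in records:
        if r.aux.std is None:
            kept.append(r)
            continue
        if r.aux.std < 0:
            raise ValueError(f"negative replicate std for {r.molecule_id}")
        if r.aux.std < max_std:
            kept.append(r)
        else:
            dropped += 1
    if report is not None:
        report.add("std_filter", len(records), len(kept), {"replicate std too high": dropped})
    return kept


def apply_standardization(
    records: Sequence[BioactivityRecord],
    report: CurationReport | None = None,
) -> tuple[list[BioactivityRecord], dict[str, StandardizedMolecule], list[RejectionRecord]]:
    """Replace SMILES by canonical parent SMILES; drop unparseable molecules."""
    std, rejects = standardize_batch([r.smiles for r in records])
    kept = [r.with_smiles(std[r.smiles].canonical_smiles) for r in records if r.smiles in std]
    if report is not None:
        report.add(
            "molecule_standardization",
            len(records),
            len(kept),
            {"unparseable molecule": len(records) - len(kept)},
        )
    by_canonical = {m.canonical_smiles: m for m in std.values()}
    return kept, by_canonical, rejects


def map_target_ids(
    records: Sequence[BioactivityRecord],
    id_map: Mapping[str, str],
    report: CurationReport | None = None,
) -> list[BioactivityRecord]:
    """Translate source target ids (e.g. HGNC) to accessions via a lookup table.

    Records without a mapping are dropped with reason "no UniProt ID".
    """
    from dataclasses import replace

    kept, dropped = [], 0
    for r in records:
        if r.target_id in id_map:
            kept.append(replace(r, target_id=id_map[r.target_id]))
        else:
            dropped += 1
    if report is not None:
        report.add("target_id_mapping", len(records), len(kept), {"no UniProt ID": dropped})
    return kept


def resolve_conflicts(
    records: Sequence[BioactivityRecord],
    max_range: float = 1.0,
    report: CurationReport | None = None,
) -> tuple[list[BioactivityRecord], CurationReport]:
    """Collapse duplicate (molecule, target, type) measurements.

    Groups whose value range exceeds ``max_range`` log units are dropped whole;
    the rest collapse to a single record carrying the arithmetic mean.
    Singleton groups pass unchanged.  Output order follows the first appearance
    of each group.
    """
    if report is None:
        report = CurationReport()
    groups: dict[tuple, list[BioactivityRecord]] = {}
    order: list[tuple] = []
    for r in records:
        key = r.conflict_key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    kept: list[BioactivityRecord] = []
    n_dropped = 0
    for key in order:
        grp = groups[key]
        values = [r.value for r in grp if r.value is not None]
        if len(grp) == 1:
            kept.append(grp[0])
            continue
        if not values or (max(values) - min(values)) > max_range:
            n_dropped += len(grp)
            report.drop_groups.append(key)
            continue
        kept.append(grp[0].with_value(sum(values) / len(values)))
    report.add(
        "conflict_resolution",
        len(records),
        len(kept),
        {
            "conflicting group (>1 log spread)": n_dropped,
            "merged duplicate": len(records) - n_dropped - len(kept),
        },
    )
    return kept, report


def _overlap_stats(
    a: Sequence[BioactivityRecord], b: Sequence[BioactivityRecord]
) -> dict[str, int]:
    la, lb = {r.smiles for r in a}, {r.smiles for r in b}
    pa, pb = {r.target_id for r in a}, {r.target_id for r in b}
    cpi_a = {(r.smiles, r.target_id) for r in a}
    cpi_b = {(r.smiles, r.target_id) for r in b}
    prof_a = {(r.smiles, r.target_id, r.activity_type, r.value) for r in a}
    prof_b = {(r.smiles, r.target_id, r.activity_type, r.value) for r in b}
    return {
        "shared_ligands": len(la & lb),
        "shared_proteins": len(pa & pb),
        "shared_unique_cpi": len(cpi_a & cpi_b),
        "shared_bioactivity_profiles": len(prof_a & prof_b),
        "unique_ligands": len(la | lb),
        "unique_proteins": len(pa | pb),
        "unique_cpi": len(cpi_a | cpi_b),
        "unique_bioactivity_profiles": len(prof_a | prof_b),
    }


def integrate_sources(
    equivs_records: Sequence[BioactivityRecord],
    papyrus_records: Sequence[BioactivityRecord],
    max_range: float = 1.0,
) -> tuple[list[BioactivityRecord], CurationReport]:
    """Union two curated sources, dedup exact profiles, then resolve conflicts."""
    report = CurationReport()
    report.overlap = _overlap_stats(equivs_records, papyrus_records)
    union = list(equivs_records) + list(papyrus_records)
    seen: set[tuple] = set()
    deduped: list[BioactivityRecord] = []
    n_dup = 0
    for r in union:
        profile = (r.smiles, r.target_id, r.activity_type, r.value)
        if profile in seen:
            n_dup += 1
            continue
        seen.add(profile)
        deduped.append(r)
    report.add("exact_dedup", len(union), len(deduped), {"exact duplicate profile": n_dup})
    resolved, report = resolve_conflicts(deduped, max_range=max_range, report=report)
    return resolved, report


def curate(
    records: Sequence[BioactivityRecord],
    allowed: frozenset = BENCHMARK_TYPES,
    max_std: float = 0.1,
    max_range: float = 1.0,
    id_map: Mapping[str, str] | None = None,
) -> tuple[list[BioactivityRecord], CurationReport]:
    """Run the full single-source workflow in the published stage order."""
    report = CurationReport()
    recs = filter_activity_types(records, allowed, report)
    recs = filter_relations(recs, report)
    recs = filter_by_std(recs, max_std, report)
    if id_map is not None:
        recs = map_target_ids(recs, id_map, report)
    recs, _, _ = apply_standardization(recs, report)
    recs, report = resolve_conflicts(recs, max_range, report)
    return recs, report
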