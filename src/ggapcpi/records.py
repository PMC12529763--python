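"""Data model and file I/O for the bioactivity pipeline.

All bioactivity values are stored on the negative-log molar scale
(pActivity = -log10 of a molar Ki/Kd/EC50/IC50); readers can convert from
nM/uM on the way in.  The conflict-group key throughout the pipeline is
(molecule, target, activity type).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("ggapcpi")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = STANDARD_AA + "X"  # 20 standard residues plus unknown

#: multiplicative factor that converts a unit to molar
UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class ActivityType(str, enum.Enum):
    Ki = "Ki"
    Kd = "Kd"
    EC50 = "EC50"
    IC50 = "IC50"
    potency = "potency"
    other = "other"


class Relation(str, enum.Enum):
    eq = "="
    le = "<="
    lt = "<"
    other = "other"
    missing = "missing"


class Source(str, enum.Enum):
    equivs = "equivs"
    papyrus = "papyrus"
    user = "user"


#: the four assay types kept for the benchmark
BENCHMARK_TYPES = frozenset(
    {ActivityType.Ki, ActivityType.Kd, ActivityType.EC50, ActivityType.IC50}
)

_ACTIVITY_ALIASES = {
    "ki": ActivityType.Ki,
    "kd": ActivityType.Kd,
    "ec50": ActivityType.EC50,
    "ic50": ActivityType.IC50,
    "potency": ActivityType.potency,
}

_RELATION_ALIASES = {
    "=": Relation.eq,
    "==": Relation.eq,
    "<=": Relation.le,
    "≤": Relation.le,
    "<": Relation.lt,
    "": Relation.missing,
}


def parse_activity_type(raw: object) -> ActivityType:
    """Map a free-text activity-type cell onto the closed enum (never drops)."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ActivityType.other
    return _ACTIVITY_ALIASES.get(str(raw).strip().lower(), ActivityType.other)


def parse_relation(raw: object) -> Relation:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return Relation.missing
    token = str(raw).strip()
    if token.lower() == "nan":
        return Relation.missing
    if token in _RELATION_ALIASES:
        return _RELATION_ALIASES[token]
    return Relation.other


@dataclass(frozen=True)
class AuxStats:
    """Per-record replicate statistics carried by some sources."""

    mean: float | None = None
    median: float | None = None
    std: float | None = None
    count: int | None = None


@dataclass(frozen=True)
class BioactivityRecord:
    """One bioactivity measurement for a (molecule, target) pair."""

    molecule_id: str
    smiles: str
    target_id: str
    activity_type: ActivityType
    relation: Relation
    value: float | None
    source: Source = Source.user
    aux: AuxStats = field(default_factory=AuxStats)

    def __post_init__(self) -> None:
        if self.value is not None and not math.isfinite(self.value):
            raise ValueError(f"non-finite bioactivity value for {self.molecule_id}")

    @property
    def conflict_key(self) -> tuple[str, str, ActivityType]:
        return (self.smiles, self.target_id, self.activity_type)

    def with_value(self, value: float) -> "BioactivityRecord":
        return replace(self, value=value)

    def with_smiles(self, smiles: str) -> "BioactivityRecord":
        return replace(self, smiles=smiles)


@dataclass
class ProteinEntry:
    """A target protein: sequence, optional structure and residue embeddings."""

    target_id: str
    sequence: str
    structure_path: Path | None = None
    embedding: np.ndarray | None = None
    pocket_residues: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.embedding is not None and self.embedding.shape[0] != len(self.sequence):
            raise ValueError(
                f"{self.target_id}: embedding has {self.embedding.shape[0]} rows "
                f"but the sequence has {len(self.sequence)} residues"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class SchemaError(ValueError):
    """A required column is absent from an input table."""


_DIALECT_COLUMNS = {
    "generic": {
        "molecule_id": "molecule_id",
        "smiles": "smiles",
        "target_id": "target_id",
        "activity_type": "activity_type",
        "relation": "relation",
        "value": "value",
    },
    "equivs": {
        "molecule_id": "molecule_id",
        "smiles": "smiles",
        "target_id": "hgnc_id",
        "activity_type": "bioactivity_type",
        "relation": "relation",
        "value": "bioactivity_value",
        "unit": "bioactivity_unit",
    },
    "papyrus": {
        "molecule_id": "source_id",
        "smiles": "smiles",
        "target_id": "uniprot_id",
        "activity_type": "activity_type",
        "relation": "relation",
        "value": "pchembl_value_mean",
        "aux_mean": "pchembl_value_mean",
        "aux_median": "pchembl_value_median",
        "aux_std": "pchembl_value_stdev",
        "aux_count": "pchembl_value_n",
    },
}

_REQUIRED = {
    "generic": ["molecule_id", "smiles", "target_id", "activity_type", "value"],
    "equivs": ["molecule_id", "smiles", "hgnc_id", "bioactivity_type", "bioactivity_value"],
    "papyrus": ["source_id", "smiles", "uniprot_id", "activity_type", "pchembl_value_mean"],
}

_SOURCE_FOR_DIALECT = {
    "generic": Source.user,
    "equivs": Source.equivs,
    "papyrus": Source.papyrus,
}


def _opt_float(x: object) -> float | None:
    if x is None:
        return None
    try:
        v = float(x)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def read_bioactivity_table(
    path: str | Path,
    source_dialect: str = "generic",
    *,
    unit_column: str | None = None,
) -> list[BioactivityRecord]:
    """Read a CSV/TSV bioactivity table into records, preserving row order.

    ``source_dialect`` selects the column mapping (``generic`` is the canonical
    interchange format; ``equivs``/``papyrus`` are column shims).  When
    ``unit_column`` is given (or the dialect declares one), raw values are
    converted to the negative-log molar scale as -log10(value * unit_to_molar).
    Unrecognised enum cells map to other/missing; rows are never dropped here.
    """
    if source_dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {source_dialect!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        logger.warning("%s: empty bioactivity table", path)
        return []
    cols = _DIALECT_COLUMNS[source_dialect]
    missing = [c for c in _REQUIRED[source_dialect] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if unit_column is None and "unit" in cols and cols["unit"] in df.columns:
        unit_column = cols["unit"]

    records: list[BioactivityRecord] = []
    for _, row in df.iterrows():
        value = _opt_float(row.get(cols["value"]))
        if value is not None and unit_column is not None:
            unit = str(row.get(unit_column, "M")).strip()
            factor = UNIT_TO_MOLAR.get(unit)
            if factor is None:
                logger.warning("unknown unit %r; value left as-is", unit)
            else:
                value = -math.log10(value * factor) if value > 0 else None
        aux = AuxStats(
            mean=_opt_float(row.get(cols.get("aux_mean", ""), None)),
            median=_opt_float(row.get(cols.get("aux_median", ""), None)),
            std=_opt_float(row.get(cols.get("aux_std", ""), None)),
            count=(lambda c: int(c) if c is not None else None)(
                _opt_float(row.get(cols.get("aux_count", ""), None))
            ),
        )
        records.append(
            BioactivityRecord(
                molecule_id=str(row[cols["molecule_id"]]),
                smiles=str(row[cols["smiles"]]),
                target_id=str(row[cols["target_id"]]),
                activity_type=parse_activity_type(row.get(cols["activity_type"])),
                relation=parse_relation(row.get(cols["relation"], None))
                if cols.get("relation") in df.columns
                else Relation.missing,
                value=value,
                source=_SOURCE_FOR_DIALECT[source_dialect],
                aux=aux,
            )
        )
    return records


def write_bioactivity_table(records: Sequence[BioactivityRecord], path: str | Path) -> None:
    """Write records as a generic-dialect CSV (round-trips with the reader)."""
    rows = [
        {
            "molecule_id": r.molecule_id,
            "smiles": r.smiles,
            "target_id": r.target_id,
            "activity_type": r.activity_type.value,
            "relation": r.relation.value,
            "value": r.value,
            "source": r.source.value,
            "aux_std": r.aux.std,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read protein sequences; header first token is the target id.

    Sequences are uppercased; gap (``-``, ``.``) and stop (``*``) symbols are
    stripped with a warning.  Duplicate ids raise.
    """
    entries: list[ProteinEntry] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = seq.replace("-", "").replace(".", "").replace("*", "")
        if cleaned != seq:
            logger.warning("%s: stripped gap/stop symbols from sequence", rec.id)
        seen[rec.id] = seen.get(rec.id, 0) + 1
        entries.append(ProteinEntry(target_id=rec.id, sequence=cleaned))
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate target_id(s) in FASTA: {', '.join(dupes)}")
    return entries


def one_hot_embedding(sequence: str) -> np.ndarray:
    """L x 21 one-hot residue embedding (20 standard residues + X).

    Non-standard letters collapse onto the X column.  This is the fallback used
    when no language-model embeddings are supplied.
    """
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    out = np.zeros((len(sequence), len(AA_ALPHABET)), dtype=np.float64)
    for i, aa in enumerate(sequence.upper()):
        out[i, idx.get(aa, idx["X"])] = 1.0
    return out


def load_residue_embeddings(
    path: str | Path | None,
    entry: ProteinEntry,
    *,
    one_hot_fallback: bool = False,
) -> np.ndarray:
    """Load a dense per-residue embedding matrix and validate its row count.

    The file may be ``.npy`` or a whitespace/comma-delimited text matrix with
    one row per residue.  With ``one_hot_fallback`` an absent file yields the
    L x 21 one-hot matrix instead of an error.
    """
    if path is None or not Path(path).exists():
        if one_hot_fallback:
            return one_hot_embedding(entry.sequence)
        raise FileNotFoundError(f"no embedding file for {entry.target_id}: {path}")
    path = Path(path)
    if path.suffix == ".npy":
        mat = np.load(path)
    else:
        mat = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    mat = np.atleast_2d(np.asarray(mat, dtype=np.float64))
    if mat.shape[0] != len(entry.sequence):
        raise ValueError(
            f"{entry.target_id}: embedding has {mat.shape[0]} rows but the "
            f"sequence has {len(entry.sequence)} residues"
        )
    return mat


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with the published defaults."""

    # curation
    allowed_types: frozenset = BENCHMARK_TYPES
    max_conflict_range: float = 1.0   # drop groups spanning >1 log (10-fold)
    max_aux_std: float = 0.1          # keep replicate std < 0.1
    # activity cliffs
    similarity_threshold: float = 0.9  # any of the three similarities, strict
    cliff_delta: float = 2.0           # >2 negative-log units (100-fold)
    # splitting
    n_clusters: int = 50
    train_frac: float = 0.8
    # model
    hidden_dim: int = 300
    n_mpnn_layers: int = 1
    n_gcn_layers: int = 1
    n_attention_heads: int = 5
    residue_embedding_dim: int = 1280
    dropout: float = 0.1
    # training
    batch_size: int = 256
    epochs: int = 100
    learning_rate: float = 1e-4
    n_folds: int = 5
    n_cycles: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "allowed_types" in raw:
            raw["allowed_types"] = frozenset(
                parse_activity_type(t) for t in raw["allowed_types"]
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dict(self.__dict__)
        d["allowed_types"] = sorted(t.value for t in self.allowed_types)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def configure_logging(level: str = "INFO") -> None:
    """Structured logging to stderr (used by the command-line entry points)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def iter_by_target(
    records: Iterable[BioactivityRecord],
) -> dict[tuple[str, ActivityType], list[BioactivityRecord]]:
    """Group records by (target, activity type), preserving input order."""
    groups: dict[tuple[str, ActivityType], list[BioactivityRecord]] = {}
    for r in records:
        groups.setdefault((r.target_id, r.activity_type), []).append(r)
    return groups
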