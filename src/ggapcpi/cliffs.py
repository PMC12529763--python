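"""Activity-cliff identification, compound labeling, and AC-aware splitting.

An activity cliff is a pair of compounds active on the same target whose
structures are highly similar (any of full-fingerprint Tanimoto, scaffold
Tanimoto, or SMILES Levenshtein similarity strictly above 0.9) but whose
bioactivities differ by strictly more than 2 negative-log units (a 100-fold
gap).  A compound is AC-labeled if it participates in at least one cliff pair.
Splitting clusters each target's compounds by fingerprint similarity (spectral
clustering) and stratifies the 80/20 draw by AC label inside every cluster, so
cliffy chemistry is proportionally represented in train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

from .records import BioactivityRecord
from .standardize import StandardizedMolecule, SimilarityTriple, similarity_triple

logger = logging.getLogger("ggapcpi")

SIMILARITY_THRESHOLD = 0.9
CLIFF_DELTA = 2.0


@dataclass(frozen=True)
class ACPair:
    """An unordered similar-compound pair on one target (canonical ordering)."""

    mol_i: str
    mol_j: str
    target_id: str
    similarity: SimilarityTriple
    delta: float
    is_cliff: bool

    def __post_init__(self) -> None:
        if self.mol_i > self.mol_j:
            raise ValueError("ACPair must be stored with mol_i <= mol_j")

    @property
    def key(self) -> tuple[str, str]:
        return (self.mol_i, self.mol_j)


def find_ac_pairs(
    target_records: Sequence[BioactivityRecord],
    molecules: Mapping[str, StandardizedMolecule],
    similarity_threshold: float = SIMILARITY_THRESHOLD,
    cliff_delta: float = CLIFF_DELTA,
) -> list[ACPair]:
    """Evaluate all unordered pairs of one target's compounds.

    Returns the similar pairs (any similarity strictly above the threshold);
    pairs whose bioactivity gap strictly exceeds ``cliff_delta`` are cliffs.
    Requires one value per molecule (run after conflict resolution).
    """
    targets = {r.target_id for r in target_records}
    if len(targets) > 1:
        raise ValueError(f"records span multiple targets: {sorted(targets)}")
    values: dict[str, float] = {}
    for r in target_records:
        if r.value is None:
            continue
        if r.smiles in values and values[r.smiles] != r.value:
            raise ValueError(
                f"molecule {r.smiles} has multiple values; resolve conflicts first"
            )
        values[r.smiles] = r.value
    smiles = sorted(values)  # canonical order makes pair keys deterministic
    if len(smiles) < 2:
        return []
    target_id = next(iter(targets))
    pairs: list[ACPair] = []
    for i in range(len(smiles)):
        for j in range(i + 1, len(smiles)):
            a, b = smiles[i], smiles[j]
            sim = similarity_triple(molecules[a], molecules[b])
            if sim.max() > similarity_threshold:
                delta = abs(values[a] - values[b])
                pairs.append(
                    ACPair(
                        mol_i=a,
                        mol_j=b,
                        target_id=target_id,
                        similarity=sim,
                        delta=delta,
                        is_cliff=delta > cliff_delta,
                    )
                )
    return pairs


def compound_ac_labels(
    pairs: Sequence[ACPair], molecules: Sequence[str]
) -> dict[str, bool]:
    """Label a molecule AC iff it sits in at least one cliff pair."""
    cliffy: set[str] = set()
    for p in pairs:
        if p.is_cliff:
            cliffy.add(p.mol_i)
            cliffy.add(p.mol_j)
    return {m: (m in cliffy) for m in molecules}


def _stratified_counts(sizes: Sequence[int], train_frac: float) -> list[int]:
    """Per-stratum train counts: round(frac*size), nudged to hit the cluster total."""
    total_train = round(train_frac * sum(sizes))
    counts = [round(train_frac * s) for s in sizes]
    counts = [min(c, s) for c, s in zip(counts, sizes)]
    # adjust by +/-1 on the strata with the largest rounding slack
    while sum(counts) != total_train:
        if sum(counts) < total_train:
            slack = [(s - c, i) for i, (s, c) in enumerate(zip(sizes, counts))]
            _, i = max(slack)
            counts[i] += 1
        else:
            slack = [(c, i) for i, c in enumerate(counts)]
            _, i = max(slack)
            counts[i] -= 1
    return counts


def cluster_molecules(
    smiles: Sequence[str],
    molecules: Mapping[str, StandardizedMolecule],
    k: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Spectral clustering on the pairwise ECFP-Tanimoto affinity matrix.

    The cluster count is capped so clusters average at least ~10 molecules;
    singleton clusters would make the within-cluster 80/20 draw vacuous.
    """
    n = len(smiles)
    k = min(k, max(1, n // 10))
    if n <= 2 or k <= 1:
        return np.zeros(n, dtype=int)
    fps = np.stack([molecules[s].ecfp for s in smiles]).astype(np.float64)
    inter = fps @ fps.T
    on = fps.sum(axis=1)
    union = on[:, None] + on[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        affinity = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    np.fill_diagonal(affinity, 1.0)
    sc = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        random_state=seed,
        assign_labels="discretize",
    )
    return sc.fit_predict(affinity)


def ac_split(
    target_records: Sequence[BioactivityRecord],
    ac_labels: Mapping[str, bool],
    molecules: Mapping[str, StandardizedMolecule],
    k: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """AC-stratified cluster split of one target's compounds.

    Returns a DataFrame with columns (smiles, target_id, cluster_id, partition,
    ac_label).  Reproducible under ``seed``; a single-molecule target goes to
    train with a warning.
    """
    targets = {r.target_id for r in target_records}
    if len(targets) != 1:
        raise ValueError("ac_split expects records of exactly one target")
    target_id = next(iter(targets))
    smiles = sorted({r.smiles for r in target_records})
    if len(smiles) == 1:
        logger.warning("%s: single molecule; assigned to train", target_id)
        return pd.DataFrame(
            {
                "smiles": smiles,
                "target_id": target_id,
                "cluster_id": [0],
                "partition": ["train"],
                "ac_label": [bool(ac_labels.get(smiles[0], False))],
            }
        )
    clusters = cluster_molecules(smiles, molecules, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    partition = np.empty(len(smiles), dtype=object)
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        strata = {}
        for i in idx:
            strata.setdefault(bool(ac_labels.get(smiles[i], False)), []).append(i)
        labels = sorted(strata)  # deterministic stratum order
        counts = _stratified_counts([len(strata[s]) for s in labels], train_frac)
        for lab, n_train in zip(labels, counts):
            members = np.array(strata[lab])
            perm = rng.permutation(len(members))
            train_idx = members[perm[:n_train]]
            test_idx = members[perm[n_train:]]
            partition[train_idx] = "train"
            partition[test_idx] = "test"
    return pd.DataFrame(
        {
            "smiles": smiles,
            "target_id": target_id,
            "cluster_id": clusters.astype(int),
            "partition": partition,
            "ac_label": [bool(ac_labels.get(s, False)) for s in smiles],
        }
    )


def combine_target_splits(per_target_splits: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-target splits; duplicate (molecule, target) keys raise."""
    if not per_target_splits:
        return pd.DataFrame(
            columns=["smiles", "target_id", "cluster_id", "partition", "ac_label"]
        )
    combined = pd.concat(per_target_splits, ignore_index=True)
    dup = combined.duplicated(subset=["smiles", "target_id"])
    if dup.any():
        keys = combined.loc[dup, ["smiles", "target_id"]].itertuples(index=False)
        raise ValueError(f"duplicate (molecule, target) keys: {list(keys)[:5]}")
    return combined


def split_dataset(
    records: Sequence[BioactivityRecord],
    molecules: Mapping[str, StandardizedMolecule],
    k: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple, list[ACPair]]]:
    """Per-(target, type) cliff annotation and split, combined across targets.

    Returns the combined split table (one row per molecule/target/type) and the
    per-group AC pair lists.  Seeds are derived per group so the result does not
    depend on group iteration order.
    """
    groups: dict[tuple, list[BioactivityRecord]] = {}
    for r in records:
        groups.setdefault((r.target_id, r.activity_type), []).append(r)
    splits, all_pairs = [], {}
    for gi, (key, recs) in enumerate(sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value))):
        pairs = find_ac_pairs(recs, molecules)
        all_pairs[key] = pairs
        labels = compound_ac_labels(pairs, sorted({r.smiles for r in recs}))
        df = ac_split(recs, labels, molecules, k=k, train_frac=train_frac, seed=seed + gi)
        df = df.assign(activity_type=key[1].value)
        splits.append(df)
    if not splits:
        return (
            pd.DataFrame(
                columns=["smiles", "target_id", "cluster_id", "partition", "ac_label", "activity_type"]
            ),
            all_pairs,
        )
    combined = pd.concat(splits, ignore_index=True)
    dup = combined.duplicated(subset=["smiles", "target_id", "activity_type"])
    if dup.any():
        raise ValueError("duplicate (molecule, target, type) rows across splits")
    return combined, all_pairs
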