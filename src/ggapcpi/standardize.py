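"""Molecule normalization, fingerprints, and the three pairwise similarities.

A molecule is reduced to its canonical parent structure (salt/solvent stripped,
charges neutralised, tautomer canonicalised) and described by two 2048-bit
radius-2 circular fingerprints — one on the whole molecule, one on its
Bemis–Murcko scaffold.  Pair similarity combines Tanimoto on both fingerprints
with a normalised Levenshtein similarity of the canonical SMILES; an activity
cliff requires any of the three to exceed 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger("ggapcpi")
RDLogger.DisableLog("rdApp.*")

FP_BITS = 2048
FP_RADIUS = 2

_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)
_metal_disconnector = rdMolStandardize.MetalDisconnector()
_uncharger = rdMolStandardize.Uncharger()
_tautomer_enumerator = rdMolStandardize.TautomerEnumerator()


@dataclass(frozen=True)
class StandardizedMolecule:
    input_smiles: str
    canonical_smiles: str
    ecfp: np.ndarray          # (2048,) uint8 binary
    scaffold_fp: np.ndarray   # (2048,) uint8 binary

    def __post_init__(self) -> None:
        assert self.ecfp.shape == (FP_BITS,)
        assert self.scaffold_fp.shape == (FP_BITS,)


@dataclass(frozen=True)
class RejectionRecord:
    """A molecule excluded from the pipeline, with the reason."""

    input_smiles: str
    reason: str


@dataclass(frozen=True)
class SimilarityTriple:
    tanimoto_full: float
    tanimoto_scaffold: float
    levenshtein_sim: float

    def max(self) -> float:
        return max(self.tanimoto_full, self.tanimoto_scaffold, self.levenshtein_sim)


def _fingerprint(mol: Chem.Mol) -> np.ndarray:
    return np.asarray(_fpgen.GetFingerprint(mol), dtype=np.uint8)


def standardize_molecule(smiles: str) -> StandardizedMolecule | RejectionRecord:
    """Normalise a SMILES to its canonical parent and fingerprint it.

    Applies, in order: functional-group normalization, metal disconnection,
    reionization, largest-fragment (salt/solvent) selection, charge
    neutralization, and tautomer canonicalization.  Unparseable or empty input
    yields a :class:`RejectionRecord` rather than raising, so batch runs
    continue.
    """
    if not smiles or not smiles.strip():
        return RejectionRecord(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return RejectionRecord(smiles, "unparseable SMILES")
    try:
        mol = rdMolStandardize.Cleanup(mol)  # normalize functional groups, reionize
        mol = _metal_disconnector.Disconnect(mol)
        mol = rdMolStandardize.FragmentParent(mol)  # drop salt/solvent fragments
        mol = _uncharger.uncharge(mol)
        mol = _tautomer_enumerator.Canonicalize(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        canonical = Chem.MolToSmiles(mol)
        parent = Chem.MolFromSmiles(canonical)
        if parent is None or parent.GetNumAtoms() == 0:
            return RejectionRecord(smiles, "standardization produced no parent")
        scaffold = MurckoScaffold.GetScaffoldForMol(parent)
        return StandardizedMolecule(
            input_smiles=smiles,
            canonical_smiles=canonical,
            ecfp=_fingerprint(parent),
            scaffold_fp=_fingerprint(scaffold),
        )
    except Exception as exc:  # pragma: no cover - defensive batch guard
        return RejectionRecord(smiles, f"standardization error: {exc}")


def standardize_batch(
    smiles_list: Sequence[str],
) -> tuple[dict[str, StandardizedMolecule], list[RejectionRecord]]:
    """Standardize many SMILES; returns (input smiles -> molecule, rejects)."""
    ok: dict[str, StandardizedMolecule] = {}
    rejects: list[RejectionRecord] = []
    for smi in smiles_list:
        if smi in ok:
            continue
        res = standardize_molecule(smi)
        if isinstance(res, RejectionRecord):
            rejects.append(res)
            logger.info("rejected molecule %r: %s", smi, res.reason)
        else:
            ok[smi] = res
    return ok, rejects


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over fingerprint on-bits."""
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        # two empty fingerprints (e.g. acyclic molecules' empty scaffolds)
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - editdistance(a, b) / max(|a|, |b|), in [0, 1]."""
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def similarity_triple(a: StandardizedMolecule, b: StandardizedMolecule) -> SimilarityTriple:
    return SimilarityTriple(
        tanimoto_full=tanimoto(a.ecfp, b.ecfp),
        tanimoto_scaffold=tanimoto(a.scaffold_fp, b.scaffold_fp),
        levenshtein_sim=levenshtein_similarity(a.canonical_smiles, b.canonical_smiles),
    )
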