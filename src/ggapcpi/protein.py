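"""Residue-level protein graphs for the graph-convolution encoder.

Two modes: ``sequence`` builds the peptide-bond chain graph (i, i±1); given a
PDB structure, ``contacts`` unions seven residue-contact types — peptide bond,
hydrogen bond, disulfide, ionic, aromatic, aromatic–sulfur, and cation–pi —
computed from inter-atomic distances with the distance cutoffs customary for
residue-interaction networks.  Self-loops are always added before the symmetric
degree normalisation used by the GCN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import ProteinEntry, one_hot_embedding

logger = logging.getLogger("ggapcpi")

# distance cutoffs (angstrom) for the contact types, residue-interaction
# network conventions
HBOND_CUTOFF = 3.5
DISULFIDE_CUTOFF = 2.2
IONIC_CUTOFF = 6.0
AROMATIC_MIN, AROMATIC_MAX = 4.5, 7.0
AROMATIC_SULFUR_CUTOFF = 5.3
CATION_PI_CUTOFF = 6.0

_POSITIVE = {"ARG", "LYS", "HIS"}
_NEGATIVE = {"ASP", "GLU"}
_AROMATIC = {"PHE", "TYR", "TRP", "HIS"}
_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_CATION_ATOMS = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "CZ"}, "HIS": {"ND1", "NE2"}}
_SULFUR_ATOMS = {"CYS": {"SG"}, "MET": {"SD"}}


@dataclass
class ProtGraph:
    """Residue graph: union adjacency, its normalisation, and input embeddings."""

    target_id: str
    adjacency: np.ndarray      # (L, L) bool, no self-loops
    norm_adj: np.ndarray       # D^-1/2 (A + I) D^-1/2
    embeddings: np.ndarray     # (L, d_emb) float64

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]


def _normalize(adjacency: np.ndarray) -> np.ndarray:
    a_hat = adjacency.astype(np.float64) + np.eye(adjacency.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def chain_adjacency(length: int) -> np.ndarray:
    adj = np.zeros((length, length), dtype=bool)
    idx = np.arange(length - 1)
    adj[idx, idx + 1] = True
    adj[idx + 1, idx] = True
    return adj


def _min_dist(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.inf
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
    return float(d.min())


def contact_adjacency(structure_path: str | Path, length: int | None = None) -> np.ndarray:
    """Union adjacency over the seven contact types, computed from a PDB file."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(structure_path)).get_structure(model=1)
    arr = arr[np.isin(arr.element, ["C", "N", "O", "S"]) & (arr.hetero == False)]  # noqa: E712
    # residue bookkeeping in file order
    res_keys: list[tuple] = []
    key_index: dict[tuple, int] = {}
    for chain, resid in zip(arr.chain_id, arr.res_id):
        key = (chain, int(resid))
        if key not in key_index:
            key_index[key] = len(res_keys)
            res_keys.append(key)
    n = len(res_keys)
    if length is not None and n != length:
        logger.warning("structure has %d residues, sequence has %d", n, length)
    res_of_atom = np.array([key_index[(c, int(r))] for c, r in zip(arr.chain_id, arr.res_id)])
    res_name = {}
    for i, key in enumerate(res_keys):
        res_name[i] = arr.res_name[res_of_atom == i][0]

    def coords(i: int, atom_names: set[str] | None = None, elements: set[str] | None = None):
        mask = res_of_atom == i
        if atom_names is not None:
            mask &= np.isin(arr.atom_name, list(atom_names))
        if elements is not None:
            mask &= np.isin(arr.element, list(elements))
        return arr.coord[mask]

    adj = np.zeros((n, n), dtype=bool)
    chains = np.array([k[0] for k in res_keys])
    resids = np.array([k[1] for k in res_keys])
    for i in range(n):
        for j in range(i + 1, n):
            ni, nj = res_name[i], res_name[j]
            linked = False
            # peptide bond
            if chains[i] == chains[j] and abs(resids[i] - resids[j]) == 1:
                linked = True
            # hydrogen bond: N/O donor-acceptor proximity between side chains/backbone
            if not linked and _min_dist(
                coords(i, elements={"N", "O"}), coords(j, elements={"N", "O"})
            ) < HBOND_CUTOFF:
                linked = True
            # disulfide
            if not linked and ni == "CYS" and nj == "CYS":
                if _min_dist(coords(i, {"SG"}), coords(j, {"SG"})) < DISULFIDE_CUTOFF:
                    linked = True
            # ionic: oppositely charged side chains
            if not linked and (
                (ni in _POSITIVE and nj in _NEGATIVE) or (ni in _NEGATIVE and nj in _POSITIVE)
            ):
                if _min_dist(coords(i), coords(j)) < IONIC_CUTOFF:
                    linked = True
            # aromatic: ring-centroid distance in the stacking window
            if not linked and ni in _AROMATIC and nj in _AROMATIC:
                ca = coords(i, _RING_ATOMS[ni])
                cb = coords(j, _RING_ATOMS[nj])
                if len(ca) and len(cb):
                    dist = float(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0)))
                    if AROMATIC_MIN <= dist <= AROMATIC_MAX:
                        linked = True
            # aromatic-sulfur
            if not linked:
                for a, b in ((i, j), (j, i)):
                    na, nb = res_name[a], res_name[b]
                    if na in _SULFUR_ATOMS and nb in _AROMATIC:
                        if (
                            _min_dist(coords(a, _SULFUR_ATOMS[na]), coords(b, _RING_ATOMS[nb]))
                            < AROMATIC_SULFUR_CUTOFF
                        ):
                            linked = True
                            break
            # cation-pi
            if not linked:
                for a, b in ((i, j), (j, i)):
                    na, nb = res_name[a], res_name[b]
                    if na in _CATION_ATOMS and nb in _AROMATIC:
                        cb = coords(b, _RING_ATOMS[nb])
                        if len(cb) and (
                            _min_dist(coords(a, _CATION_ATOMS[na]), cb.mean(axis=0)[None])
                            < CATION_PI_CUTOFF
                        ):
                            linked = True
                            break
            if linked:
                adj[i, j] = adj[j, i] = True
    return adj


def build_protein_graph(
    entry: ProteinEntry,
    mode: str = "sequence",
    embeddings: np.ndarray | None = None,
) -> ProtGraph:
    """Build the residue graph for one protein.

    ``mode='contacts'`` requires ``entry.structure_path`` and unions the seven
    contact types; ``mode='sequence'`` uses the peptide-bond chain only.  If no
    embedding matrix is supplied (argument or ``entry.embedding``), the one-hot
    fallback is attached.
    """
    if mode not in {"sequence", "contacts"}:
        raise ValueError(f"unknown protein graph mode {mode!r}")
    length = len(entry.sequence)
    if mode == "contacts":
        if entry.structure_path is None:
            raise ValueError(
                f"{entry.target_id}: mode='contacts' needs a structure; "
                "fall back to mode='sequence'"
            )
        adjacency = contact_adjacency(entry.structure_path, length)
    else:
        adjacency = chain_adjacency(length)
    emb = embeddings if embeddings is not None else entry.embedding
    if emb is None:
        emb = one_hot_embedding(entry.sequence)
    emb = np.asarray(emb, dtype=np.float64)
    if emb.shape[0] != adjacency.shape[0]:
        raise ValueError(
            f"{entry.target_id}: embedding rows ({emb.shape[0]}) != graph size "
            f"({adjacency.shape[0]})"
        )
    return ProtGraph(
        target_id=entry.target_id,
        adjacency=adjacency,
        norm_adj=_normalize(adjacency),
        embeddings=emb,
    )
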