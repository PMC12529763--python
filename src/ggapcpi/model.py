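"""The structure-free compound–protein interaction network.

Four blocks, all operating at a shared hidden width ``d_h`` (default 300):

* a communicative message-passing ligand encoder over the directed molecular
  graph — node and edge hidden states are updated jointly, the reverse-edge
  hidden is subtracted when building edge messages, and a shared per-atom GRU
  cell followed by an atom sum reads out the graph embedding ``H_lig``;
* a symmetric-normalised graph convolution over the residue-contact graph,
  turning per-residue language-model embeddings (1280-dim by default) into
  residue states ``H_res`` and their mean ``H_prot``;
* multihead cross-attention pooling — ligand atoms are queries, protein
  residues are keys/values; each row of every head's attention matrix is a
  probability vector over residues, and head outputs (atom-averaged) are
  concatenated into the complex embedding ``H_comp``;
* a two-layer feed-forward decoder on ``H_CPI = H_lig ⊕ H_comp ⊕ H_prot``.

Ablation variants swap single blocks (fingerprint ligand branch, linear
protein branch, one-hot residue inputs, plain concatenation) so each
component's contribution can be isolated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from . import nn
from .nn import Parameter, Tensor, concat, gather_rows, segment_max, segment_sum
from .protein import ProtGraph
from .standardize import StandardizedMolecule

logger = logging.getLogger("ggapcpi")

# ---------------------------------------------------------------- featurization
# chemprop-convention feature blocks; dimensions are part of the model contract
_ATOMIC_NUMS = list(range(1, 101))
_DEGREES = [0, 1, 2, 3, 4, 5]
_CHARGES = [-2, -1, 0, 1, 2]
_CHIRAL_TAGS = [0, 1, 2, 3]
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]
_BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]
_STEREO = list(range(6))

ATOM_FDIM = (len(_ATOMIC_NUMS) + 1) + (len(_DEGREES) + 1) + (len(_CHARGES) + 1) \
    + (len(_CHIRAL_TAGS) + 1) + (len(_NUM_HS) + 1) + (len(_HYBRIDIZATIONS) + 1) + 2
BOND_FDIM = 1 + len(_BOND_TYPES) + 2 + (len(_STEREO) + 1)
EDGE_FDIM = ATOM_FDIM + BOND_FDIM  # edge init sees its source atom


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    vec[choices.index(value) if value in choices else len(choices)] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    return (
        _one_hot(atom.GetAtomicNum(), _ATOMIC_NUMS)
        + _one_hot(atom.GetTotalDegree(), _DEGREES)
        + _one_hot(atom.GetFormalCharge(), _CHARGES)
        + _one_hot(int(atom.GetChiralTag()), _CHIRAL_TAGS)
        + _one_hot(atom.GetTotalNumHs(), _NUM_HS)
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0, atom.GetMass() * 0.01]
    )


def _bond_features(bond: Chem.Bond) -> list[float]:
    return (
        [0.0]
        + _one_hot(bond.GetBondType(), _BOND_TYPES)[:-1]
        + [1.0 if bond.GetIsConjugated() else 0.0, 1.0 if bond.IsInRing() else 0.0]
        + _one_hot(int(bond.GetStereo()), _STEREO)
    )


@dataclass
class MolGraph:
    """Directed molecular graph with paired reverse edges."""

    smiles: str
    atom_features: np.ndarray   # (n_atoms, ATOM_FDIM)
    edge_features: np.ndarray   # (n_edges, EDGE_FDIM); edges are directed
    edge_src: np.ndarray        # (n_edges,) source atom of each directed edge
    edge_dst: np.ndarray        # (n_edges,) destination atom
    rev_index: np.ndarray       # (n_edges,) index of the reverse directed edge
    ecfp: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_features.shape[0]


def featurize_molecule(mol: StandardizedMolecule | str) -> MolGraph:
    """Deterministic atom/bond feature matrices plus the reverse-edge table."""
    if isinstance(mol, StandardizedMolecule):
        smiles, ecfp = mol.canonical_smiles, mol.ecfp
    else:
        smiles, ecfp = mol, None
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None or rdmol.GetNumAtoms() == 0:
        raise ValueError(f"cannot featurize molecule {smiles!r}")
    atoms = np.array([_atom_features(a) for a in rdmol.GetAtoms()], dtype=np.float64)
    src, dst, feats = [], [], []
    for bond in rdmol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        for a, b in ((u, v), (v, u)):
            src.append(a)
            dst.append(b)
            feats.append(list(atoms[a]) + bf)
    n_edges = len(src)
    rev = np.arange(n_edges) ^ 1  # edges appended in (fwd, rev) pairs
    return MolGraph(
        smiles=smiles,
        atom_features=atoms,
        edge_features=np.array(feats, dtype=np.float64).reshape(n_edges, EDGE_FDIM),
        edge_src=np.array(src, dtype=np.intp),
        edge_dst=np.array(dst, dtype=np.intp),
        rev_index=rev,
        ecfp=None if ecfp is None else np.asarray(ecfp, dtype=np.float64),
    )


@dataclass
class BatchedMolGraph:
    """Disconnected union of several molecular graphs."""

    atom_features: np.ndarray
    edge_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    rev_index: np.ndarray
    mol_index: np.ndarray        # (n_atoms,) which molecule each atom belongs to
    atom_slices: list[tuple[int, int]]
    ecfp: np.ndarray | None

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_mols(self) -> int:
        return len(self.atom_slices)


def batch_molgraphs(graphs: Sequence[MolGraph]) -> BatchedMolGraph:
    atom_off, edge_off = 0, 0
    atoms, edges, src, dst, rev, mol_idx, slices, fps = [], [], [], [], [], [], [], []
    for i, g in enumerate(graphs):
        atoms.append(g.atom_features)
        edges.append(g.edge_features)
        src.append(g.edge_src + atom_off)
        dst.append(g.edge_dst + atom_off)
        rev.append(g.rev_index + edge_off)
        mol_idx.append(np.full(g.n_atoms, i, dtype=np.intp))
        slices.append((atom_off, atom_off + g.n_atoms))
        fps.append(g.ecfp)
        atom_off += g.n_atoms
        edge_off += g.n_edges
    return BatchedMolGraph(
        atom_features=np.concatenate(atoms, axis=0),
        edge_features=np.concatenate(edges, axis=0)
        if edges
        else np.zeros((0, EDGE_FDIM)),
        edge_src=np.concatenate(src) if src else np.zeros(0, dtype=np.intp),
        edge_dst=np.concatenate(dst) if dst else np.zeros(0, dtype=np.intp),
        rev_index=np.concatenate(rev) if rev else np.zeros(0, dtype=np.intp),
        mol_index=np.concatenate(mol_idx),
        atom_slices=slices,
        ecfp=np.stack(fps) if all(f is not None for f in fps) and fps else None,
    )


# ------------------------------------------------------------------- the model
ABLATION_VARIANTS = (
    "kano_only",
    "no_mol_encoder",
    "no_prot_encoder",
    "no_esm",
    "no_cross_attention",
    "no_integration",
)

ONE_HOT_DIM = 21  # 20 standard residues + X


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 300
    n_mpnn_layers: int = 1
    n_gcn_layers: int = 1
    n_attention_heads: int = 5
    residue_embedding_dim: int = 1280
    readout_hidden_factor: int = 2   # readout GRU hidden = factor * hidden_dim
    ecfp_dim: int = 2048
    dropout: float = 0.1
    seed: int = 0
    # ablation switches
    no_mol_encoder: bool = False
    no_prot_encoder: bool = False
    no_esm: bool = False
    no_cross_attention: bool = False
    ligand_only: bool = False
    per_type_training: bool = False

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_attention_heads != 0:
            raise ValueError(
                f"hidden dimension {self.hidden_dim} must be divisible by the "
                f"attention head count {self.n_attention_heads}"
            )

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.n_attention_heads

    @property
    def residue_input_dim(self) -> int:
        return ONE_HOT_DIM if self.no_esm else self.residue_embedding_dim

    @property
    def cpi_dim(self) -> int:
        if self.ligand_only:
            return self.hidden_dim
        if self.no_cross_attention:
            return 2 * self.hidden_dim
        return 3 * self.hidden_dim


def apply_ablation(config: ModelConfig, variant: str) -> ModelConfig:
    """Return the config of a named ablation variant of the full model."""
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}")
    if variant == "kano_only":
        return replace(config, ligand_only=True)
    if variant == "no_integration":
        return replace(config, per_type_training=True)
    return replace(config, **{variant: True})


class GGAPModel:
    """Encoder–attention–decoder network predicting pActivity for a CPI pair."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.training = False
        self._rng = np.random.default_rng(self.config.seed)
        self._dropout_rng = np.random.default_rng(self.config.seed + 1)
        self.params: dict[str, Parameter] = {}
        self._build()

    # ------------------------------------------------------------------ setup
    def _add_linear(self, name: str, fan_in: int, fan_out: int) -> None:
        self.params.update(nn.linear_params(self._rng, name, fan_in, fan_out))

    def _build(self) -> None:
        cfg = self.config
        d = cfg.hidden_dim
        if cfg.no_mol_encoder:
            self._add_linear("lig.fp", cfg.ecfp_dim, d)
        else:
            self._add_linear("lig.atom_in", ATOM_FDIM, d)
            self._add_linear("lig.edge_in", EDGE_FDIM, d)
            for layer in range(cfg.n_mpnn_layers):
                self._add_linear(f"lig.node_update{layer}", 2 * d, d)
                self._add_linear(f"lig.edge_update{layer}", d, d)
            self._add_linear("lig.atom_out", 3 * d, d)
            self.params.update(
                nn.gru_cell_params(
                    self._rng, "lig.readout", d, cfg.readout_hidden_factor * d
                )
            )
        if not cfg.ligand_only:
            for layer in range(cfg.n_gcn_layers):
                fan_in = cfg.residue_input_dim if layer == 0 else d
                self._add_linear(f"prot.gcn{layer}", fan_in, d)
            if not cfg.no_cross_attention:
                for h in range(cfg.n_attention_heads):
                    for proj in ("Q", "K", "V"):
                        self._add_linear(f"attn.head{h}.{proj}", d, cfg.head_dim)
        self._add_linear("dec.hidden", cfg.cpi_dim, d)
        self._add_linear("dec.out", d, 1)

    def count_parameters(self) -> int:
        """Number of trainable scalars (frozen input embeddings excluded)."""
        return sum(p.data.size for p in self.params.values())

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def _drop(self, x: Tensor) -> Tensor:
        return nn.dropout(x, self.config.dropout, self._dropout_rng, self.training)

    # --------------------------------------------------------- ligand encoder
    def encode_ligand(self, batch: BatchedMolGraph) -> tuple[Tensor, Tensor]:
        """Return per-atom embeddings and the per-molecule graph embeddings."""
        cfg = self.config
        if cfg.no_mol_encoder:
            if batch.ecfp is None:
                raise ValueError("fingerprint ablation needs ECFP vectors")
            h_lig = nn.linear(Tensor(batch.ecfp), self.params, "lig.fp")
            return h_lig, h_lig  # one "atom" row per molecule
        n_atoms = batch.n_atoms
        h_v = nn.linear(Tensor(batch.atom_features), self.params, "lig.atom_in").relu()
        h_e0 = nn.linear(Tensor(batch.edge_features), self.params, "lig.edge_in").relu()
        h_e = h_e0
        for layer in range(cfg.n_mpnn_layers):
            # node message: sum of incoming edge hiddens, boosted element-wise
            # by their max (communicative aggregation; empty neighborhoods -> 0)
            m_sum = segment_sum(h_e, batch.edge_dst, n_atoms)
            m_max = segment_max(h_e, batch.edge_dst, n_atoms)
            m_v = m_sum * m_max
            h_v = self._drop(
                nn.linear(concat([h_v, m_v]), self.params, f"lig.node_update{layer}").relu()
            )
            # edge message: updated head-node hidden minus the reverse edge
            m_e = gather_rows(h_v, batch.edge_dst) - gather_rows(h_e, batch.rev_index)
            h_e = self._drop(
                (h_e0 + nn.linear(m_e, self.params, f"lig.edge_update{layer}")).relu()
            )
        m_sum = segment_sum(h_e, batch.edge_dst, n_atoms)
        m_max = segment_max(h_e, batch.edge_dst, n_atoms)
        m_final = m_sum * m_max
        e0_v = segment_sum(h_e0, batch.edge_dst, n_atoms)  # incident initial hiddens
        h_atom = self._drop(
            nn.linear(concat([m_final, h_v, e0_v]), self.params, "lig.atom_out").relu()
        )
        # permutation-invariant GRU readout: shared cell per atom, hidden state
        # initialised from [H_atom; M], halves folded back to d_h, atoms summed
        d = cfg.hidden_dim
        h0 = concat([h_atom, m_final])
        h1 = nn.gru_cell(h_atom, h0, self.params, "lig.readout")
        folded = h1.slice_cols(0, d)
        for k in range(1, cfg.readout_hidden_factor):
            folded = folded + h1.slice_cols(k * d, (k + 1) * d)
        h_lig = segment_sum(folded, batch.mol_index, batch.n_mols)
        return h_atom, h_lig

    # -------------------------------------------------------- protein encoder
    def encode_protein(self, graph: ProtGraph) -> tuple[Tensor, Tensor]:
        """Residue embeddings through the GCN; mean pooling gives H_prot."""
        cfg = self.config
        h = Tensor(graph.embeddings)
        norm = Tensor(graph.norm_adj)
        for layer in range(cfg.n_gcn_layers):
            h_in = h if cfg.no_prot_encoder else norm @ h
            h = self._drop(nn.linear(h_in, self.params, f"prot.gcn{layer}").relu())
        h_prot = h.mean(axis=0, keepdims=True)
        return h, h_prot

    # --------------------------------------------------------- attention pool
    def cross_attention_pool(
        self, h_atom: Tensor, h_res: Tensor
    ) -> tuple[Tensor, np.ndarray]:
        """Pool atoms against residues; returns H_comp and the attention tensor
        (heads, atoms, residues) for interpretability."""
        cfg = self.config
        scale = 1.0 / np.sqrt(cfg.head_dim)
        heads, attn = [], []
        for h in range(cfg.n_attention_heads):
            q = nn.linear(h_atom, self.params, f"attn.head{h}.Q")
            k = nn.linear(h_res, self.params, f"attn.head{h}.K")
            v = nn.linear(h_res, self.params, f"attn.head{h}.V")
            a = ((q @ k.T) * scale).softmax_rows()
            heads.append((a @ v).mean(axis=0, keepdims=True))
            attn.append(a.data)
        return concat(heads, axis=-1), np.stack(attn)


    # ----------------------------------------------------------------- decode
    def decode(self, h_cpi: Tensor) -> Tensor:
        hidden = self._drop(nn.linear(h_cpi, self.params, "dec.hidden").relu())
        return nn.linear(hidden, self.params, "dec.out")

    def forward(
        self,
        batch: BatchedMolGraph,
        prot_graphs: Mapping[str, ProtGraph],
        pair_proteins: Sequence[str],
        return_attention: bool = False,
    ):
        """Predict pActivity for pairs (molecule i of the batch, protein id i).

        Returns the (n_pairs,) prediction tensor, and optionally the per-pair
        attention tensors.
        """
        cfg = self.config
        if len(pair_proteins) != batch.n_mols:
            raise ValueError("one protein id per batched molecule is required")
        h_atom, h_lig = self.encode_ligand(batch)
        if cfg.ligand_only:
            y = self.decode(h_lig)
            return (y.reshape(-1), []) if return_attention else y.reshape(-1)
        encoded = {
            pid: self.encode_protein(prot_graphs[pid]) for pid in dict.fromkeys(pair_proteins)
        }
        outputs, attention = [], []
        for i, pid in enumerate(pair_proteins):
            h_res, h_prot = encoded[pid]
            if cfg.no_mol_encoder:
                # fingerprint branch: the molecule embedding is the single query
                a0, a1 = i, i + 1
            else:
                a0, a1 = batch.atom_slices[i]
            atom_rows = gather_rows(h_atom, np.arange(a0, a1))
            h_lig_i = gather_rows(h_lig, np.array([i]))
            if cfg.no_cross_attention:
                h_cpi = concat([h_lig_i, h_prot], axis=-1)
            else:
                h_comp, attn = self.cross_attention_pool(atom_rows, h_res)
                h_cpi = concat([h_lig_i, h_comp, h_prot], axis=-1)
                if return_attention:
                    attention.append(attn)
            outputs.append(self.decode(h_cpi))
        y = concat(outputs, axis=0).reshape(-1)
        return (y, attention) if return_attention else y

    def predict(
        self,
        batch: BatchedMolGraph,
        prot_graphs: Mapping[str, ProtGraph],
        pair_proteins: Sequence[str],
        return_attention: bool = False,
    ):
        """Deterministic inference (dropout off)."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(batch, prot_graphs, pair_proteins, return_attention)
        finally:
            self.training = was_training
        if return_attention:
            y, attention = out
            return y.data.copy(), attention
        return out.data.copy()

    # ------------------------------------------------------------- checkpoint
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("checkpoint parameter names do not match the config")
        for k, arr in state.items():
            if self.params[k].data.shape != arr.shape:
                raise ValueError(
                    f"checkpoint shape mismatch for {k}: "
                    f"{arr.shape} vs {self.params[k].data.shape}"
                )
            self.params[k].data = np.array(arr, dtype=np.float64)

    def save(self, path: str | Path) -> None:
        """Single-file archive holding the config and named parameter arrays."""
        arrays = {f"param:{k}": v for k, v in self.state_dict().items()}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GGAPModel":
        with np.load(path, allow_pickle=False) as archive:
            config = ModelConfig(**json.loads(str(archive["config"])))
            model = cls(config)
            model.load_state_dict(
                {k[len("param:"):]: archive[k] for k in archive.files if k.startswith("param:")}
            )
        return model


def count_parameters(config: ModelConfig | None = None) -> int:
    """Trainable-parameter count of a configuration (pure function)."""
    return GGAPModel(config or ModelConfig()).count_parameters()
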