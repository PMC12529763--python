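"""Architecture contracts: featurization, encoders, attention, ablations."""

import numpy as np
import pytest
from rdkit import Chem

from ggapcpi.model import (
    ABLATION_VARIANTS,
    ATOM_FDIM,
    EDGE_FDIM,
    GGAPModel,
    ModelConfig,
    apply_ablation,
    batch_molgraphs,
    count_parameters,
    featurize_molecule,
)
from ggapcpi.nn import Tensor
from ggapcpi.protein import ProtGraph, build_protein_graph, chain_adjacency
from ggapcpi.records import ProteinEntry


# --------------------------------------------------------------- featurization
@pytest.mark.parametrize(
    "smiles,n_atoms,n_edges",
    [("C", 1, 0), ("CC", 2, 2), ("c1ccccc1", 6, 12)],
)
def test_molecular_graph_counts(smiles, n_atoms, n_edges):
    g = featurize_molecule(smiles)
    assert g.n_atoms == n_atoms
    assert g.n_edges == n_edges
    assert g.atom_features.shape == (n_atoms, ATOM_FDIM)
    assert g.edge_features.shape == (n_edges, EDGE_FDIM)
    # every directed edge has exactly one reverse
    assert np.array_equal(g.rev_index[g.rev_index], np.arange(n_edges))
    assert np.array_equal(g.edge_src[g.rev_index], g.edge_dst)


def test_zero_atom_input_raises():
    with pytest.raises(ValueError):
        featurize_molecule("not-a-smiles")


# -------------------------------------------------------------- protein graphs
def test_sequence_mode_chain_adjacency():
    graph = build_protein_graph(ProteinEntry("P", "MKV"), "sequence")
    expected = np.zeros((3, 3), dtype=bool)
    expected[0, 1] = expected[1, 0] = expected[1, 2] = expected[2, 1] = True
    assert np.array_equal(graph.adjacency, expected)
    assert np.allclose(graph.norm_adj, graph.norm_adj.T)  # symmetric after self-loops


def test_single_residue_graph():
    graph = build_protein_graph(ProteinEntry("P", "M"), "sequence")
    assert graph.adjacency.shape == (1, 1)
    assert graph.norm_adj[0, 0] == pytest.approx(1.0)


def test_contacts_mode_requires_structure():
    with pytest.raises(ValueError, match="structure"):
        build_protein_graph(ProteinEntry("P", "MKV"), "contacts")


def test_contact_graph_from_structure(tmp_path):
    # two CYS side by side with SG atoms 2.0 A apart: peptide bond + disulfide
    pdb = tmp_path / "toy.pdb"
    pdb.write_text(
        "ATOM      1  N   CYS A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  CYS A   1       1.400   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  SG  CYS A   1       2.000   9.000   0.000  1.00  0.00           S\n"
        "ATOM      4  N   CYS A   2       2.800   0.000   0.000  1.00  0.00           N\n"
        "ATOM      5  CA  CYS A   2       4.200   0.000   0.000  1.00  0.00           C\n"
        "ATOM      6  SG  CYS A   2       2.000  11.000   0.000  1.00  0.00           S\n"
        "ATOM      7  N   GLY A   9       0.000  30.000   0.000  1.00  0.00           N\n"
        "ATOM      8  CA  GLY A   9       1.400  30.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    entry = ProteinEntry("P", "CCG", structure_path=pdb)
    graph = build_protein_graph(entry, "contacts")
    assert graph.adjacency[0, 1] and graph.adjacency[1, 0]   # bonded neighbors
    assert not graph.adjacency[0, 2] and not graph.adjacency[1, 2]  # far residue
    assert np.array_equal(graph.adjacency, graph.adjacency.T)


# ------------------------------------------------------------- parameter count
def test_decoder_parameter_count_by_hand():
    # two-layer decoder at d_h=300: 900*300 + 300 + 300*1 + 1
    model = GGAPModel(ModelConfig())
    decoder = sum(
        model.params[k].data.size for k in model.params if k.startswith("dec.")
    )
    assert decoder == 900 * 300 + 300 + 300 * 1 + 1 == 270_601


def test_count_is_monotone_in_hidden_dim():
    small = count_parameters(ModelConfig(hidden_dim=150))
    large = count_parameters(ModelConfig(hidden_dim=300))
    assert large > small


def test_one_hot_ablation_shrinks_residue_input():
    cfg = apply_ablation(ModelConfig(), "no_esm")
    model = GGAPModel(cfg)
    assert model.params["prot.gcn0.W"].shape == (21, 300)


def test_unknown_ablation_variant_rejected():
    with pytest.raises(ValueError):
        apply_ablation(ModelConfig(), "no_such_variant")


def test_head_divisibility_is_enforced():
    with pytest.raises(ValueError):
        ModelConfig(hidden_dim=301)


# ------------------------------------------------------- encoder invariants
def _prot(seq="MKVLATGRES", seed=0, dim=21):
    rng = np.random.default_rng(seed)
    emb = rng.random((len(seq), dim))
    return ProteinEntry("P", seq, embedding=emb)


def test_hlig_invariant_to_atom_reindexing(tiny_model):
    smiles = "CCOC(=O)c1ccc(N)cc1"
    mol = Chem.MolFromSmiles(smiles)
    variants = [Chem.MolToSmiles(mol, canonical=False, rootedAtAtom=k) for k in (0, 4, 9)]
    embeddings = []
    for smi in variants:
        batch = batch_molgraphs([featurize_molecule(smi)])
        _, h_lig = tiny_model.encode_ligand(batch)
        embeddings.append(h_lig.data[0])
    for e in embeddings[1:]:
        assert np.allclose(e, embeddings[0], atol=1e-5)


def test_protein_outputs_equivariant_under_residue_permutation(tiny_model):
    graph = build_protein_graph(_prot(), "sequence")
    perm = np.random.default_rng(1).permutation(graph.n_residues)
    permuted = ProtGraph(
        target_id="P",
        adjacency=graph.adjacency[np.ix_(perm, perm)],
        norm_adj=graph.norm_adj[np.ix_(perm, perm)],
        embeddings=graph.embeddings[perm],
    )
    h_res, h_prot = tiny_model.encode_protein(graph)
    h_res_p, h_prot_p = tiny_model.encode_protein(permuted)
    assert np.allclose(h_prot_p.data, h_prot.data, atol=1e-5)     # pooled: invariant
    assert np.allclose(h_res_p.data, h_res.data[perm], atol=1e-5)  # rows: equivariant
    batch = batch_molgraphs([featurize_molecule("CCO")])
    h_atom, _ = tiny_model.encode_ligand(batch)
    h_comp, attn = tiny_model.cross_attention_pool(h_atom, h_res)
    h_comp_p, attn_p = tiny_model.cross_attention_pool(h_atom, h_res_p)
    assert np.allclose(h_comp_p.data, h_comp.data, atol=1e-5)
    assert np.allclose(attn_p, attn[:, :, perm], atol=1e-5)  # columns permute


def test_attention_rows_sum_to_one(tiny_model):
    batch = batch_molgraphs([featurize_molecule("CCOC(=O)C")])
    h_atom, _ = tiny_model.encode_ligand(batch)
    h_res, _ = tiny_model.encode_protein(build_protein_graph(_prot(), "sequence"))
    _, attn = tiny_model.cross_attention_pool(h_atom, h_res)
    assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
    assert (attn >= 0).all()


def test_single_residue_attention_is_one(tiny_model):
    batch = batch_molgraphs([featurize_molecule("CCO")])
    h_atom, _ = tiny_model.encode_ligand(batch)
    h_res, _ = tiny_model.encode_protein(
        build_protein_graph(ProteinEntry("P", "M", embedding=np.ones((1, 21))), "sequence")
    )
    _, attn = tiny_model.cross_attention_pool(h_atom, h_res)
    assert np.allclose(attn, 1.0)


def test_zero_projections_give_uniform_attention(tiny_model):
    for h in range(tiny_model.config.n_attention_heads):
        for proj in ("Q", "K"):
            tiny_model.params[f"attn.head{h}.{proj}.W"].data[:] = 0.0
            tiny_model.params[f"attn.head{h}.{proj}.b"].data[:] = 0.0
    batch = batch_molgraphs([featurize_molecule("CCO")])
    h_atom, _ = tiny_model.encode_ligand(batch)
    graph = build_protein_graph(_prot(), "sequence")
    h_res, _ = tiny_model.encode_protein(graph)
    _, attn = tiny_model.cross_attention_pool(h_atom, h_res)
    assert np.allclose(attn, 1.0 / graph.n_residues, atol=1e-12)


def test_single_atom_molecule_uses_empty_neighborhood_convention(tiny_model):
    batch = batch_molgraphs([featurize_molecule("C")])
    h_atom, h_lig = tiny_model.encode_ligand(batch)
    assert h_atom.shape == (1, 20)
    assert np.isfinite(h_lig.data).all()


def test_gcn_single_residue_identity_closed_form():
    cfg = ModelConfig(hidden_dim=20, residue_embedding_dim=20, dropout=0.0)
    model = GGAPModel(cfg)
    model.params["prot.gcn0.W"].data = np.eye(20)
    model.params["prot.gcn0.b"].data[:] = 0.0
    h0 = np.random.default_rng(2).random((1, 20))  # nonnegative: ReLU is a no-op
    graph = ProtGraph("P", np.zeros((1, 1), dtype=bool), np.ones((1, 1)), h0)
    h_res, h_prot = model.encode_protein(graph)
    assert np.allclose(h_res.data, h0)
    assert np.allclose(h_prot.data, h0)


def test_identical_fully_connected_residues_stay_identical(tiny_model):
    L = 5
    emb = np.tile(np.random.default_rng(3).random(21), (L, 1))
    adj = np.ones((L, L), dtype=bool) & ~np.eye(L, dtype=bool)
    from ggapcpi.protein import _normalize

    graph = ProtGraph("P", adj, _normalize(adj), emb)
    h_res, h_prot = tiny_model.encode_protein(graph)
    assert np.allclose(h_res.data, h_res.data[0])
    assert np.allclose(h_prot.data, h_res.data[0])


# ------------------------------------------------------------------- decoding
def test_decoder_degenerate_weights(tiny_model):
    d = tiny_model.config.hidden_dim
    h_cpi = Tensor(np.random.default_rng(4).random((1, 3 * d)))
    for name in ("dec.hidden", "dec.out"):
        tiny_model.params[f"{name}.W"].data[:] = 0.0
        tiny_model.params[f"{name}.b"].data[:] = 0.0
    assert tiny_model.decode(h_cpi).data.item() == 0.0
    tiny_model.params["dec.out.b"].data[:] = 3.5  # constant head
    assert tiny_model.decode(h_cpi).data.item() == 3.5


def test_cpi_dimension_by_variant():
    assert ModelConfig().cpi_dim == 900
    assert apply_ablation(ModelConfig(), "no_cross_attention").cpi_dim == 600
    assert apply_ablation(ModelConfig(), "kano_only").cpi_dim == 300


def test_ligand_only_variant_ignores_the_protein(tiny_config):
    cfg = apply_ablation(tiny_config, "kano_only")
    model = GGAPModel(cfg)
    batch = batch_molgraphs([featurize_molecule("CCO")])
    g1 = {"A": build_protein_graph(_prot("MKV", 1), "sequence")}
    g2 = {"B": build_protein_graph(_prot("ACDEFGHIK", 2), "sequence")}
    y1 = model.predict(batch, g1, ["A"])
    y2 = model.predict(batch, g2, ["B"])
    assert y1 == pytest.approx(y2)


def test_fingerprint_variant_runs_without_atom_graphs(tiny_config):
    from ggapcpi.standardize import standardize_molecule

    cfg = apply_ablation(tiny_config, "no_mol_encoder")
    model = GGAPModel(cfg)
    std = standardize_molecule("CCOC(=O)c1ccc(N)cc1")
    batch = batch_molgraphs([featurize_molecule(std)])
    graphs = {"P": build_protein_graph(_prot(), "sequence")}
    y = model.predict(batch, graphs, ["P"])
    assert y.shape == (1,) and np.isfinite(y).all()


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    batch = batch_molgraphs([featurize_molecule("CCO")])
    graphs = {"P": build_protein_graph(_prot(), "sequence")}
    before = tiny_model.predict(batch, graphs, ["P"])
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = GGAPModel.load(path)
    after = loaded.predict(batch, graphs, ["P"])
    assert np.array_equal(before, after)
    assert loaded.config == tiny_model.config


def test_variant_list_is_closed():
    assert set(ABLATION_VARIANTS) == {
        "kano_only",
        "no_mol_encoder",
        "no_prot_encoder",
        "no_esm",
        "no_cross_attention",
        "no_integration",
    }
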