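"""Integrated training, ensemble contracts, and uncertainty bookkeeping."""

import numpy as np
import pytest

from ggapcpi.cliffs import split_dataset
from ggapcpi.curation import resolve_conflicts
from ggapcpi.model import GGAPModel, ModelConfig
from ggapcpi.records import ActivityType, BioactivityRecord, Relation
from ggapcpi.training import (
    CPIDataset,
    EnsembleModel,
    MemberProvenance,
    TrainConfig,
    fine_tune,
    make_integrated_dataset,
    prepare_dataset,
    remove_overlap,
    sample_type_matched_validation,
    train_ensemble,
)

TINY_TRAIN = TrainConfig(batch_size=16, epochs=1, learning_rate=1e-3, seed=0)


@pytest.fixture(scope="module")
def split_setup(train_fixture):
    records, _ = resolve_conflicts(train_fixture.records)
    table, _ = split_dataset(records, train_fixture.molecules, seed=0)
    return train_fixture, records, table


def test_pooled_dataset_keeps_type_tags(split_setup):
    ds, records, table = split_setup
    pooled = make_integrated_dataset(records, table, ds.proteins, "train")
    types = {e.activity_type for e in pooled.examples}
    assert len(pooled) == int((table.partition == "train").sum())
    assert types <= {ActivityType.Ki, ActivityType.Kd, ActivityType.EC50, ActivityType.IC50}


def test_per_type_datasets_partition_the_pool(split_setup):
    ds, records, table = split_setup
    pooled = make_integrated_dataset(records, table, ds.proteins, "train")
    by_type = make_integrated_dataset(records, table, ds.proteins, "train", per_type=True)
    assert sum(len(d) for d in by_type.values()) == len(pooled)


def test_records_without_split_assignment_raise(split_setup):
    ds, records, table = split_setup
    stray = BioactivityRecord("x", "CCO", "SYNP0", ActivityType.Ki, Relation.eq, 5.0)
    with pytest.raises(ValueError, match="split assignment"):
        make_integrated_dataset(records + [stray], table, ds.proteins, "train")


def _toy_dataset(values_by_type, proteins, graphs):
    from ggapcpi.training import TrainExample

    examples = [
        TrainExample(smi, "SYNP0", a_type, v)
        for a_type, items in values_by_type.items()
        for smi, v in items
    ]
    return CPIDataset(examples, graphs, proteins)


def test_type_matched_sampling_equal_allocation(split_setup):
    ds, records, table = split_setup
    from ggapcpi.model import featurize_molecule
    from ggapcpi.protein import build_protein_graph

    graphs = {"CCO": featurize_molecule("CCO")}
    prots = {"SYNP0": build_protein_graph(ds.proteins[0], "sequence")}
    # two occupied 0.5-log bins with 100 and 10 members, budget 20 -> 10 + 10
    data = _toy_dataset(
        {
            ActivityType.Ki: [("CCO", 5.1 + 0.001 * i) for i in range(100)]
            + [("CCO", 8.1 + 0.001 * i) for i in range(10)],
            ActivityType.IC50: [("CCO", 6.0)],
        },
        prots,
        graphs,
    )
    sub = sample_type_matched_validation(data, budget=20, seed=1)
    assert len(sub) == 20
    low = sum(1 for e in sub.examples if e.value < 6)
    assert low == 10  # equal draw from each occupied bin
    assert all(e.activity_type is ActivityType.Ki for e in sub.examples)
    # budget >= available returns every reference-type record
    assert len(sample_type_matched_validation(data, budget=10_000)) == 110
    with pytest.raises(ValueError):
        sample_type_matched_validation(
            _toy_dataset({ActivityType.IC50: [("CCO", 6.0)]}, prots, graphs)
        )


def test_default_run_produces_ten_members(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    cfg = ModelConfig(hidden_dim=10, no_esm=True, dropout=0.0, seed=0)
    ensemble = train_ensemble(data, cfg, TINY_TRAIN)
    assert len(ensemble) == 10
    cycles = [p.cycle for p in ensemble.provenance]
    folds = [p.fold for p in ensemble.provenance]
    assert cycles == [0] * 5 + [1] * 5
    assert folds == list(range(5)) * 2


def test_same_seed_reruns_are_bit_identical(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    cfg = ModelConfig(hidden_dim=10, no_esm=True, dropout=0.1, seed=0)
    e1 = train_ensemble(data, cfg, TINY_TRAIN)
    e2 = train_ensemble(data, cfg, TINY_TRAIN)
    for m1, m2 in zip(e1.members, e2.members):
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)


def test_fold_partitions_are_disjoint_and_cover(split_setup):
    from sklearn.model_selection import KFold

    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    kf = KFold(n_splits=5, shuffle=True, random_state=0)
    seen = []
    for _, va in kf.split(np.arange(len(data))):
        seen.extend(va.tolist())
    assert sorted(seen) == list(range(len(data)))


def test_ensemble_mean_std_closed_form(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    cfg = ModelConfig(hidden_dim=10, no_esm=True, dropout=0.0, seed=0)
    members = [GGAPModel(ModelConfig(**{**vars(cfg), "seed": s})) for s in (1, 2)]
    # constant heads: member predictions are exactly 5.0 and 7.0
    for m, c in zip(members, (5.0, 7.0)):
        for name in ("dec.hidden", "dec.out"):
            m.params[f"{name}.W"].data[:] = 0.0
            m.params[f"{name}.b"].data[:] = 0.0
        m.params["dec.out.b"].data[:] = c
    ens = EnsembleModel(members, [MemberProvenance(0, i, 0, 0.0) for i in range(2)])
    (pred,) = ens.predict_pairs([(data.examples[0].smiles, data.examples[0].target_id)], data.prot_graphs)
    assert pred.mean == pytest.approx(6.0)
    assert pred.std == pytest.approx(np.sqrt(2.0))  # sample std with n-1
    assert np.array_equal(np.sort(pred.members), [5.0, 7.0])
    # translation invariance: shifting one member's constant shifts the mean only
    members[0].params["dec.out.b"].data[:] = 6.0
    (shifted,) = ens.predict_pairs(
        [(data.examples[0].smiles, data.examples[0].target_id)], data.prot_graphs
    )
    assert shifted.mean == pytest.approx(6.5)
    assert shifted.std == pytest.approx(np.sqrt(0.5))


def test_mean_std_match_recomputation_from_members(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    cfg = ModelConfig(hidden_dim=10, no_esm=True, dropout=0.0, seed=0)
    ens = train_ensemble(data, cfg, TINY_TRAIN)
    pairs = [(e.smiles, e.target_id) for e in data.examples[:5]]
    for pred in ens.predict_pairs(pairs, data.prot_graphs):
        assert pred.mean == np.mean(pred.members)
        assert pred.std == pytest.approx(np.std(pred.members, ddof=1))


def test_unfeaturizable_pair_yields_error_entry_not_abort(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    cfg = ModelConfig(hidden_dim=10, no_esm=True, dropout=0.0, seed=0)
    member = GGAPModel(cfg)
    ens = EnsembleModel([member], [MemberProvenance(0, 0, 0, 0.0)])
    good = (data.examples[0].smiles, data.examples[0].target_id)
    preds = ens.predict_pairs([good, ("??bad??", "SYNP0")], data.prot_graphs)
    assert preds[0].error is None and np.isfinite(preds[0].mean)
    assert preds[1].error is not None and np.isnan(preds[1].mean)


def test_fine_tune_zero_epochs_is_identity(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    model = GGAPModel(ModelConfig(hidden_dim=10, no_esm=True, seed=0))
    before = model.state_dict()
    tuned = fine_tune(model, data, TrainConfig(epochs=0))
    after = tuned.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_fine_tune_reduces_training_loss(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    model = GGAPModel(ModelConfig(hidden_dim=10, no_esm=True, dropout=0.0, seed=0))

    def mse():
        errs = [
            model.predict(b, data.prot_graphs, p) - y for b, p, y in data.batches(64)
        ]
        return float((np.concatenate(errs) ** 2).mean())

    before = mse()
    fine_tune(model, data, TrainConfig(epochs=10, learning_rate=1e-3, seed=0))
    assert mse() < before


def test_overlap_dedup_removes_exact_rows():
    mk = lambda v: BioactivityRecord("m", "CCO", "P1", ActivityType.Ki, Relation.eq, v)
    new = [mk(5.0), mk(6.0), mk(7.0)]
    ref = [mk(5.0), mk(7.0), mk(9.0)]
    assert [r.value for r in remove_overlap(new, ref)] == [6.0]


def test_ensemble_checkpoint_roundtrip(tmp_path, split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    cfg = ModelConfig(hidden_dim=10, no_esm=True, dropout=0.0, seed=0)
    member = GGAPModel(cfg)
    ens = EnsembleModel([member], [MemberProvenance(0, 0, 0, 0.0)])
    ens.save(tmp_path / "ens")
    loaded = EnsembleModel.load(tmp_path / "ens")
    pairs = [(data.examples[0].smiles, data.examples[0].target_id)]
    a = ens.predict_pairs(pairs, data.prot_graphs)[0]
    b = loaded.predict_pairs(pairs, data.prot_graphs)[0]
    assert a.mean == b.mean


def test_dataset_smaller_than_fold_count_raises(split_setup):
    ds, records, table = split_setup
    data = make_integrated_dataset(records, table, ds.proteins, "train")
    small = data.subset([0, 1, 2])
    with pytest.raises(ValueError, match="folds"):
        train_ensemble(small, ModelConfig(hidden_dim=10, no_esm=True), TINY_TRAIN)
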