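"""Metric machinery against independent references and closed forms."""

import numpy as np
import pytest
from scipy import stats

from ggapcpi.evaluation import (
    cliff_metrics,
    enrichment_factor,
    pocket_enrichment,
    regression_metrics,
    residue_attention_coefficients,
    scoring_ranking_powers,
    uncertainty_sweep,
)
from ggapcpi.training import PredictionWithUncertainty


def test_perfect_and_inverted_predictions():
    y = np.array([1.0, 2.0, 3.0, 5.0])
    rep = regression_metrics(y, y)
    assert (rep.rmse, rep.pcc, rep.srcc) == (0.0, 1.0, 1.0)
    rep = regression_metrics(y, -y)
    assert rep.pcc == pytest.approx(-1.0)
    assert rep.srcc == pytest.approx(-1.0)


def test_hand_computed_example():
    rep = regression_metrics([1, 2, 3], [1, 2, 4])
    assert rep.rmse == pytest.approx(np.sqrt(1 / 3))
    assert rep.srcc == pytest.approx(1.0)  # rank order preserved


def test_zero_variance_is_flagged_not_nan():
    rep = regression_metrics([1.0, 1.0], [2.0, 3.0])
    assert rep.pcc is None and rep.srcc is None
    assert rep.undefined_reason == "zero variance"
    assert np.isfinite(rep.rmse)


def test_metrics_match_reference_implementations():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(3, 40)
        y = rng.normal(size=n)
        p = y + rng.normal(scale=rng.uniform(0.01, 2.0), size=n)
        rep = regression_metrics(y, p)
        assert rep.rmse == pytest.approx(np.sqrt(np.mean((p - y) ** 2)), abs=1e-10)
        assert rep.pcc == pytest.approx(stats.pearsonr(y, p)[0], abs=1e-10)
        assert rep.srcc == pytest.approx(stats.spearmanr(y, p)[0], abs=1e-10)


def test_srcc_equals_pcc_of_ranks_with_ties():
    y = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
    p = np.array([1.5, 2.5, 2.5, 2.5, 4.0])
    rep = regression_metrics(y, p)
    assert rep.srcc == pytest.approx(stats.spearmanr(y, p)[0], abs=1e-12)
    ranked = regression_metrics(stats.rankdata(y), stats.rankdata(p))
    assert rep.srcc == pytest.approx(ranked.pcc, abs=1e-12)


def test_cliff_metrics_restrict_to_mask():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    p = np.array([1.1, 1.9, 3.5, 3.0])
    mask = np.array([True, False, True, False])
    rep = cliff_metrics(y, p, mask)
    sub = regression_metrics(y[mask], p[mask])
    assert (rep.rmse, rep.pcc, rep.srcc, rep.n) == (sub.rmse, sub.pcc, sub.srcc, 2)
    full = cliff_metrics(y, p, np.ones(4, dtype=bool))
    assert full == regression_metrics(y, p)
    empty = cliff_metrics(y, p, np.zeros(4, dtype=bool))
    assert empty.n == 0 and not empty.defined


def test_enrichment_factor_worked_examples():
    # 1000 candidates, 10 binders, 5 of them in the top 10 -> EF1% = 50
    scores = np.linspace(1.0, 0.0, 1000)
    labels = np.zeros(1000, dtype=bool)
    labels[[0, 2, 4, 6, 8, 500, 600, 700, 800, 900]] = True
    res = enrichment_factor(scores, labels, 0.01)
    assert res.ef == pytest.approx(50.0)
    assert (res.ntb_top, res.ntb_total) == (5, 10)
    labels = np.zeros(1000, dtype=bool)
    labels[:10] = True
    assert enrichment_factor(scores, labels, 0.01).ef == pytest.approx(100.0)


def test_enrichment_factor_bounds_and_monotone_invariance():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=500)
    labels = rng.random(500) < 0.1
    res = enrichment_factor(scores, labels, 0.05)
    assert 0 <= res.ef <= 1 / 0.05
    transformed = enrichment_factor(np.exp(scores) * 3 + 1, labels, 0.05)
    assert transformed.ef == res.ef


def test_enrichment_factor_validates_input():
    with pytest.raises(ValueError, match="binder"):
        enrichment_factor([1.0, 2.0], [False, False])
    with pytest.raises(ValueError, match="fraction"):
        enrichment_factor([1.0, 2.0], [True, False], fraction=0.0)


def test_random_scores_average_unit_enrichment():
    rng = np.random.default_rng(2)
    labels = np.zeros(2000, dtype=bool)
    labels[:100] = True
    efs = [
        enrichment_factor(rng.normal(size=2000), labels, 0.01).ef for _ in range(300)
    ]
    assert abs(np.mean(efs) - 1.0) < 0.3


def test_scoring_ranking_powers_per_group():
    y = np.array([1, 2, 3, 1, 2, 3], dtype=float)
    p = np.array([1, 2, 3, 3, 2, 1], dtype=float)  # perfect then inverted
    g = np.array(["A", "A", "A", "B", "B", "B"])
    per_group, (mean_pcc, mean_srcc) = scoring_ranking_powers(y, p, g)
    assert per_group["A"] == (pytest.approx(1.0), pytest.approx(1.0))
    assert per_group["B"] == (pytest.approx(-1.0), pytest.approx(-1.0))
    assert mean_pcc == pytest.approx(0.0) and mean_srcc == pytest.approx(0.0)


def test_small_groups_are_excluded():
    y = np.array([1.0, 1.0, 2.0])
    p = np.array([1.0, 1.0, 2.0])
    g = np.array(["A", "B", "B"])
    per_group, _ = scoring_ranking_powers(y, p, g)
    assert "A" not in per_group


def _preds(means, stds):
    return [
        PredictionWithUncertainty(m, s, np.array([m])) for m, s in zip(means, stds)
    ]


def test_uncertainty_sweep_edges_and_monotonicity():
    y = np.array([5.0, 6.0, 7.0])
    preds = _preds([5.1, 6.5, 8.0], [0.1, 0.3, 0.9])
    curve = uncertainty_sweep(preds, y, [0.05, 0.1, 0.3, 1.0])
    assert curve[0].mae is None and curve[0].n == 0  # below the lowest std
    assert curve[-1].n == 3
    assert curve[-1].mae == pytest.approx(np.mean([0.1, 0.5, 1.0]))
    sizes = [pt.n for pt in curve]
    assert sizes == sorted(sizes)
    with pytest.raises(ValueError):
        uncertainty_sweep(preds, y, [1.0, 0.5])


def test_attention_coefficients_average_heads_and_atoms():
    attn = np.zeros((2, 3, 4))
    attn[:, :, 1] = 1.0
    coefs = residue_attention_coefficients(attn)
    assert np.array_equal(coefs, [0, 1, 0, 0])


def test_pocket_enrichment_concentrated_and_forced_cases():
    L, pocket = 20, list(range(5, 10))
    attn = np.full((2, 3, L), 1e-9)
    attn[:, :, pocket] = 0.2
    reports = pocket_enrichment({"T": [attn]}, {"T": pocket})
    (rep,) = reports
    assert rep.hits == len(pocket)
    assert rep.ef == pytest.approx(L / len(pocket))
    assert rep.p_value < 0.05 and rep.pocket_mean > rep.nonpocket_mean
    # |pocket| = L-1 with the lone nonpocket residue ranked last -> EF = L/(L-1)
    pocket2 = list(range(L - 1))
    attn2 = np.full((1, 1, L), 1.0)
    attn2[0, 0, L - 1] = 0.0
    (rep2,) = pocket_enrichment({"T": [attn2]}, {"T": pocket2})
    assert rep2.ef == pytest.approx(L / (L - 1))


def test_pocket_enrichment_rejects_degenerate_pockets():
    attn = np.ones((1, 1, 5))
    with pytest.raises(ValueError):
        pocket_enrichment({"T": [attn]}, {"T": []})
    with pytest.raises(ValueError):
        pocket_enrichment({"T": [attn]}, {"T": list(range(5))})
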