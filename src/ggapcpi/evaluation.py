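"""Regression, activity-cliff, virtual-screening, and interpretability metrics.

General performance is RMSE, Pearson correlation (PCC) and Spearman rank
correlation (SRCC); the cliff variants are the same statistics restricted to
AC-labeled compounds.  Virtual screening adds the top-1% enrichment factor
EF = (NTB_top / NTB_total) / fraction, plus per-target scoring (PCC) and
ranking (SRCC) powers.  Ensemble uncertainty is assessed by sweeping an
uncertainty threshold and recomputing subset MAE, and the cross-attention
matrix is tested for enrichment of annotated binding-pocket residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("ggapcpi")


@dataclass(frozen=True)
class MetricReport:
    rmse: float
    pcc: float | None
    srcc: float | None
    n: int
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def _pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    return float((yc * pc).sum() / math.sqrt((yc**2).sum() * (pc**2).sum()))


def regression_metrics(y_true, y_pred) -> MetricReport:
    """RMSE, PCC, and SRCC (average ranks for ties).

    Correlations need n >= 2 and nonzero variance in both vectors; otherwise
    they are reported as undefined with an explicit reason, never silent NaN.
    """
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = y.size
    if n == 0:
        return MetricReport(float("nan"), None, None, 0, "empty input")
    rmse = float(np.sqrt(((p - y) ** 2).mean()))
    if n < 2:
        return MetricReport(rmse, None, None, n, "need at least 2 points for correlations")
    if np.ptp(y) == 0 or np.ptp(p) == 0:
        return MetricReport(rmse, None, None, n, "zero variance")
    pcc = _pearson(y, p)
    srcc = _pearson(stats.rankdata(y), stats.rankdata(p))
    return MetricReport(rmse, pcc, srcc, n)


def cliff_metrics(y_true, y_pred, ac_mask) -> MetricReport:
    """The same metrics computed only on AC-labeled entries."""
    mask = np.asarray(ac_mask, dtype=bool)
    y = np.asarray(y_true, dtype=np.float64)
    if mask.shape != y.shape:
        raise ValueError("ac_mask must align with the value vectors")
    if not mask.any():
        return MetricReport(float("nan"), None, None, 0, "no AC-labeled entries")
    return regression_metrics(y[mask], np.asarray(y_pred, dtype=np.float64)[mask])


@dataclass(frozen=True)
class ScreeningResult:
    ef: float
    ntb_top: int
    ntb_total: int
    fraction: float
    n: int


def enrichment_factor(scores, binder_labels, fraction: float = 0.01) -> ScreeningResult:
    """Enrichment factor among the top-ranked fraction of candidates.

    Candidates are ranked by descending score; the top set has ceil(fraction*n)
    members with ties broken by stable input order.  EF = (NTB_top/NTB_total)
    divided by the fraction, so 1 is chance and 1/fraction is perfect.
    """
    s = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(binder_labels, dtype=bool)
    if s.shape != labels.shape:
        raise ValueError("scores and binder labels must align")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ntb_total = int(labels.sum())
    if ntb_total == 0:
        raise ValueError("no true binders in the candidate set")
    n = s.size
    k = math.ceil(fraction * n)
    top = np.argsort(-s, kind="stable")[:k]
    ntb_top = int(labels[top].sum())
    return ScreeningResult(
        ef=(ntb_top / ntb_total) / fraction,
        ntb_top=ntb_top,
        ntb_total=ntb_total,
        fraction=fraction,
        n=n,
    )


def scoring_ranking_powers(
    y_true, y_pred, grouping
) -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    """Per-target scoring (PCC) and ranking (SRCC) powers.

    Groups with fewer than two points or zero variance are excluded with a
    warning.  Returns the per-group table and the unweighted means.
    """
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    g = np.asarray(grouping)
    per_group: dict[str, tuple[float, float]] = {}
    for group in sorted(set(g.tolist())):
        mask = g == group
        rep = regression_metrics(y[mask], p[mask])
        if not rep.defined:
            logger.warning("group %s excluded: %s", group, rep.undefined_reason)
            continue
        per_group[str(group)] = (rep.pcc, rep.srcc)
    if not per_group:
        return per_group, (float("nan"), float("nan"))
    pccs, srccs = zip(*per_group.values())
    return per_group, (float(np.mean(pccs)), float(np.mean(srccs)))


@dataclass(frozen=True)
class SweepPoint:
    threshold: float
    mae: float | None
    n: int


def uncertainty_sweep(predictions, y_true, thresholds) -> list[SweepPoint]:
    """Subset MAE after screening by ensemble uncertainty.

    For each threshold t the subset keeps samples with std <= t; empty subsets
    yield an undefined point.  Thresholds must be sorted ascending, so subset
    size is nondecreasing along the curve.
    """
    thr = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(thr) < 0):
        raise ValueError("thresholds must be sorted ascending")
    stds = np.array([p.std for p in predictions])
    means = np.array([p.mean for p in predictions])
    y = np.asarray(y_true, dtype=np.float64)
    out = []
    for t in thr:
        mask = stds <= t
        if not mask.any():
            out.append(SweepPoint(float(t), None, 0))
            continue
        mae = float(np.abs(means[mask] - y[mask]).mean())
        out.append(SweepPoint(float(t), mae, int(mask.sum())))
    return out


@dataclass
class PocketEnrichment:
    target_id: str
    coefficients: np.ndarray   # (L,) mean attention per residue
    top_n: int
    hits: int
    ef: float
    pocket_mean: float
    nonpocket_mean: float
    t_statistic: float
    p_value: float


def residue_attention_coefficients(attention: np.ndarray) -> np.ndarray:
    """Mean over heads and query atoms of a (heads, atoms, residues) tensor."""
    a = np.asarray(attention, dtype=np.float64)
    if a.ndim != 3:
        raise ValueError("attention tensor must be (heads, atoms, residues)")
    return a.mean(axis=(0, 1))


def pocket_enrichment(
    attention_by_target: Mapping[str, Sequence[np.ndarray]],
    pocket_residues: Mapping[str, Sequence[int]],
) -> list[PocketEnrichment]:
    """Attention-based retrieval of annotated pocket residues.

    Per protein: residue coefficients are averaged over all its pairs' attention
    tensors; the top-N residues (N = pocket size, ties broken by residue index)
    are compared with the annotated pocket.  EF = (hits/N) / (pocket/L); pocket
    vs nonpocket coefficients are compared with an unequal-variance two-sample
    t-test.
    """
    reports = []
    for target_id, tensors in attention_by_target.items():
        if target_id not in pocket_residues:
            raise KeyError(f"no pocket annotation for {target_id}")
        coefs = np.mean([residue_attention_coefficients(t) for t in tensors], axis=0)
        L = coefs.size
        pocket = np.asarray(sorted(set(pocket_residues[target_id])), dtype=int)
        if pocket.size == 0 or pocket.size >= L:
            raise ValueError(f"{target_id}: pocket must be a proper nonempty residue subset")
        n_top = pocket.size
        top = np.argsort(-coefs, kind="stable")[:n_top]
        hits = int(np.isin(top, pocket).sum())
        in_pocket = np.zeros(L, dtype=bool)
        in_pocket[pocket] = True
        t_stat, p_val = stats.ttest_ind(coefs[in_pocket], coefs[~in_pocket], equal_var=False)
        reports.append(
            PocketEnrichment(
                target_id=target_id,
                coefficients=coefs,
                top_n=n_top,
                hits=hits,
                ef=(hits / n_top) / (pocket.size / L),
                pocket_mean=float(coefs[in_pocket].mean()),
                nonpocket_mean=float(coefs[~in_pocket].mean()),
                t_statistic=float(t_stat),
                p_value=float(p_val),
            )
        )
    return reports
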