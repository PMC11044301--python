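"""Diagnostic-test statistics for threshold markers.

Implements the statistical machinery used to evaluate a continuous
prognostic marker (here ADC-R(x)) against a binary outcome:

* empirical AUC in its Mann-Whitney pairwise form, with DeLong
  structural-component variance and paired/unpaired DeLong z-tests;
* zero-false-positive-rate cutoffs ("marker > c" with c the maximum
  marker value among good-outcome subjects in the derivation sample);
* confusion-matrix metrics (sensitivity/specificity/PPV/NPV) with exact
  Clopper-Pearson 95% confidence intervals;
* nonparametric group comparisons (Mann-Whitney U, Kruskal-Wallis with
  Bonferroni-corrected pairwise post hoc) and categorical tests
  (Yates-corrected chi-square or Fisher's exact);
* the conventional AUC performance bands (poor/fair/good/excellent).

Positive class throughout is the *poor* neurological outcome; the marker
is oriented so larger values indicate a worse prognosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ROCAnalysis",
    "ZeroFPRCutoff",
    "ConfusionCounts",
    "DiagnosticPerformance",
    "DeLongResult",
    "empirical_auc",
    "delong_variance",
    "delong_covariance",
    "delong_test",
    "auc_ci",
    "roc_analysis",
    "zero_fpr_cutoff",
    "confusion_at_rule",
    "clopper_pearson",
    "diagnostic_metrics",
    "mann_whitney",
    "kruskal_wallis_with_posthoc",
    "categorical_tests",
    "auc_band",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class ROCAnalysis:
    """Empirical ROC summary: AUC, DeLong variance, Wald 95% CI, curve points."""

    auc: float
    auc_ci: tuple[float, float]
    variance: float
    curve: tuple[tuple[float, float], ...]  # (fpr, tpr) pairs


@dataclass(frozen=True)
class ZeroFPRCutoff:
    """A 100%-specificity rule derived on one sample.

    ``rule`` is the strict inequality "marker > cutoff_value"; by
    construction no good-outcome subject of the derivation sample is
    rule-positive, so the false-positive rate there is exactly 0.
    """

    threshold_x: float
    cutoff_value: float
    derivation_sensitivity: float

    @property
    def rule(self) -> str:
        return f"marker > {self.cutoff_value:g}"

    def predict(self, values: np.ndarray | Sequence[float]) -> np.ndarray:
        return np.asarray(values, dtype=float) > self.cutoff_value


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity/specificity/PPV/NPV in percent with exact 95% CIs.

    A metric whose denominator is zero is reported as NaN (not
    available), never as 0; its CI is (nan, nan).
    """

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    design: Literal["paired", "unpaired"]


# ---------------------------------------------------------------------------
# AUC and DeLong machinery


def _kernel_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Mann-Whitney kernel psi(pos_i, neg_j): 1 if pos>neg, 0.5 if tied, 0 else."""
    diff = pos[:, None] - neg[None, :]
    return np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))


def _as_groups(pos_values, neg_values) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos_values, dtype=float).ravel()
    neg = np.asarray(neg_values, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome groups must be non-empty")
    return pos, neg


def empirical_auc(pos_values, neg_values) -> float:
    """Empirical AUC as the mean Mann-Whitney kernel over all (pos, neg) pairs.

    Equals the trapezoidal area under the empirical ROC curve; ties
    contribute 1/2.
    """
    pos, neg = _as_groups(pos_values, neg_values)
    return float(_kernel_matrix(pos, neg).mean())


def _structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = _kernel_matrix(pos, neg)
    return k.mean(axis=1), k.mean(axis=0)  # V10 (per positive), V01 (per negative)


def delong_variance(pos_values, neg_values) -> float:
    """DeLong variance of the empirical AUC from structural components.

    var = S10/m + S01/n with S10, S01 the sample variances (n-1
    denominator) of the per-positive and per-negative components.
    """
    pos, neg = _as_groups(pos_values, neg_values)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong variance requires at least 2 subjects per group")
    v10, v01 = _structural_components(pos, neg)
    return float(v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size)


def delong_covariance(pos_a, neg_a, pos_b, neg_b) -> float:
    """DeLong covariance of two AUCs measured on the same subjects.

    The two markers must be aligned: pos_a[i] and pos_b[i] belong to the
    same (poor-outcome) subject, likewise the negatives.
    """
    pa, na = _as_groups(pos_a, neg_a)
    pb, nb = _as_groups(pos_b, neg_b)
    if pa.size != pb.size or na.size != nb.size:
        raise ValueError("paired markers must share subjects (group sizes differ)")
    if pa.size < 2 or na.size < 2:
        raise ValueError("DeLong covariance requires at least 2 subjects per group")
    v10a, v01a = _structural_components(pa, na)
    v10b, v01b = _structural_components(pb, nb)
    s10 = np.cov(v10a, v10b, ddof=1)[0, 1]
    s01 = np.cov(v01a, v01b, ddof=1)[0, 1]
    return float(s10 / pa.size + s01 / na.size)


def delong_test(
    marker_a,
    marker_b,
    labels,
    design: Literal["paired", "unpaired"] = "paired",
    labels_b=None,
) -> DeLongResult:
    """Two-sided DeLong z-test comparing two empirical AUCs.

    Paired: ``marker_a`` and ``marker_b`` are two markers on the same
    subjects, ``labels`` the shared binary outcome (truthy = positive
    class); the covariance of the AUCs is estimated from shared
    structural components.  Unpaired: two independent samples, with
    ``labels`` for marker_a and ``labels_b`` for marker_b, and the
    variances simply add.
    """
    la = np.asarray(labels).astype(bool).ravel()
    a = np.asarray(marker_a, dtype=float).ravel()
    if design == "paired":
        b = np.asarray(marker_b, dtype=float).ravel()
        if not (a.size == b.size == la.size):
            raise ValueError("paired design requires markers and labels of equal length")
        pos_a, neg_a = a[la], a[~la]
        pos_b, neg_b = b[la], b[~la]
        auc_a = empirical_auc(pos_a, neg_a)
        auc_b = empirical_auc(pos_b, neg_b)
        var = (
            delong_variance(pos_a, neg_a)
            + delong_variance(pos_b, neg_b)
            - 2.0 * delong_covariance(pos_a, neg_a, pos_b, neg_b)
        )
    elif design == "unpaired":
        if labels_b is None:
            raise ValueError("unpaired design requires labels_b for the second sample")
        lb = np.asarray(labels_b).astype(bool).ravel()
        b = np.asarray(marker_b, dtype=float).ravel()
        if a.size != la.size or b.size != lb.size:
            raise ValueError("markers and labels must have equal length within each sample")
        pos_a, neg_a = a[la], a[~la]
        pos_b, neg_b = b[lb], b[~lb]
        auc_a = empirical_auc(pos_a, neg_a)
        auc_b = empirical_auc(pos_b, neg_b)
        var = delong_variance(pos_a, neg_a) + delong_variance(pos_b, neg_b)
    else:
        raise ValueError(f"unknown design {design!r}")

    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return DeLongResult(auc_a=auc_a, auc_b=auc_b, z=0.0, p=1.0, design=design)
        raise ValueError("degenerate variance: zero variance with non-zero AUC difference")
    z = diff / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p=float(min(p, 1.0)), design=design)


def auc_ci(auc: float, variance: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation (Wald) CI for an AUC, clipped to [0, 1]."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    half = zcrit * math.sqrt(variance)
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_analysis(pos_values, neg_values) -> ROCAnalysis:
    """Full empirical ROC summary for one marker and one binary outcome."""
    pos, neg = _as_groups(pos_values, neg_values)
    auc = empirical_auc(pos, neg)
    var = delong_variance(pos, neg) if (pos.size >= 2 and neg.size >= 2) else 0.0
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return ROCAnalysis(
        auc=auc,
        auc_ci=auc_ci(auc, var),
        variance=var,
        curve=tuple(zip(fpr.tolist(), tpr.tolist())),
    )


# ---------------------------------------------------------------------------
# cutoffs and confusion-matrix metrics


def zero_fpr_cutoff(good_values, poor_values, threshold_x: float = float("nan")) -> ZeroFPRCutoff:
    """Derive the 100%-specificity rule "marker > max(good_values)".

    A poor-outcome subject whose marker exactly equals the maximum
    good-outcome value is rule-negative (the inequality is strict), so
    ties count against sensitivity.
    """
    good, poor = _as_groups(good_values, poor_values)
    cutoff = float(good.max())
    sens = float(np.mean(poor > cutoff))
    return ZeroFPRCutoff(
        threshold_x=threshold_x, cutoff_value=cutoff, derivation_sensitivity=sens
    )


def confusion_at_rule(values, outcomes, cutoff: float) -> ConfusionCounts:
    """Confusion counts for the rule "marker > cutoff".

    ``outcomes`` is truthy for the positive (poor-outcome) class.
    """
    v = np.asarray(values, dtype=float).ravel()
    y = np.asarray(outcomes).astype(bool).ravel()
    if v.size != y.size:
        raise ValueError("values and outcomes must have equal length")
    pred = v > cutoff
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & y)),
        fp=int(np.count_nonzero(pred & ~y)),
        fn=int(np.count_nonzero(~pred & y)),
        tn=int(np.count_nonzero(~pred & ~y)),
    )


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI as proportions in [0, 1].

    At successes = n the lower bound is (alpha/2)^(1/n); at 0 successes
    the lower bound is exactly 0 (and symmetrically for the upper).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="beta")
    return (float(lo), float(hi))


def _metric(successes: int, denom: int) -> tuple[float, tuple[float, float]]:
    if denom == 0:
        return math.nan, (math.nan, math.nan)
    lo, hi = clopper_pearson(successes, denom)
    return 100.0 * successes / denom, (100.0 * lo, 100.0 * hi)


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticPerformance:
    """Sensitivity/specificity/PPV/NPV (percent) with exact 95% CIs."""
    sens, sens_ci = _metric(counts.tp, counts.tp + counts.fn)
    spec, spec_ci = _metric(counts.tn, counts.tn + counts.fp)
    ppv, ppv_ci = _metric(counts.tp, counts.tp + counts.fp)
    npv, npv_ci = _metric(counts.tn, counts.tn + counts.fn)
    return DiagnosticPerformance(
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        ppv=ppv,
        ppv_ci=ppv_ci,
        npv=npv,
        npv_ci=npv_ci,
    )


# ---------------------------------------------------------------------------
# nonparametric and categorical group comparisons


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    Exact enumeration is used for small samples (n <= 8 per group, no
    ties), matching common practice.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size <= 8 and b.size <= 8 and np.unique(np.concatenate([a, b])).size == a.size + b.size) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)))


@dataclass(frozen=True)
class PairwiseComparison:
    groups: tuple[int, int]
    u: float
    p: float
    significant: bool


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    p: float
    bonferroni_alpha: float
    pairwise: tuple[PairwiseComparison, ...]


def kruskal_wallis_with_posthoc(groups: Sequence, alpha: float = 0.05) -> KruskalWallisResult:
    """Kruskal-Wallis H (tie-corrected, df=2) across three groups with
    pairwise Mann-Whitney post hoc at the Bonferroni level alpha/3."""
    if len(groups) != 3:
        raise ValueError("exactly 3 groups required")
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("all groups must be non-empty")
    try:
        with np.errstate(invalid="ignore"):
            res = sps.kruskal(*arrs)
        h, p = float(res.statistic), float(res.pvalue)
    except ValueError:
        h, p = math.nan, math.nan
    if math.isnan(h):
        # all values identical across every group: no evidence of difference
        h, p = 0.0, 1.0
    bonf = alpha / 3.0
    pairs = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        mw = mann_whitney(arrs[i], arrs[j])
        pairs.append(
            PairwiseComparison(groups=(i, j), u=mw.u, p=mw.p, significant=mw.p < bonf)
        )
    return KruskalWallisResult(h=h, p=p, bonferroni_alpha=bonf, pairwise=tuple(pairs))


@dataclass(frozen=True)
class CategoricalTestResult:
    method: Literal["chi2", "fisher"]
    statistic: float
    p: float


def categorical_tests(table) -> CategoricalTestResult:
    """Chi-square (Yates-corrected for 2x2) or Fisher's exact on a 2xk table.

    A 2x2 table with any expected cell count < 5 is tested with Fisher's
    exact (hypergeometric) test; otherwise chi-square is used, with
    continuity correction only in the 2x2 case.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate margins: zero row or column total")
    is_2x2 = t.shape == (2, 2)
    expected = sps.contingency.expected_freq(t)
    if is_2x2 and np.any(expected < 5):
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return CategoricalTestResult(method="fisher", statistic=math.nan, p=float(p))
    chi2, p, _, _ = sps.chi2_contingency(t, correction=is_2x2)
    return CategoricalTestResult(method="chi2", statistic=float(chi2), p=float(p))


# ---------------------------------------------------------------------------
# AUC performance bands


def auc_band(auc: float) -> str:
    """Map an AUC to the conventional performance label.

    0.50-0.69 poor, 0.70-0.79 fair, 0.80-0.89 good, 0.90-1.00 excellent;
    values below 0.50 are labelled "worse than chance".
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc < 0.5:
        return "worse than chance"
    if auc < 0.7:
        return "poor"
    if auc < 0.8:
        return "fair"
    if auc < 0.9:
        return "good"
    return "excellent"
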