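"""Method-agreement statistics for ordinal risk categories and paired scores.

Two calcium-scoring methods applied to the same patients yield a k x k
confusion matrix of risk categories (rows = test method, columns = reference
method). Agreement is summarised by:

* **linear-weighted Cohen kappa** — chance-corrected agreement with weights
  ``w_ij = 1 - |i - j| / (k - 1)``, so near-miss classifications earn partial
  credit. The standard error uses the asymptotic variance of the weighted
  kappa (Fleiss, Cohen & Everitt), with the 95% CI as ``kappa +/- 1.96 SE``;
  a multinomial bootstrap is available as a cross-check.
* **concordance percentages** — % of cases in the same category, within one
  category, and incorrectly assigned to category 0 (a false zero score).
* **detection metrics** — sensitivity/specificity/PPV/NPV of calcium
  detection after binarising both axes at category >= 1.
* **paired-score summaries** — median difference with IQR and an exact
  binomial CI of the median, Spearman correlation, the Wilcoxon signed-rank
  test, and classical Bland-Altman limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .risk import CATEGORY_LABELS

__all__ = [
    "KappaEstimate",
    "DetectionMetrics",
    "PairedScoreSummary",
    "linear_weights",
    "weighted_kappa",
    "bootstrap_kappa_ci",
    "percent_same_category",
    "percent_within_one",
    "percent_false_zero",
    "detection_metrics",
    "paired_summary",
    "load_category_table",
    "save_category_table",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, matching printed report precision."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _as_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    if t.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    return t


def linear_weights(k: int) -> np.ndarray:
    """Agreement weights ``w_ij = 1 - |i - j| / (k - 1)`` for k categories."""
    if k < 2:
        raise ValueError("need at least two categories")
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def quadratic_weights(k: int) -> np.ndarray:
    """Optional quadratic scheme ``1 - (|i - j| / (k - 1))^2``."""
    if k < 2:
        raise ValueError("need at least two categories")
    idx = np.arange(k)
    return 1.0 - (np.abs(idx[:, None] - idx[None, :]) / (k - 1)) ** 2


@dataclass(frozen=True)
class KappaEstimate:
    """Weighted kappa with asymptotic standard error and 95% CI."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    weighting: str = "linear"

    def strength(self) -> str:
        """Conventional verbal band for the point estimate."""
        k = self.kappa
        for hi, name in [(0.2, "slight"), (0.4, "fair"), (0.6, "moderate"),
                         (0.8, "substantial"), (1.0, "excellent")]:
            if k <= hi:
                return name if k > 0 else "poor"
        return "excellent"


def weighted_kappa(table: np.ndarray, weighting: str = "linear") -> KappaEstimate:
    """Cohen's weighted kappa of a test-vs-reference confusion matrix.

    ``kappa = (P_o - P_e) / (1 - P_e)`` with observed and chance-expected
    weighted agreement computed from joint and marginal proportions. The
    variance follows the asymptotic formula of Fleiss, Cohen & Everitt.
    """
    t = _as_table(table)
    k = t.shape[0]
    w = {"linear": linear_weights, "quadratic": quadratic_weights}[weighting](k)
    n = t.sum()
    p = t / n
    r = p.sum(axis=1)  # test-method marginals (rows)
    c = p.sum(axis=0)  # reference marginals (columns)
    po = float((p * w).sum())
    pe = float((r[:, None] * c[None, :] * w).sum())
    if abs(1.0 - pe) < 1e-12:
        raise ValueError(
            "chance-expected agreement is 1 (degenerate marginals: fewer than "
            "two categories in use); weighted kappa is undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    w_row = (w * c[None, :]).sum(axis=1)  # expected weight given test category i
    w_col = (w * r[:, None]).sum(axis=0)  # expected weight given reference category j
    term = (w - (w_row[:, None] + w_col[None, :]) * (1.0 - kappa)) ** 2
    var = (float((p * term).sum()) - (kappa - pe * (1.0 - kappa)) ** 2) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    return KappaEstimate(kappa, se, kappa - 1.96 * se, kappa + 1.96 * se, weighting)


def bootstrap_kappa_ci(
    table: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    weighting: str = "linear",
) -> tuple[float, float]:
    """Percentile CI of the weighted kappa under multinomial resampling."""
    t = _as_table(table)
    n = int(t.sum())
    probs = (t / n).ravel()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_boot)
    kappas = []
    for d in draws:
        try:
            kappas.append(weighted_kappa(d.reshape(t.shape), weighting).kappa)
        except ValueError:  # degenerate replicate
            continue
    lo, hi = np.quantile(kappas, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def percent_same_category(table: np.ndarray) -> float:
    """Percent of cases the two methods place in the same category."""
    t = _as_table(table)
    return 100.0 * float(np.trace(t)) / float(t.sum())


def percent_within_one(table: np.ndarray) -> float:
    """Percent of cases within one category of the reference."""
    t = _as_table(table)
    k = t.shape[0]
    idx = np.arange(k)
    near = np.abs(idx[:, None] - idx[None, :]) <= 1
    return 100.0 * float(t[near].sum()) / float(t.sum())


def percent_false_zero(table: np.ndarray) -> float:
    """Percent of reference-positive cases the test method calls category 0."""
    t = _as_table(table)
    return 100.0 * float(t[0].sum() - t[0, 0]) / float(t.sum())


@dataclass(frozen=True)
class DetectionMetrics:
    """Binary calcium-detection performance against the reference."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()


def detection_metrics(table: np.ndarray) -> DetectionMetrics:
    """Sensitivity/specificity/PPV/NPV after binarising at category >= 1.

    A metric with a zero denominator is reported as NaN and named in
    ``undefined`` rather than silently coerced to 0.
    """
    t = _as_table(table)
    tn = float(t[0, 0])
    fn = float(t[0, 1:].sum())
    fp = float(t[1:, 0].sum())
    tp = float(t[1:, 1:].sum())
    metrics = {}
    undefined = []
    for name, num, den in [
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ]:
        if den == 0:
            metrics[name] = float("nan")
            undefined.append(name)
        else:
            metrics[name] = 100.0 * num / den
    return DetectionMetrics(int(tp), int(fp), int(fn), int(tn),
                            undefined=tuple(undefined), **metrics)


@dataclass(frozen=True)
class PairedScoreSummary:
    """Difference summary of two score lists measured on the same subjects."""

    median_diff: float
    iqr: tuple[float, float]
    median_ci: tuple[float, float]
    spearman_rho: float
    spearman_p: float
    wilcoxon_p: float
    n: int
    degenerate: bool  # all differences zero: rank tests undefined
    mean_diff: float
    loa: tuple[float, float]  # classical Bland-Altman mean +/- 1.96 sd


def _median_ci_exact(sorted_d: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Distribution-free CI of the median from binomial order statistics."""
    n = len(sorted_d)
    # largest l with P(X < l) <= alpha/2 for X ~ Bin(n, 1/2)
    l = int(stats.binom.ppf(alpha / 2, n, 0.5))
    while l > 0 and stats.binom.cdf(l - 1, n, 0.5) > alpha / 2:
        l -= 1
    u = n - 1 - l
    if l > u:
        return float(sorted_d[0]), float(sorted_d[-1])
    return float(sorted_d[l]), float(sorted_d[u])


def paired_summary(a: np.ndarray, b: np.ndarray) -> PairedScoreSummary:
    """Summarise paired differences ``a - b`` (e.g. test minus reference).

    Quartiles use linear interpolation; the median CI is the exact binomial
    order-statistic interval; Spearman uses average ranks for ties; the
    Wilcoxon signed-rank test drops zero differences and uses the exact null
    for n <= 25, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score lists must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    ci = _median_ci_exact(np.sort(d))
    rho, rho_p = stats.spearmanr(a, b)
    nz = d[d != 0]
    degenerate = len(nz) == 0
    if degenerate:
        wp = float("nan")
    else:
        method = "exact" if len(nz) <= 25 else "approx"
        wp = float(stats.wilcoxon(nz, method=method).pvalue)
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    return PairedScoreSummary(
        median_diff=float(med),
        iqr=(float(q1), float(q3)),
        median_ci=ci,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        wilcoxon_p=wp,
        n=len(a),
        degenerate=degenerate,
        mean_diff=mean,
        loa=(mean - 1.96 * sd, mean + 1.96 * sd),
    )


# ---------------------------------------------------------------------------
# Confusion-matrix CSV I/O
# ---------------------------------------------------------------------------


def save_category_table(table: np.ndarray, path: str | Path) -> Path:
    """Write a k x k count matrix as CSV (rows = test, columns = reference)."""
    t = _as_table(table).astype(int)
    k = t.shape[0]
    labels = CATEGORY_LABELS[:k] if k <= len(CATEGORY_LABELS) else [str(i) for i in range(k)]
    pd.DataFrame(t, index=labels, columns=labels).to_csv(path, index_label="category")
    return Path(path)


def load_category_table(path: str | Path) -> np.ndarray:
    """Read a confusion-matrix CSV, validating integer non-negative counts."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    for (i, j), v in np.ndenumerate(values):
        fv = float(v)
        if fv < 0 or fv != int(fv):
            raise ValueError(
                f"invalid count {v} at row {df.index[i]}, column {df.columns[j]} "
                f"of {path}: counts must be non-negative integers"
            )
    return _as_table(values.astype(float)).astype(int)
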