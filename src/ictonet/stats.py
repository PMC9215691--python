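"""Group-level statistics: rank-sum tests, Holm correction, bootstrap effect
sizes, ROC metrics, and the supplementary spectral/connectivity measures.

Rank-sum conventions
--------------------
The test statistic reported as "U" throughout is the rank sum W of group 1
(mid-ranks under ties), not the classical Mann-Whitney U = W - n1(n1+1)/2:
only the rank-sum reading is consistent with printed values exceeding
n1*n2.  The normal approximation uses a 0.5 continuity correction: for the
right tail z = (W - mu - 0.5)/sigma; two-sided, |W - mu| is shrunk by 0.5
before dividing.  mu = n1(n1+n2+1)/2 and sigma includes the usual tie
correction.  These conventions reproduce MATLAB's ``ranksum`` output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .networks import FunctionalNetwork
from .segment import EEGSegment

__all__ = [
    "StatTestResult",
    "EffectSizeCI",
    "RocResult",
    "ranksum",
    "ranksum_from_summary",
    "holm",
    "bootstrap_median_diff",
    "roc_metrics",
    "relative_band_power",
    "node_strength",
]


@dataclass
class StatTestResult:
    """Rank-sum test summary (W, U, z, p; corrected p filled in by callers)."""

    W: float
    U_mw: float
    z: float
    p: float
    n1: int
    n2: int
    tail: str
    p_corrected: float | None = None


@dataclass
class EffectSizeCI:
    """Unpaired median difference with bootstrap 95% CI."""

    median_diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    method: str = "BCa"


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    sensitivity: float
    specificity: float
    threshold: float


# ----------------------------------------------------------------------
# rank-sum machinery
# ----------------------------------------------------------------------
def _z_and_p(w: float, mu: float, sigma: float, tail: str) -> tuple[float, float]:
    if sigma == 0:
        raise ValueError("zero rank-sum variance (all values tied)")
    if tail == "right":
        z = (w - mu - 0.5) / sigma
        p = float(_stats.norm.sf(z))
    elif tail == "two-sided":
        diff = w - mu
        z = (diff - 0.5 * np.sign(diff)) / sigma
        p = float(2.0 * _stats.norm.sf(abs(z)))
    else:
        raise ValueError("tail must be 'right' or 'two-sided'")
    return float(z), min(p, 1.0)


#: largest tie-free sample total for which ``method='auto'`` enumerates the
#: exact null distribution instead of using the normal approximation
_EXACT_LIMIT = 15


def ranksum(x, y, tail: str = "right", method: str = "auto") -> StatTestResult:
    """Mann-Whitney/Wilcoxon rank-sum test of group ``x`` vs group ``y``.

    ``tail='right'`` tests whether x tends to exceed y.  Uses mid-ranks for
    ties, tie-corrected variance, and continuity correction (see module
    docstring for the exact conventions).  ``method='auto'`` switches to the
    exact enumerated null distribution for small tie-free samples, where the
    normal approximation is coarse; ``'normal'`` / ``'exact'`` force one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = _stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z, p = _z_and_p(w, mu, math.sqrt(sigma2), tail)
    tie_free = counts.size == n
    if method == "exact" or (method == "auto" and tie_free and n <= _EXACT_LIMIT):
        p = ranksum_exact_p(x, y, tail=tail)
    elif method not in ("auto", "normal"):
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    return StatTestResult(
        W=w, U_mw=w - n1 * (n1 + 1) / 2.0, z=z, p=p, n1=n1, n2=n2, tail=tail
    )


def ranksum_from_summary(
    w: float, n1: int, n2: int, tail: str = "right"
) -> tuple[float, float]:
    """(z, p) recomputed from a published rank sum W and group sizes.

    Assumes no ties (raw data unavailable); W must lie in the feasible range
    [n1(n1+1)/2, n1(n1+2*n2+1)/2].
    """
    w_min = n1 * (n1 + 1) / 2.0
    w_max = n1 * (n1 + 2 * n2 + 1) / 2.0
    if not (w_min <= w <= w_max):
        raise ValueError(
            f"W={w} outside feasible range [{w_min}, {w_max}] for "
            f"n1={n1}, n2={n2}"
        )
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return _z_and_p(w, mu, sigma, tail)


def ranksum_exact_p(x, y, tail: str = "right") -> float:
    """Exact rank-sum p-value by full enumeration of the null distribution.

    Valid for tie-free samples; O(n1*n2*W) dynamic program over the number
    of subsets of {1..n} of size n1 with a given rank sum.  Serves as the
    small-sample oracle for the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    if np.unique(combined).size != n:
        raise ValueError("exact enumeration requires tie-free data")
    ranks = _stats.rankdata(combined)
    w_obs = int(round(ranks[:n1].sum()))
    dist = _ranksum_null_distribution(n1, n2)
    total = math.comb(n, n1)
    if tail == "right":
        p = sum(c for w, c in dist.items() if w >= w_obs) / total
    elif tail == "two-sided":
        mu = n1 * (n + 1) / 2.0
        d = abs(w_obs - mu)
        p = sum(c for w, c in dist.items() if abs(w - mu) >= d) / total
    else:
        raise ValueError("tail must be 'right' or 'two-sided'")
    return float(min(p, 1.0))


def _ranksum_null_distribution(n1: int, n2: int) -> dict[int, int]:
    """Counts of subsets of ranks {1..n1+n2} of size n1 by rank sum."""
    n = n1 + n2
    # dp[k][s] = number of k-subsets of the first r ranks with sum s
    dp = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            for s, c in list(dp[k - 1].items()):
                dp[k][s + r] = dp[k].get(s + r, 0) + c
    return dp[n1]


def holm(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down corrected p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


# ----------------------------------------------------------------------
# effect sizes and classification metrics
# ----------------------------------------------------------------------
def bootstrap_median_diff(
    x, y, n_boot: int = 5000, seed: int = 0
) -> EffectSizeCI:
    """Unpaired median difference median(x) - median(y) with BCa 95% CI.

    Falls back to the percentile interval (with a warning) when the BCa
    correction is degenerate (e.g. all-equal samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")

    def stat(a, b, axis=-1):
        return np.median(a, axis=axis) - np.median(b, axis=axis)

    diff = float(stat(x, y))
    method = "BCa"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _stats.bootstrap(
                (x, y), stat, n_resamples=n_boot, confidence_level=0.95,
                method="BCa", rng=np.random.default_rng(seed), vectorized=True,
            )
        lo, hi = float(res.confidence_interval.low), float(
            res.confidence_interval.high
        )
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("degenerate BCa interval")
    except Exception:
        warnings.warn(
            "BCa interval degenerate; falling back to percentile bootstrap",
            stacklevel=2,
        )
        method = "percentile"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _stats.bootstrap(
                (x, y), stat, n_resamples=n_boot, confidence_level=0.95,
                method="percentile", rng=np.random.default_rng(seed),
                vectorized=True,
            )
        lo, hi = float(res.confidence_interval.low), float(
            res.confidence_interval.high
        )
    return EffectSizeCI(
        median_diff=diff, ci_low=lo, ci_high=hi, n_boot=n_boot, method=method
    )


def roc_metrics(scores, labels) -> RocResult:
    """ROC curve, AUC, and sensitivity/specificity at the Youden-J threshold.

    AUC is computed through the Mann-Whitney identity AUC = U / (n1 * n2)
    with U the Mann-Whitney statistic of the positive-class scores (mid-rank
    tie handling gives the standard tie-averaged AUC).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    res = ranksum(pos, neg, tail="right")
    auc = res.U_mw / (pos.size * neg.size)

    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(labels.astype(int), scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        auc=float(auc),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
    )


# ----------------------------------------------------------------------
# supplementary measures
# ----------------------------------------------------------------------
def relative_band_power(
    seg: EEGSegment,
    band: tuple[float, float],
    channel: str,
    total_band: tuple[float, float] = (1.0, 45.0),
) -> float:
    """Welch relative power of ``band`` within ``total_band`` for one channel.

    Intended for broadband (unfiltered) re-referenced segments.  Welch PSD
    with 2 s Hann windows at 50% overlap; band powers are trapezoidal
    integrals of the PSD over the (inclusive) frequency ranges.
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band edges must satisfy 0 < low < high")
    if hi > seg.fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist ({seg.fs / 2} Hz)")
    x = seg.data[seg.channel_index(channel)]
    nperseg = min(int(round(2.0 * seg.fs)), x.size)
    freqs, psd = _signal.welch(
        x, fs=seg.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )

    def band_power(f_lo: float, f_hi: float) -> float:
        m = (freqs >= f_lo) & (freqs <= f_hi)
        if m.sum() < 2:
            return float(psd[m].sum())
        return float(np.trapezoid(psd[m], freqs[m]))

    total = band_power(*total_band)
    if total == 0:
        return 0.0
    return min(band_power(lo, hi) / total, 1.0)


def node_strength(net: FunctionalNetwork, channel: str) -> float:
    """Connection strength of one electrode: in-strength + out-strength,
    i.e. twice the row sum of the symmetric PLV weight matrix."""
    i = net.node_index(channel)
    return float(2.0 * net.weights[i].sum())
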