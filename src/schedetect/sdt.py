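"""Signal-detection metrics and exact nonparametric tests.

Yes/no detection outcomes are summarized by the discriminability index
d' = z(H) - z(F) and the criterion c = -(z(H) + z(F))/2, where H is the hit
rate, F the false-alarm rate and z the inverse standard-normal CDF
(Stanislaw & Todorov conventions).  Perfect proportions are replaced by the
1/(2n) rule before the z-transform so both statistics stay finite.  For
single-class test sets, sensitivity is recovered from proportion correct in
a two-alternative forced-choice (2AFC) framing, d' = sqrt(2) * z(p).

Group comparisons use an exact one-sample Wilcoxon signed-rank test (full
null distribution, average ranks for ties) and a tie-corrected Friedman
rank test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "SDTMetrics",
    "StatTestResult",
    "rates",
    "correct_extreme",
    "dprime_yesno",
    "dprime_2afc",
    "wilcoxon_one_sample",
    "bonferroni_threshold",
    "bonferroni_flags",
    "friedman",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for a yes/no detection task.

    Signal trials split into hits (tp) and misses (fn); noise trials into
    correct rejections (tn) and false alarms (fp).
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_signal(self) -> int:
        return self.tp + self.fn

    @property
    def n_noise(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class SDTMetrics:
    sensitivity: float
    specificity: float
    d_prime: float
    criterion: float


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    alpha_corrected: float | None = None


def rates(confusion: ConfusionCounts) -> tuple[float, float]:
    """Hit rate (sensitivity) and correct-rejection rate (specificity)."""
    if confusion.n_signal == 0:
        raise ValueError("no signal trials: sensitivity undefined")
    if confusion.n_noise == 0:
        raise ValueError("no noise trials: specificity undefined")
    return confusion.tp / confusion.n_signal, confusion.tn / confusion.n_noise


def correct_extreme(p: float, n: int) -> float:
    """Replace proportions of 0 and 1 by 1/(2n) and 1 - 1/(2n).

    Keeps the inverse-normal transform finite for perfect scores; proportions
    strictly inside (0, 1) pass through unchanged.
    """
    if n <= 0:
        raise ValueError("trial count must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion out of range: {p}")
    if p == 0.0:
        return 1.0 / (2 * n)
    if p == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p


def dprime_yesno(
    sensitivity: float, specificity: float, n_signal: int, n_noise: int
) -> tuple[float, float]:
    """Yes/no d' and criterion c from hit and correct-rejection rates.

    H and F are extreme-corrected with the trial counts of their own class;
    then d' = z(H) - z(F) and c = -(z(H) + z(F))/2.
    """
    h = correct_extreme(sensitivity, n_signal)
    f = correct_extreme(1.0 - specificity, n_noise)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return zh - zf, -(zh + zf) / 2.0


def sdt_metrics(confusion: ConfusionCounts) -> SDTMetrics:
    """Full yes/no metric set from confusion counts."""
    sens, spec = rates(confusion)
    d, c = dprime_yesno(sens, spec, confusion.n_signal, confusion.n_noise)
    return SDTMetrics(sensitivity=sens, specificity=spec, d_prime=d, criterion=c)


def dprime_2afc(accuracy: float, n: int) -> float:
    """2AFC d' from proportion correct: sqrt(2) * z(accuracy).

    The continuous closed form underlying the published 2AFC lookup tables;
    extreme proportions are clamped by the same 1/(2n) rule, so perfect
    accuracy maps to a finite value.  Chance (0.5) maps to 0 and the function
    is odd around chance.
    """
    if n <= 0:
        raise ValueError("trial count must be positive")
    return math.sqrt(2.0) * float(stats.norm.ppf(correct_extreme(accuracy, n)))


def _signed_rank_setup(values: np.ndarray, mu0: float) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero differences and return (signs, average ranks of |d|)."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    return np.sign(d), ranks


def _exact_signed_rank_p(signs: np.ndarray, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank sum via dynamic programming.

    Works on doubled ranks (integers even with midranks) and convolves the
    null distribution of the positive-rank sum T+ over all 2^n equally likely
    sign assignments.  p = min(1, 2 * min(P(T+ <= t), P(T+ >= t))).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    t_obs = int(np.rint(2 * np.sum(ranks[signs > 0])))
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled T+ equal to s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    lower = counts[: t_obs + 1].sum()
    upper = counts[t_obs:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_one_sample(
    values, mu0: float = 0.0, alpha_corrected: float | None = None
) -> StatTestResult:
    """Exact two-sided one-sample Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention); tied magnitudes get
    average ranks.  The reported statistic W is the rank sum of the less
    frequent sign, and the p-value comes from the full 2^n null distribution
    of sign assignments (computed by convolution, exact also under ties).
    """
    signs, ranks = _signed_rank_setup(np.asarray(values, dtype=float), mu0)
    w_pos = float(np.sum(ranks[signs > 0]))
    w_neg = float(np.sum(ranks[signs < 0]))
    p = _exact_signed_rank_p(signs, ranks)
    return StatTestResult(
        statistic=min(w_pos, w_neg),
        p_value=p,
        n=int(signs.size),
        method="wilcoxon-signed-rank-exact",
        alpha_corrected=alpha_corrected,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Familywise-corrected per-test threshold alpha / m."""
    if m <= 0:
        raise ValueError("number of tests must be positive")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def bonferroni_flags(p_values, alpha: float, m: int | None = None) -> list[bool]:
    """Significance flags p <= alpha/m (m defaults to the family size)."""
    p_values = list(p_values)
    thr = bonferroni_threshold(alpha, m if m is not None else len(p_values))
    return [p <= thr for p in p_values]


def _friedman_statistic(matrix: np.ndarray) -> tuple[float, np.ndarray]:
    """Tie-corrected Friedman chi-square and the within-block rank matrix."""
    n, k = matrix.shape
    ranked = np.apply_along_axis(stats.rankdata, 1, matrix)
    col_sums = ranked.sum(axis=0)
    num = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    den = float(np.sum(ranked**2)) - n * k * (k + 1) ** 2 / 4.0
    if den == 0.0:  # every block fully tied
        return 0.0, ranked
    return num / den, ranked


def friedman(matrix, p_method: str = "chisq") -> StatTestResult:
    """Friedman rank test over an (n blocks x k treatments) matrix.

    Treatments are ranked within each block with average ranks for ties; the
    statistic uses the standard tie-correction (fully tied blocks contribute
    nothing, and an entirely tied matrix yields 0).  ``p_method`` selects the
    chi-square reference distribution on k-1 degrees of freedom ("chisq",
    default) or the exact permutation null over all (k!)^n within-block
    orderings ("exact", only sensible for tiny n).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    chi2, ranked = _friedman_statistic(matrix)
    if p_method == "chisq":
        p = float(stats.chi2.sf(chi2, k - 1))
    elif p_method == "exact":
        p = _friedman_exact_p(ranked, chi2)
    else:
        raise ValueError(f"unknown p_method: {p_method}")
    return StatTestResult(statistic=chi2, p_value=p, n=n, method=f"friedman-{p_method}")


def _friedman_exact_p(ranked: np.ndarray, chi2_obs: float) -> float:
    """P(chi2 >= observed) over all within-block column permutations.

    Permuting the within-block ranks (rather than raw values) preserves tie
    patterns, which is the exact conditional null given the tie structure.
    """
    n, k = ranked.shape
    if math.factorial(k) ** n > 500_000:
        raise ValueError("exact Friedman p infeasible at this size")
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for assignment in itertools.product(perms, repeat=n):
        permuted = np.stack([ranked[i, list(pi)] for i, pi in enumerate(assignment)])
        stat, _ = _friedman_statistic(permuted)
        total += 1
        if stat >= chi2_obs - 1e-12:
            count += 1
    return count / total
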