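"""The study's nonparametric statistical chain.

Threshold distributions in small psychophysics cohorts routinely violate
normality, so the analysis gates on Shapiro-Wilk and then runs: paired
Wilcoxon signed-rank tests (baseline vs flicker, per task) with the matched
-pairs rank-biserial correlation as effect size and a bootstrap 95% CI; the
threshold relative percentage change score that puts the three tasks on a
common scale despite their different maximum contrasts; and a Friedman test
across tasks on those change scores with Kendall's W and Conover post hoc
pairwise comparisons (Bonferroni corrected).

The Wilcoxon test drops zero differences, assigns average ranks to ties,
enumerates the exact tie-aware null distribution of W+ for small samples
(n <= 25 by default, via a rank-sum convolution) and otherwise uses the
normal approximation with continuity and tie corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "PairedResult",
    "FriedmanResult",
    "PosthocResult",
    "ChangeScore",
    "threshold_relative_change",
    "wilcoxon_signed_rank",
    "rank_biserial",
    "friedman",
    "kendall_w_from_chi2",
    "conover_posthoc",
    "normality_gate",
]


@dataclass(frozen=True)
class ChangeScore:
    """Threshold change due to flicker, as a percentage of the task's
    maximum contrast: 100 * (T_flicker - T_baseline) / max_contrast."""

    value: float  # percent
    T_baseline: float
    T_flicker: float
    max_contrast: float


def threshold_relative_change(
    T_baseline: float, T_flicker: float, max_contrast: float
) -> ChangeScore:
    """Flicker-induced threshold change in percent of the task's max contrast.

    Positive when the flicker threshold is higher (sensitivity loss).
    """
    if max_contrast <= 0:
        raise ValueError("max_contrast must be > 0")
    value = 100.0 * (T_flicker - T_baseline) / max_contrast
    return ChangeScore(
        value=float(value),
        T_baseline=float(T_baseline),
        T_flicker=float(T_flicker),
        max_contrast=float(max_contrast),
    )


@dataclass(frozen=True)
class PairedResult:
    """Paired Wilcoxon signed-rank outcome with rank-biserial effect size."""

    w_statistic: float  # smaller of the two signed-rank sums
    w_plus: float
    w_minus: float
    n_effective: int
    p_value: float
    method: str  # "exact" or "approx"
    rrb: float
    rrb_ci: tuple[float, float] | None = None


def _signed_ranks(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    d = x - y
    d = d[d != 0]  # drop zero differences (standard Wilcoxon convention)
    if d.size == 0:
        raise ValueError("all paired differences are zero: test is degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return d, ranks, w_plus, w_minus


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by convolving the tie-aware signed-rank distribution.

    Average ranks are multiples of 1/2, so doubling makes them integers and
    the null pmf of 2*W+ follows from a standard knapsack convolution over
    the 2^n equiprobable sign assignments.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _approx_p(d: np.ndarray, ranks: np.ndarray, w_small: float) -> float:
    n = d.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise ValueError("zero variance in signed-rank statistic")
    z = (w_small - mean + 0.5) / np.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * stats.norm.cdf(z)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_cutoff: int = 25,
) -> PairedResult:
    """Paired two-sided Wilcoxon signed-rank test on matched samples.

    ``mode`` is "auto" (exact when n_effective <= exact_cutoff), "exact" or
    "approx"; "exact" can be forced at any n for validation.
    """
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    d, ranks, w_plus, w_minus = _signed_ranks(x, y)
    n = d.size
    w_small = min(w_plus, w_minus)
    use_exact = mode == "exact" or (mode == "auto" and n <= exact_cutoff)
    if use_exact:
        p = _exact_p(ranks, w_plus)
        method = "exact"
    else:
        p = _approx_p(d, ranks, w_small)
        method = "approx"
    rrb = (w_plus - w_minus) / (w_plus + w_minus)
    return PairedResult(
        w_statistic=w_small,
        w_plus=w_plus,
        w_minus=w_minus,
        n_effective=n,
        p_value=p,
        method=method,
        rrb=float(rrb),
    )


def rank_biserial(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Matched-pairs rank-biserial correlation with a percentile bootstrap CI.

    rrb = (R+ - R-) / (R+ + R-) over the signed ranks of the non-zero paired
    differences; the CI resamples pairs with replacement.
    """
    d_full = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d0 = d_full[d_full != 0]
    if d0.size == 0:
        raise ValueError("all paired differences are zero: rrb is degenerate")
    ranks = rankdata(np.abs(d0))
    point = float((ranks[d0 > 0].sum() - ranks[d0 < 0].sum()) / ranks.sum())
    if n_boot < 1:
        return point, (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d0.size, size=(n_boot, d0.size))
    db = d0[idx]
    rb = rankdata(np.abs(db), axis=1)
    sums = rb.sum(axis=1)
    plus = np.where(db > 0, rb, 0.0).sum(axis=1)
    minus = np.where(db < 0, rb, 0.0).sum(axis=1)
    boot = (plus - minus) / sums
    alpha = (1 - ci_level) / 2
    lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return point, (float(lo), float(hi))


@dataclass(frozen=True)
class FriedmanResult:
    """Friedman chi-square with Kendall's W concordance effect size."""

    chi2: float
    df: int
    p_value: float
    kendall_w: float
    rank_sums: tuple[float, ...]


def kendall_w_from_chi2(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance, W = chi2 / (n * (k - 1))."""
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 subjects and k >= 2 conditions")
    return float(chi2) / (n * (k - 1))


def _rank_rows(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n x k matrix")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    return rankdata(data, axis=1)


def friedman(data) -> FriedmanResult:
    """Tie-corrected Friedman test on an n x k repeated-measures matrix.

    chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A1 - C1), where R_j are the
    column sums of within-row ranks, A1 the sum of squared ranks and
    C1 = n*k*(k+1)^2/4; p comes from the chi-square with k-1 df and
    Kendall's W = chi2 / (n*(k-1)).
    """
    r = _rank_rows(data)
    n, k = r.shape
    R = r.sum(axis=0)
    A1 = float((r**2).sum())
    C1 = n * k * (k + 1) ** 2 / 4.0
    dev2 = float(((R - n * (k + 1) / 2.0) ** 2).sum())
    if A1 - C1 <= 0:  # every row fully tied
        chi2 = 0.0
    else:
        chi2 = (k - 1) * dev2 / (A1 - C1)
    p = float(stats.chi2.sf(chi2, k - 1))
    return FriedmanResult(
        chi2=float(chi2),
        df=k - 1,
        p_value=p,
        kendall_w=kendall_w_from_chi2(chi2, n, k),
        rank_sums=tuple(float(v) for v in R),
    )


@dataclass(frozen=True)
class PosthocResult:
    """Conover all-pairs comparisons after a Friedman test."""

    pairs: tuple[tuple[int, int], ...]
    t_statistics: tuple[float, ...]
    p_adjusted: tuple[float, ...]  # Bonferroni, capped at 1
    df: int


def conover_posthoc(data) -> PosthocResult:
    """Conover's rank-based pairwise t comparisons on the Friedman ranks.

    Follows Conover (Practical Nonparametric Statistics, 3rd ed.): the
    difference of column rank sums R_i - R_j is referred to a t distribution
    with (n-1)(k-1) df and pooled variance 2n(A1 - B1)/((n-1)(k-1)), where
    A1 is the sum of squared within-row ranks and B1 = sum_j R_j^2 / n.
    Other variance formulations exist in the literature; this is the
    textbook one.  Perfect concordance leaves zero residual rank variance
    and yields infinite t (p = 0) for any non-zero rank-sum difference.
    """
    r = _rank_rows(data)
    n, k = r.shape
    R = r.sum(axis=0)
    A1 = float((r**2).sum())
    B1 = float((R**2).sum()) / n
    df = (n - 1) * (k - 1)
    denom2 = 2.0 * n * (A1 - B1) / df
    pairs, tstats, padj = [], [], []
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            diff = R[i] - R[j]
            if denom2 <= 0:
                t = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
            else:
                t = float(diff / np.sqrt(denom2))
            if np.isinf(t):
                p = 0.0
            else:
                p = float(min(1.0, 2.0 * stats.t.sf(abs(t), df) * n_pairs))
            pairs.append((i, j))
            tstats.append(t)
            padj.append(p if not np.isnan(p) else 1.0)
    return PosthocResult(
        pairs=tuple(pairs),
        t_statistics=tuple(tstats),
        p_adjusted=tuple(padj),
        df=df,
    )


def normality_gate(
    samples: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> tuple[bool, dict]:
    """Shapiro-Wilk on every sample; route to nonparametric tests if any fails.

    Returns ``(use_nonparametric, p_values)``.  Constant samples are
    degenerate and raise.
    """
    if isinstance(samples, Mapping):
        items = list(samples.items())
    else:
        items = [(str(i), s) for i, s in enumerate(samples)]
    pvals: dict = {}
    for name, s in items:
        arr = np.asarray(s, dtype=float)
        if arr.size < 3:
            raise ValueError(f"sample {name!r} needs n >= 3 for Shapiro-Wilk")
        if np.ptp(arr) == 0:
            raise ValueError(f"sample {name!r} is constant: normality undefined")
        pvals[name] = float(stats.shapiro(arr).pvalue)
    return any(p < alpha for p in pvals.values()), pvals
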