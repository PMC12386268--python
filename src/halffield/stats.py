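"""Inferential layer: Steel's many-to-one rank test, chi-square homogeneity,
and median/IQR group summaries.

Steel's test compares each of k treatment groups against a shared control
using Wilcoxon rank-sum statistics computed on the pairwise joint ranking,
then adjusts for the family of k comparisons through the joint null
distribution of the standardized statistics.  Because every comparison
shares the control sample, the statistics are positively correlated:

    corr(Z_g, Z_h) = sqrt( n_g / (n_g + n0) ) * sqrt( n_h / (n_h + n0) ),

which is exactly a one-factor ("equicorrelated" when sizes match, value 1/2)
structure Z_g = lambda_g * U + sqrt(1 - lambda_g^2) * e_g.  The familywise
two-sided adjusted p-value for comparison g is P(max_j |Z_j| >= c_g); the
one-factor structure reduces this to a single Gaussian quadrature, evaluated
deterministically here.  For small tie-free samples the marginal threshold
c_g is taken from the exact Wilcoxon null (normal-score transform), which
removes the discreteness error of the normal approximation; otherwise a
continuity-corrected normal standardization is used.  A permutation mode
re-labels the pooled observations and builds the max-|z| null empirically.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import chi2, mannwhitneyu, rankdata

#: preferred reporting order for experimental groups
GROUP_ORDER = ["control", "uniform", "in-field", "out-of-field"]

#: largest per-sample size for which the exact marginal Wilcoxon null is used
EXACT_MARGIN_MAX_N = 25

#: cap on sampled label permutations
MAX_PERMUTATIONS = 1_000_000

SteelMode = Literal["mvn", "permutation"]


@dataclass(frozen=True)
class SteelTestResult:
    treatments: tuple[str, ...]
    z_stats: np.ndarray  # standardized rank statistic per treatment
    correlation: np.ndarray  # (k, k) statistic correlation matrix
    p_adjusted: np.ndarray  # familywise-adjusted two-sided p per treatment
    method: SteelMode
    n_control: int
    n_treatment: tuple[int, ...]
    mc_error: np.ndarray  # numerical/Monte-Carlo error estimate per p


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def _rank_sum_z(control: np.ndarray, treat: np.ndarray, cc: bool) -> float:
    """Standardized midrank Wilcoxon statistic of treatment vs control.

    Positive when the treatment tends to exceed the control.  Variance is
    tie-corrected; `cc` applies a 0.5 continuity correction to |W - E[W]|.
    Fully tied pairs get z = 0.
    """
    n0, n1 = len(control), len(treat)
    pooled = np.concatenate([control, treat])
    n = n0 + n1
    ranks = rankdata(pooled)
    w = ranks[n0:].sum()
    ew = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n0 * n1 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    d = w - ew
    if cc:
        d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    return float(d / np.sqrt(var))


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def _marginal_threshold(control: np.ndarray, treat: np.ndarray) -> float:
    """Normal-scale threshold |c| equivalent to the marginal two-sided p.

    Small tie-free samples use the exact Wilcoxon null (so the familywise
    adjustment starts from an exact marginal p); otherwise the
    continuity-corrected normal z is used directly.
    """
    small = max(len(control), len(treat)) <= EXACT_MARGIN_MAX_N
    pooled = np.concatenate([control, treat])
    if small and not _has_ties(pooled):
        p = float(
            mannwhitneyu(
                treat, control, alternative="two-sided", method="exact"
            ).pvalue
        )
        p = min(max(p, 1e-300), 1.0)
        return float(ndtri(1.0 - p / 2.0)) if p < 1.0 else 0.0
    return abs(_rank_sum_z(control, treat, cc=True))


def _factor_loadings(n_control: int, n_treatment: Sequence[int]) -> np.ndarray:
    return np.sqrt(np.array(n_treatment) / (np.array(n_treatment) + n_control))


@lru_cache(maxsize=8)
def _hermegauss(m: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite_e.hermegauss(m)
    return x, w / np.sqrt(2.0 * np.pi)


def _max_abs_mvn_tail(
    c: float, loadings: np.ndarray, nodes: int = 96
) -> tuple[float, float]:
    """P(max_j |Z_j| >= c) for the one-factor Gaussian vector.

    Z_j = lambda_j * U + sqrt(1 - lambda_j^2) * e_j with U, e_j iid N(0,1),
    so the rectangle probability is a 1D integral over U, evaluated by
    Gauss-Hermite quadrature.  Returns (tail, error estimate), the error
    taken as the change when the node count is halved.
    """
    if c <= 0:
        return 1.0, 0.0

    def estimate(m: int) -> float:
        x, w = _hermegauss(m)
        lam = loadings[:, None]
        s = np.sqrt(1.0 - lam**2)
        inside = ndtr((c - lam * x) / s) - ndtr((-c - lam * x) / s)
        return float(1.0 - (w * inside.prod(axis=0)).sum())

    full = estimate(nodes)
    return min(max(full, 0.0), 1.0), abs(full - estimate(nodes // 2))


# ---------------------------------------------------------------------------
# Steel's test
# ---------------------------------------------------------------------------

def steel_test(
    control: Sequence[float],
    treatments: Mapping[str, Sequence[float]],
    mode: SteelMode = "mvn",
    seed: int | None = None,
    n_permutations: int = 10_000,
) -> SteelTestResult:
    """Steel's many-to-one rank test of each treatment against a control.

    Two-sided throughout.  ``mvn`` mode (default, deterministic) evaluates
    the familywise max-|Z| tail under the one-factor multivariate normal
    null; ``permutation`` mode permutes pooled group labels (exhaustively
    when the number of distinct relabelings is small, otherwise sampling
    ``n_permutations`` relabelings seeded by ``seed``) and reads the
    adjusted p off the empirical max-|z| null, so those p-values are exact
    multiples of 1 / (number of relabelings used).
    """
    if not treatments:
        raise ValueError("steel_test needs at least one treatment group")
    control = np.asarray(control, dtype=float)
    names = tuple(treatments.keys())
    samples = [np.asarray(treatments[g], dtype=float) for g in names]
    if len(control) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("every sample must contain at least 2 values")

    n0 = len(control)
    sizes = tuple(len(s) for s in samples)
    loadings = _factor_loadings(n0, sizes)
    corr = np.outer(loadings, loadings)
    np.fill_diagonal(corr, 1.0)
    z = np.array([_rank_sum_z(control, s, cc=False) for s in samples])

    if mode == "mvn":
        p_adj = np.empty(len(samples))
        err = np.empty(len(samples))
        for i, s in enumerate(samples):
            c = _marginal_threshold(control, s)
            p_adj[i], err[i] = _max_abs_mvn_tail(c, loadings)
    elif mode == "permutation":
        p_adj, n_used = _permutation_p(
            control, samples, seed=seed, n_permutations=n_permutations
        )
        err = np.full(len(samples), 1.0 / np.sqrt(n_used))
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    return SteelTestResult(
        treatments=names,
        z_stats=z,
        correlation=corr,
        p_adjusted=p_adj,
        method=mode,
        n_control=n0,
        n_treatment=sizes,
        mc_error=err,
    )


def _n_relabelings(sizes: Sequence[int]) -> float:
    from math import comb

    total = sum(sizes)
    count = 1.0
    for s in sizes:
        count *= comb(total, s)
        total -= s
    return count


def _permutation_p(
    control: np.ndarray,
    samples: list[np.ndarray],
    seed: int | None,
    n_permutations: int,
) -> tuple[np.ndarray, int]:
    pooled = np.concatenate([control] + samples)
    sizes = [len(control)] + [len(s) for s in samples]
    bounds = np.cumsum(sizes)
    z_obs = np.abs(
        [_rank_sum_z(control, s, cc=False) for s in samples]
    )

    def max_abs_z(arrangement: np.ndarray) -> float:
        c = arrangement[: bounds[0]]
        return max(
            abs(_rank_sum_z(c, arrangement[bounds[i] : bounds[i + 1]], cc=False))
            for i in range(len(samples))
        )

    exhaustive = _n_relabelings(sizes) <= min(n_permutations, MAX_PERMUTATIONS)
    if exhaustive:
        null = np.array(
            [max_abs_z(pooled[np.array(perm)]) for perm in _distinct_relabelings(sizes)]
        )
    else:
        rng = np.random.default_rng(seed)
        b = min(n_permutations, MAX_PERMUTATIONS)
        null = np.empty(b)
        for i in range(b):
            null[i] = max_abs_z(rng.permutation(pooled))
    p = np.array([(null >= z - 1e-12).mean() for z in z_obs])
    return p, len(null)


def _distinct_relabelings(sizes: Sequence[int]) -> Iterable[list[int]]:
    """All distinct assignments of indices 0..N-1 into ordered groups."""
    from itertools import combinations

    n = sum(sizes)

    def rec(avail: frozenset, k: int, acc: list[int]):
        if k == len(sizes):
            yield acc
            return
        for comb_ in combinations(sorted(avail), sizes[k]):
            yield from rec(avail - set(comb_), k + 1, acc + list(comb_))

    yield from rec(frozenset(range(n)), 0, [])


# ---------------------------------------------------------------------------
# chi-square homogeneity
# ---------------------------------------------------------------------------

def chi_square_test(observed: np.ndarray | Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity on a contingency table.

    Expected counts come from the row/column margins; no continuity
    correction.  Degenerate (all-zero) rows or columns are rejected with an
    error naming the offending category.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("observed must be at least a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    for axis_name, margins in (("row", rows), ("column", cols)):
        zero = np.flatnonzero(margins == 0)
        if zero.size:
            raise ValueError(
                f"degenerate {axis_name} {zero[0]}: all counts are zero"
            )
    expected = np.outer(rows, cols) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=float(chi2.sf(statistic, df)),
        expected=expected,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_groups(
    metrics: Mapping[str, Sequence[float]]
) -> list[GroupSummary]:
    """Median and quartiles per group, linear-interpolation convention.

    Output order is Control, Uniform, In-field, Out-of-field; unknown group
    names are appended alphabetically.
    """
    known = [g for g in GROUP_ORDER if g in metrics]
    extra = sorted(g for g in metrics if g not in GROUP_ORDER)
    out = []
    for g in known + extra:
        vals = np.asarray(metrics[g], dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {g!r} has no values")
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        out.append(GroupSummary(group=g, n=vals.size, median=float(med), q1=float(q1), q3=float(q3)))
    return out
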