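"""Exact Wilcoxon signed-rank and Friedman rank-sum tests.

These are the two nonparametric tests used for the cohort comparisons: the
Wilcoxon signed-rank test for paired per-domain proportions (n = 6 pairs,
one per RDoC domain), and the Friedman rank-sum test for blocked designs
such as instance counts across follow-up windows.

The Wilcoxon implementation enumerates the exact null distribution of the
positive-rank sum over all 2^n sign assignments when the sample is small
(n ≤ 25 after dropping zero differences) and tie-free; otherwise it falls
back to the normal approximation with tie correction and continuity
correction. With six uniformly one-signed, tie-free pairs the exact
two-sided p is 2/2^6 = 0.03125 — the signature value of a consistent
six-domain effect.

Zero differences are dropped (the classical treatment) by default; the
Pratt variant (zeros kept for ranking, then removed) is available via
``zero_method="pratt"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from scipy.stats import rankdata

EXACT_CROSSOVER_N = 25  # enumeration of 2^25 sign vectors stays desk-scale


@dataclass(frozen=True)
class PairedSample:
    """Paired observations across conditions (e.g. six domain proportions)."""

    a: tuple[float, ...]
    b: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b) or len(self.a) < 1:
            raise ValueError("a and b must be equal-length, non-empty")
        if self.labels and len(self.labels) != len(self.a):
            raise ValueError("labels length mismatch")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.a, dtype=float) - np.asarray(self.b, dtype=float)


@dataclass(frozen=True)
class WilcoxonResult:
    w: float                 # sum of ranks of positive differences
    p_two_sided: float
    n: int                   # pairs after zero-drop
    method: Literal["exact", "normal_approx"]


class DegenerateSampleError(ValueError):
    """All paired differences are zero: the test statistic is undefined."""


def _signed_rank_parts(diffs: np.ndarray,
                       zero_method: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (ranks of |d|, signs) after applying the zero policy."""
    if zero_method == "wilcox":
        diffs = diffs[diffs != 0]
        if diffs.size == 0:
            raise DegenerateSampleError("degenerate sample: all differences zero")
        ranks = rankdata(np.abs(diffs))  # mid-ranks on ties
        return ranks, np.sign(diffs)
    if zero_method == "pratt":
        if not np.any(diffs):
            raise DegenerateSampleError("degenerate sample: all differences zero")
        ranks = rankdata(np.abs(diffs))
        keep = diffs != 0
        return ranks[keep], np.sign(diffs[keep])
    raise ValueError(f"unknown zero_method {zero_method!r}")


def _exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p by full enumeration of sign assignments.

    Enumerates the null distribution of W = sum of positive ranks; the
    two-sided p is min(1, 2·min(P(W ≤ w), P(W ≥ w))).
    """
    n = ranks.size
    total = 1 << n
    # distribution of W over subsets, via iterative convolution on the
    # (scaled-to-integer) rank values; ranks here are tie-free integers
    int_ranks = np.rint(ranks).astype(int)
    max_w = int(int_ranks.sum())
    counts = np.zeros(max_w + 1, dtype=np.int64)
    counts[0] = 1
    for r in int_ranks:  # tie-free ranks are the integers 1..n
        counts[r:] += counts[:-r].copy()
    w_int = int(round(w_obs))
    p_le = counts[: w_int + 1].sum() / total
    p_ge = counts[w_int:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_approx_p(ranks: np.ndarray, w_obs: float) -> float:
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    # continuity correction toward the mean
    z = (w_obs - mean - 0.5 * np.sign(w_obs - mean)) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def wilcoxon_signed_rank(sample: PairedSample | None = None,
                         *,
                         a: Sequence[float] | None = None,
                         b: Sequence[float] | None = None,
                         mode: Literal["auto", "exact", "approx"] = "auto",
                         zero_method: Literal["wilcox", "pratt"] = "wilcox",
                         ) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired observations.

    W is the sum of the ranks (mid-ranks on ties) of the positive
    differences a − b. In ``auto`` mode the exact sign-enumeration
    distribution is used when n ≤ 25 after zero-drop and the |differences|
    are tie-free; otherwise the normal approximation with continuity and
    tie correction.
    """
    if sample is None:
        if a is None or b is None:
            raise ValueError("provide a PairedSample or both a and b")
        sample = PairedSample(a=tuple(a), b=tuple(b))
    ranks, signs = _signed_rank_parts(sample.differences, zero_method)
    n = ranks.size
    w = float(ranks[signs > 0].sum())

    has_ties = np.unique(ranks).size < n
    if mode == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free |differences|")
    use_exact = (mode == "exact") or (mode == "auto" and not has_ties
                                      and n <= EXACT_CROSSOVER_N)
    if use_exact:
        return WilcoxonResult(w=w, p_two_sided=_exact_p(ranks, w), n=n,
                              method="exact")
    return WilcoxonResult(w=w, p_two_sided=_normal_approx_p(ranks, w),
                          n=n, method="normal_approx")


# ---------------------------------------------------------------------------
# Friedman rank-sum test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockDesign:
    """Complete blocks × conditions matrix of real responses."""

    matrix: tuple[tuple[float, ...], ...]
    block_labels: tuple[str, ...] = ()
    condition_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.matrix)
        if n < 2:
            raise ValueError("need at least 2 blocks")
        k = len(self.matrix[0])
        if k < 2:
            raise ValueError("need at least 2 conditions")
        if any(len(row) != k for row in self.matrix):
            raise ValueError("incomplete block matrix")


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    tie_corrected: bool


def friedman(design: BlockDesign | Sequence[Sequence[float]]) -> FriedmanResult:
    """Friedman rank-sum test on a complete block design.

    Within each block, conditions receive mid-ranks; the statistic is
    ``chi2 = 12/(n·k·(k+1)) · Σ_j R_j² − 3·n·(k+1)`` with the standard tie
    correction divisor, df = k − 1, and the p-value from the chi-square
    upper tail. Constant blocks everywhere yield chi2 = 0 and p = 1.
    """
    if not isinstance(design, BlockDesign):
        design = BlockDesign(matrix=tuple(tuple(float(x) for x in row)
                                          for row in design))
    mat = np.asarray(design.matrix, dtype=float)
    n, k = mat.shape
    ranks = np.apply_along_axis(rankdata, 1, mat)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)

    # tie correction: divide by 1 − Σ(t³ − t) / (n·k·(k²−1))
    tie_sum = 0.0
    for row in mat:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    tie_corrected = tie_sum > 0
    if correction <= 0:
        # every block constant: no information, chi2 defined as 0
        return FriedmanResult(chi2=0.0, df=k - 1, p=1.0, tie_corrected=True)
    chi2 /= correction
    p = float(chi2_dist.sf(chi2, k - 1))
    return FriedmanResult(chi2=chi2, df=k - 1, p=p, tie_corrected=tie_corrected)
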