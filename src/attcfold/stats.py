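"""Descriptive and inferential statistics for site cohorts.

Skews follow the top-strand convention: GC skew = (G - C)/(G + C) and
AT skew = (A - T)/(A + T) counted on the strand handed in, so a negative
top-strand skew means the bottom strand is enriched in the corresponding
purine.  Group comparisons use the two-sided Wilcoxon rank-sum test (exact
null enumeration for small tie-free samples, tie/continuity-corrected normal
approximation otherwise) and ordinary least-squares regression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .attc import _validate_sequence

__all__ = [
    "SkewResult",
    "TestResult",
    "RegressionResult",
    "MaximalRepeat",
    "skews",
    "pairwise_identity",
    "direct_repeats",
    "rank_sum_test",
    "linear_fit",
    "cohort_summary",
]

EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class SkewResult:
    gc_skew: Optional[float]  # None when G + C == 0
    at_skew: Optional[float]  # None when A + T == 0
    strand: str = "top"


def skews(sequence: str, strand_label: str = "top") -> SkewResult:
    """GC and AT skew of a sequence as written (pass the top strand for the
    conventional orientation).  Zero-denominator components are None."""
    s = _validate_sequence(sequence)
    ng, nc = s.count("G"), s.count("C")
    na, nt = s.count("A"), s.count("T")
    gc = (ng - nc) / (ng + nc) if ng + nc else None
    at = (na - nt) / (na + nt) if na + nt else None
    return SkewResult(gc_skew=gc, at_skew=at, strand=strand_label)


_DEFAULT_SCORING = dict(match_score=1.0, mismatch_score=-1.0,
                        open_gap_score=-2.0, extend_gap_score=-1.0)


def pairwise_identity(a: str, b: str, scoring: Optional[dict] = None) -> float:
    """Percent identity under global end-to-end alignment.

    Identity is 100 x matches / alignment columns (gap columns count in the
    denominator); callers round to the nearest integer for reporting.
    """
    from Bio import Align

    a = _validate_sequence(a)
    b = _validate_sequence(b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    for k, v in {**_DEFAULT_SCORING, **(scoring or {})}.items():
        setattr(aligner, k, v)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = aln.length
    return 100.0 * counts.identities / columns


@dataclass(frozen=True)
class MaximalRepeat:
    sequence: str
    start_a: int
    start_b: int
    length: int


def direct_repeats(a: str, b: str, min_len: int = 4) -> list[MaximalRepeat]:
    """All maximal exact substrings shared by two sequences.

    An occurrence is maximal when it cannot be extended on either side.
    Results are sorted by length (descending), then by position.
    """
    if min_len < 4:
        raise ValueError("min_len must be at least 4")
    a = _validate_sequence(a)
    b = _validate_sequence(b)
    na, nb = len(a), len(b)
    # run[i][j] = length of common suffix of a[:i], b[:j]
    run = np.zeros((na + 1, nb + 1), dtype=np.int32)
    for i in range(1, na + 1):
        ai = a[i - 1]
        for j in range(1, nb + 1):
            if ai == b[j - 1]:
                run[i, j] = run[i - 1, j - 1] + 1
    hits = []
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            ln = int(run[i, j])
            if ln < min_len:
                continue
            # right-maximal: the match does not continue at (i+1, j+1)
            if i < na and j < nb and a[i] == b[j]:
                continue
            hits.append(MaximalRepeat(
                sequence=a[i - ln:i], start_a=i - ln, start_b=j - ln,
                length=ln))
    hits.sort(key=lambda r: (-r.length, r.start_a, r.start_b))
    return hits


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    n_x: int
    n_y: int
    method: str  # exact | normal_approximation


def _exact_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    nx, ny = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    ranks = {}
    for r, v in enumerate(pooled, start=1):
        ranks.setdefault(v, r)
    w_obs = sum(ranks[v] for v in x)
    n = nx + ny
    all_ranks = range(1, n + 1)
    total = 0
    le = ge = 0
    for combo in itertools.combinations(all_ranks, nx):
        w = sum(combo)
        total += 1
        if w <= w_obs:
            le += 1
        if w >= w_obs:
            ge += 1
    p = min(1.0, 2.0 * min(le / total, ge / total))
    return TestResult(statistic=float(w_obs), p_two_sided=p,
                      n_x=nx, n_y=ny, method="exact")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact null enumeration when the pooled sample has at most 12
    tie-free observations, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    if len(set(pooled)) == 1:
        return TestResult(statistic=float("nan"), p_two_sided=1.0,
                          n_x=len(x), n_y=len(y), method="exact")
    no_ties = len(set(pooled)) == len(pooled)
    if no_ties and len(pooled) <= EXACT_RANKSUM_MAX_N:
        return _exact_rank_sum(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return TestResult(statistic=float(res.statistic),
                      p_two_sided=float(res.pvalue),
                      n_x=len(x), n_y=len(y),
                      method="normal_approximation")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares with a t-test on the slope (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:  # flat response: slope 0, no variance explained
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, p_slope=1.0)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            p_slope=float(res.pvalue))


def cohort_summary(
    site_table: pd.DataFrame,
    grouping: str,
    pfold_threshold: float = 0.1,
    low_band: tuple[float, float] = (1e-7, 1e-5),
) -> pd.DataFrame:
    """Per-group summaries of site properties.

    Expects columns ``pfold``, ``length``, ``gap`` (dG_bs - dG_ts) and
    ``gc_skew``/``at_skew``; reports median length, the proportion of sites
    with pfold strictly above the threshold, the proportion inside the
    closed low-pfold band, the mean strand-stability gap and median skews.
    Empty groups are omitted with a warning.
    """
    rows = []
    for name, grp in site_table.groupby(grouping):
        if grp.empty:  # pragma: no cover - groupby drops empties
            warnings.warn(f"group {name!r} is empty; omitted")
            continue
        pf = grp["pfold"].to_numpy(dtype=float)
        row = {
            grouping: name,
            "n": len(grp),
            "median_length": float(grp["length"].median()),
            "prop_pfold_above": float(np.mean(pf > pfold_threshold)),
            "prop_pfold_low_band": float(np.mean(
                (pf >= low_band[0]) & (pf <= low_band[1]))),
        }
        if "gap" in grp:
            row["mean_gap"] = float(grp["gap"].mean())
        if "gc_skew" in grp:
            row["median_gc_skew"] = float(grp["gc_skew"].median())
        if "at_skew" in grp:
            row["median_at_skew"] = float(grp["at_skew"].median())
        rows.append(row)
    if not rows:
        warnings.warn("no non-empty groups")
    return pd.DataFrame(rows)
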