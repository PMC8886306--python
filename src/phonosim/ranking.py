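"""Kendall rank correlation between measure-based and clinician severity.

Clinicians rank the six error patterns from least (1) to most (6) severe
in terms of assumed impact on intelligibility. Each phonological measure
also induces a severity ordering over the patterns via its mean effect
score. Agreement between orderings is quantified with Kendall's tau-b,

    tau_b = (C - D) / sqrt((n0 - n1) (n0 - n2)),

where C and D count concordant and discordant pairs, n0 = n(n-1)/2 and
n1, n2 correct for ties in either vector. With only six patterns the
normal approximation for the p-value is unreliable, so the two-sided p is
computed exactly by enumerating all n! pairings when n <= 8 (the tie
structure, and hence the denominator, is permutation-invariant).

For the structural measures (WCM, IPC) the *absolute* mean effects enter
the correlations: a complexity change of either sign is a change.
"""

from __future__ import annotations

import math
from itertools import permutations
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "kendall_tau_b",
    "read_rank_table",
    "severity_correlation_matrix",
    "summarize_ratings",
]

#: measure columns of a rank table, in presentation order
MEASURES = ("clinical", "wcm", "ipc", "pcc", "lvn", "pwp")
#: measures entering the correlations as absolute values
ABSOLUTE_MEASURES = frozenset({"wcm", "ipc"})


def _pair_stats(x: Sequence[float], y: Sequence[float]) -> tuple[int, int, int]:
    """(S, tie pairs in x, tie pairs in y) over all index pairs."""
    n = len(x)
    s = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = (x[i] > x[j]) - (x[i] < x[j])
            dy = (y[i] > y[j]) - (y[i] < y[j])
            if dx == 0:
                tx += 1
            if dy == 0:
                ty += 1
            s += dx * dy
    return s, tx, ty


def kendall_tau_b(
    x: Sequence[float],
    y: Sequence[float],
    *,
    p_method: str = "auto",
) -> tuple[float, float]:
    """Kendall's tau-b with average-rank tie correction.

    ``p_method``: 'exact' (full permutation enumeration, n <= 8),
    'normal' (large-sample approximation), or 'auto' (exact when n <= 8).
    Returns (tau, two-sided p).
    """
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    s, tx, ty = _pair_stats(x, y)
    n0 = n * (n - 1) // 2
    if tx == n0 or ty == n0:
        raise ValueError("tau undefined for a constant vector")
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    tau = s / denom
    if p_method == "auto":
        p_method = "exact" if n <= 8 else "normal"
    if p_method == "exact":
        total = hits = 0
        threshold = abs(s) - 1e-9
        for perm in permutations(y):
            s_perm, _, _ = _pair_stats(x, perm)
            total += 1
            if abs(s_perm) >= threshold:
                hits += 1
        p = hits / total
    elif p_method == "normal":
        var = n * (n - 1) * (2 * n + 5) / 18.0
        if s == 0:
            p = 1.0
        else:
            z = (abs(s) - 1) / math.sqrt(var)  # continuity-corrected
            p = math.erfc(z / math.sqrt(2))
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return tau, min(p, 1.0)


def read_rank_table(path: str | Path) -> pd.DataFrame:
    """Read a per-pattern severity table (TSV, indexed by pattern name)
    with columns ``clinical_mean``, ``wcm_mean``, ..., ``pwp_mean``."""
    df = pd.read_csv(path, sep="\t").set_index("pattern")
    missing = [m for m in MEASURES if f"{m}_mean" not in df.columns]
    if missing:
        raise ValueError(f"rank table lacks mean columns for: {missing}")
    if df.index.duplicated().any():
        raise ValueError("duplicate pattern rows in rank table")
    return df


def severity_correlation_matrix(
    rank_table: pd.DataFrame, *, p_method: str = "auto"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise tau-b over clinical ranking and the five measure means.

    Absolute values are taken for the structural measures (WCM, IPC)
    before correlating. Returns (tau matrix, p matrix); diagonals are 1
    and NaN respectively.
    """
    cols = {}
    for m in MEASURES:
        v = rank_table[f"{m}_mean"].astype(float)
        cols[m] = v.abs() if m in ABSOLUTE_MEASURES else v
    tau = pd.DataFrame(index=MEASURES, columns=MEASURES, dtype=float)
    pval = pd.DataFrame(index=MEASURES, columns=MEASURES, dtype=float)
    for i, a in enumerate(MEASURES):
        tau.loc[a, a] = 1.0
        for b in MEASURES[i + 1 :]:
            t, p = kendall_tau_b(cols[a], cols[b], p_method=p_method)
            tau.loc[a, b] = tau.loc[b, a] = t
            pval.loc[a, b] = pval.loc[b, a] = p
    return tau, pval


def summarize_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-pattern mean and SD of per-respondent severity rankings.

    ``ratings``: one row per respondent, one column per pattern, values
    1..n_patterns. Respondent exclusion (e.g. by years of experience) is
    the caller's responsibility.
    """
    return pd.DataFrame(
        {"clinical_mean": ratings.mean(axis=0), "clinical_sd": ratings.std(axis=0, ddof=0)}
    )
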