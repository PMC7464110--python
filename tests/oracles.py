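"""Independent brute-force oracles used to validate the implementation.

Everything here deliberately avoids the code paths of the package (and of
the vectorized/library routines being checked): plain Python loops and
exhaustive enumeration only.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np


def naive_gefc_mask(
    green: np.ndarray,
    red: np.ndarray,
    wl_min: float,
    wl_max: float,
    int_min: float,
    int_max: float,
    lam_g: float = 530.0,
    lam_r: float = 630.0,
) -> np.ndarray:
    """Per-pixel loop applying the GEFC selection definition directly."""
    rows, cols = green.shape
    out = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            g = float(green[i, j])
            r = float(red[i, j])
            total = g + r
            if total <= 0:
                continue
            wl = (lam_g * g + lam_r * r) / total
            out[i, j] = int_min <= total <= int_max and wl_min <= wl <= wl_max
    return out


def naive_sector_label(
    shape: tuple[int, int],
    center: tuple[float, float],
    pitch_um: float,
) -> np.ndarray:
    """Exhaustive per-pixel distance classification into sector codes.

    0 = outside macula, 1 = fovea, 2 = parafovea, 3 = perifovea.
    """
    rows, cols = shape
    out = np.zeros(shape, dtype=np.int8)
    for i in range(rows):
        for j in range(cols):
            d_mm = math.hypot(i - center[0], j - center[1]) * pitch_um / 1000.0
            if d_mm < 0.75:
                out[i, j] = 1
            elif d_mm < 1.5:
                out[i, j] = 2
            elif d_mm < 3.0:
                out[i, j] = 3
    return out


def mann_whitney_exact(a: list[float], b: list[float]) -> tuple[float, float]:
    """Exact Mann-Whitney U and two-sided p by enumerating all labelings.

    U counts pairs with a > b (ties 1/2). Assumes small tie-free samples.
    """
    na, nb = len(a), len(b)

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    pooled = list(a) + list(b)
    mean_u = na * nb / 2.0
    count = 0
    total = 0
    for idx in combinations(range(na + nb), na):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(na + nb) if i not in idx]
        u = u_stat(xs, ys)
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def wilcoxon_signed_rank_exact(
    a: list[float], b: list[float]
) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank (zeros dropped, two-sided p).

    Enumerates all 2^n sign assignments of the nonzero |differences|;
    assumes no tied |differences| among the kept pairs.
    """
    d = [x - y for x, y in zip(a, b) if x != y]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    absd = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0.0] * n
    for rank, i in enumerate(absd, start=1):
        ranks[i] = float(rank)
    w_plus = sum(r for r, di in zip(ranks, d) if di > 0)
    mean_w = n * (n + 1) / 4.0
    count = 0
    for signs in product([1, -1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        if abs(w - mean_w) >= abs(w_plus - mean_w) - 1e-12:
            count += 1
    stat = min(w_plus, n * (n + 1) / 2.0 - w_plus)
    return stat, count / 2**n


def friedman_chi_square(matrix: np.ndarray) -> float:
    """Friedman Q via explicit per-row rank summation (mid-ranks, ties)."""
    n, m = matrix.shape
    ranks = np.empty_like(matrix, dtype=float)
    for i in range(n):
        row = matrix[i]
        for j in range(m):
            less = sum(1 for v in row if v < row[j])
            equal = sum(1 for v in row if v == row[j])
            ranks[i, j] = less + (equal + 1) / 2.0
    col_sums = ranks.sum(axis=0)
    ss = sum((rj - n * (m + 1) / 2.0) ** 2 for rj in col_sums)
    denom = (ranks**2).sum() - n * m * (m + 1) ** 2 / 4.0
    if denom == 0:
        return 0.0
    return float((m - 1) * ss / denom)


def icc_a1_pingouin(session1: np.ndarray, session2: np.ndarray) -> float:
    """ICC(A,1) via pingouin's ANOVA route (independent implementation)."""
    import pandas as pd
    import pingouin as pg

    n = len(session1)
    df = pd.DataFrame(
        {
            "subj": np.repeat(np.arange(n), 2),
            "sess": np.tile([1, 2], n),
            "y": np.column_stack([session1, session2]).ravel(),
        }
    )
    res = pg.intraclass_corr(df, targets="subj", raters="sess", ratings="y")
    return float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
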