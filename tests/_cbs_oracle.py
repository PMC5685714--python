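"""Independent brute-force circular-binary-segmentation oracle.

Everything here recomputes the classic pooled-SD two-sample t statistic
directly from array slices / window sums — no code shared with the package
implementation — while following the same declared determinism contract
(per-span generator seeded with [seed, chrom_index, lo, hi]; the full
permutation matrix drawn in one ``rng.permuted`` call).
"""

from __future__ import annotations

import numpy as np


def valid_pairs(n: int, min_seg: int) -> list[tuple[int, int]]:
    """All legal circular split pairs (arc = [i, j)); pieces empty or >= min_seg."""
    pairs = []
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            left, mid, right = i, j - i, n - j
            if mid < min_seg:
                continue
            if left != 0 and left < min_seg:
                continue
            if right != 0 and right < min_seg:
                continue
            if left == 0 and right == 0:
                continue
            pairs.append((i, j))
    return pairs


def t_statistic(x: np.ndarray, i: int, j: int) -> float:
    """Pooled-SD two-sample |t| between arc [i, j) and its complement."""
    arc = x[i:j]
    rest = np.concatenate([x[:i], x[j:]])
    n = len(x)
    m1, m2 = arc.mean(), rest.mean()
    ss = float(((arc - m1) ** 2).sum() + ((rest - m2) ** 2).sum())
    if ss == 0:
        return np.inf if m1 != m2 else 0.0
    var = ss / (n - 2)
    return abs(m1 - m2) / np.sqrt(var * (1 / len(arc) + 1 / len(rest)))


def best_split(x: np.ndarray, min_seg: int) -> tuple[float, int, int]:
    """Exhaustive all-pairs max-|t| split; smallest (i, j) on ties."""
    best = (-np.inf, -1, -1)
    for i, j in valid_pairs(len(x), min_seg):
        t = t_statistic(x, i, j)
        if t > best[0]:
            best = (t, i, j)
    return best


def _row_max_t(row: np.ndarray, min_seg: int) -> float:
    """Max |t| over all legal splits of one (permuted) span, via window sums."""
    n = len(row)
    c = np.concatenate([[0.0], np.cumsum(row)])
    c2 = np.concatenate([[0.0], np.cumsum(row**2)])
    total, total2 = c[-1], c2[-1]
    out = 0.0
    for k in range(min_seg, n):
        i = np.arange(n - k + 1)
        ok = ((i == 0) | (i >= min_seg)) & ((n - i - k == 0) | (n - i - k >= min_seg))
        ok &= ~((i == 0) & (i + k == n))
        if not ok.any():
            continue
        S = c[i + k] - c[i]
        SS = c2[i + k] - c2[i]
        m1 = S / k
        m2 = (total - S) / (n - k)
        ss = (SS - S**2 / k) + (total2 - SS - (total - S) ** 2 / (n - k))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m1 - m2) / np.sqrt(np.maximum(ss, 0.0) / (n - 2) * (1 / k + 1 / (n - k)))
        t = np.where(ss <= 0, np.where(m1 != m2, np.inf, 0.0), t)
        m = np.nanmax(np.where(ok, t, -np.inf))
        out = max(out, float(m))
    return out


def split_significant(
    x: np.ndarray, t_obs: float, alpha: float, n_perm: int,
    rng: np.random.Generator, min_seg: int,
) -> bool:
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    count = sum(_row_max_t(perms[m], min_seg) >= t_obs for m in range(n_perm))
    return count <= int(np.floor(alpha * n_perm))


def cbs_boundaries(
    x: np.ndarray, alpha: float, n_perm: int, seed: int,
    chrom_index: int, min_seg: int,
) -> list[tuple[int, int]]:
    """Full recursive CBS with exhaustive split search + full permutations."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_seg:
            out.append((lo, hi))
            return
        span = x[lo:hi]
        t, i, j = best_split(span, min_seg)
        if not np.isfinite(t) and t < 0:
            out.append((lo, hi))
            return
        if t <= 0:
            out.append((lo, hi))
            return
        rng = np.random.default_rng([seed, chrom_index, lo, hi])
        if not split_significant(span, t, alpha, n_perm, rng, min_seg):
            out.append((lo, hi))
            return
        for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
            if b > a:
                recurse(a, b)

    recurse(0, len(x))
    return sorted(out)


def merge_boundaries(
    spans: list[tuple[int, int]], x: np.ndarray, merge_tol: float
) -> list[tuple[int, int]]:
    spans = list(spans)
    while len(spans) > 1:
        means = [float(np.mean(x[a:b])) for a, b in spans]
        gaps = np.abs(np.diff(means))
        i = int(np.argmin(gaps))
        if gaps[i] >= merge_tol:
            break
        spans[i] = (spans[i][0], spans[i + 1][1])
        del spans[i + 1]
    return spans
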