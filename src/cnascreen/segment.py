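"""Circular binary segmentation (CBS) with permutation change-point tests.

Each chromosome's usable-bin log2 ratios are treated as a circle; the best
split is the arc maximizing the two-group t-like statistic, accepted when its
within-span permutation p-value is at or below ``alpha``, and accepted
sub-spans are recursed.  The search over splits is exhaustive over all
(i, j) pairs: because the statistic is symmetric under swapping an arc with
its complement, the non-wrapping windows of every length cover all circular
splits.

Implementation notes
--------------------
* For a span of ``n`` values with total ``T`` and total sum of squares
  ``TSS``, the pooled-SD t statistic of the split into an arc (sum ``S``,
  length ``k``) and its complement satisfies

      t^2 = BSS * (n - 2) / (TSS - BSS),
      BSS = S^2/k + (T - S)^2/(n - k) - T^2/n,

  a strictly increasing function of the between-group sum of squares BSS
  (T and TSS are permutation-invariant).  Maximization and permutation
  comparisons are therefore done on BSS, which avoids the 0/0 of a perfect
  fit while selecting and testing exactly the same splits.
* Determinism contract: every tested span draws its own generator
  ``np.random.default_rng([seed, chrom_index, lo, hi])`` (lo/hi are usable-
  bin offsets within the chromosome) and materializes the full
  ``n_perm x n`` permutation matrix in one ``rng.permuted`` call before
  evaluation, so early stopping of the count cannot change any decision or
  any later span's draws.
* Ties in the split statistic resolve to the smallest left index, then the
  smallest right index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import CopyRatioProfile

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
DEFAULT_MIN_SEG_BINS = 2
DEFAULT_MERGE_TOL = 0.05
_PERM_BLOCK = 250


@dataclass
class SegmentedProfile:
    """Piecewise-constant segments partitioning each chromosome's usable bins.

    ``segments`` columns: chrom, start, end (0-based half-open bp), n_bins,
    mean_log2 (mean of member-bin log2 ratios).
    """

    segments: pd.DataFrame
    sample_id: str = "sample"
    alpha_used: float = DEFAULT_ALPHA
    bin_width_used: int = 0
    bin_noise_sd: float | None = None  # robust per-bin log2 noise estimate

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "n_bins", "mean_log2"}
        missing = required - set(self.segments.columns)
        if missing:
            raise ValueError(f"SegmentedProfile missing columns: {sorted(missing)}")
        self.segments = self.segments.reset_index(drop=True)

    @property
    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"]).to_numpy().astype(float)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def weights(self) -> np.ndarray:
        """Segment length / total segmented genome length."""
        return self.lengths / self.total_length


def _valid_window_mask(n: int, k: int, min_seg: int) -> np.ndarray:
    """Which window starts i (arc = [i, i+k)) yield legal segment pieces."""
    i = np.arange(n - k + 1)
    left_ok = (i == 0) | (i >= min_seg)
    right = n - (i + k)
    right_ok = (right == 0) | (right >= min_seg)
    whole = (i == 0) & (right == 0)
    return left_ok & right_ok & ~whole


def _best_split(x: np.ndarray, min_seg: int) -> tuple[float, int, int]:
    """Maximize BSS over legal (i, j) pairs; smallest (i, j) on ties.

    Returns (bss, i, j); bss = -inf when no legal split exists.
    """
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    T = c[-1]
    best = (-np.inf, -1, -1)
    for k in range(min_seg, n):
        mask = _valid_window_mask(n, k, min_seg)
        if not mask.any():
            continue
        S = c[k:] - c[:-k]
        with np.errstate(invalid="ignore"):
            bss = S**2 / k + (T - S) ** 2 / (n - k) - T**2 / n
        bss[~mask] = -np.inf
        i = int(np.argmax(bss))
        if bss[i] > best[0]:
            best = (float(bss[i]), i, i + k)
        elif bss[i] == best[0] and best[1] >= 0:
            if (i, i + k) < (best[1], best[2]):
                best = (float(bss[i]), i, i + k)
    return best


def _null_max_bss(perms: np.ndarray, min_seg: int) -> np.ndarray:
    """Per-row maximum BSS over legal splits for a block of permuted spans."""
    m, n = perms.shape
    c = np.concatenate([np.zeros((m, 1)), np.cumsum(perms, axis=1)], axis=1)
    T = c[:, -1:]
    out = np.full(m, -np.inf)
    for k in range(min_seg, n):
        mask = _valid_window_mask(n, k, min_seg)
        if not mask.any():
            continue
        S = c[:, k:] - c[:, :-k]
        bss = S**2 / k + (T - S) ** 2 / (n - k) - T**2 / n
        bss[:, ~mask] = -np.inf
        np.maximum(out, bss.max(axis=1), out=out)
    return out


def _split_is_significant(
    x: np.ndarray,
    obs_bss: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    min_seg: int,
) -> bool:
    """Permutation test: p = #{null max BSS >= observed}/n_perm <= alpha?"""
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    threshold = int(np.floor(alpha * n_perm))
    count = 0
    for start in range(0, n_perm, _PERM_BLOCK):
        block = perms[start : start + _PERM_BLOCK]
        count += int((_null_max_bss(block, min_seg) >= obs_bss).sum())
        if count > threshold:
            return False
    return True


def _segment_chromosome(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    seed: int,
    chrom_index: int,
    min_seg: int,
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's usable-bin vector -> [lo, hi) spans."""
    boundaries: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_seg:
            boundaries.append((lo, hi))
            return
        span = x[lo:hi]
        bss, i, j = _best_split(span, min_seg)
        if not np.isfinite(bss) or bss <= 0:
            boundaries.append((lo, hi))
            return
        rng = np.random.default_rng([seed, chrom_index, lo, hi])
        if not _split_is_significant(span, bss, alpha, n_perm, rng, min_seg):
            boundaries.append((lo, hi))
            return
        for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
            if b > a:
                recurse(a, b)

    recurse(0, len(x))
    boundaries.sort()
    return boundaries


def _merge_close_segments(
    spans: list[tuple[int, int]], x: np.ndarray, merge_tol: float
) -> list[tuple[int, int]]:
    """Re-merge adjacent segments whose means differ by < merge_tol."""
    spans = list(spans)
    while len(spans) > 1:
        means = [float(np.mean(x[a:b])) for a, b in spans]
        diffs = np.abs(np.diff(means))
        i = int(np.argmin(diffs))
        if diffs[i] >= merge_tol:
            break
        spans[i] = (spans[i][0], spans[i + 1][1])
        del spans[i + 1]
    return spans


def cbs_segment(
    profile: CopyRatioProfile,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    merge_tol: float = DEFAULT_MERGE_TOL,
) -> SegmentedProfile:
    """Segment a log2-ratio profile chromosome by chromosome.

    A chromosome with fewer than ``min_seg_bins`` usable bins becomes a
    single segment with a warning.  Identical inputs and seed give identical
    output.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    table = profile.bins.table
    usable = profile.usable
    rows = []
    diffs: list[np.ndarray] = []
    for chrom_index, chrom in enumerate(profile.bins.chroms):
        on_chrom = (table["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(on_chrom & usable)
        if len(idx) == 0:
            continue
        x = profile.log2ratio[idx]
        if len(x) > 1:
            diffs.append(np.diff(x))
        if len(idx) < min_seg_bins:
            logger.warning("chromosome %s has %d usable bins; single segment", chrom, len(idx))
            spans = [(0, len(idx))]
        else:
            spans = _segment_chromosome(x, alpha, n_perm, seed, chrom_index, min_seg_bins)
            spans = _merge_close_segments(spans, x, merge_tol)
        starts = table["start"].to_numpy()[idx]
        ends = table["end"].to_numpy()[idx]
        for a, b in spans:
            rows.append(
                (chrom, int(starts[a]), int(ends[b - 1]), b - a, float(np.mean(x[a:b])))
            )
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "mean_log2"])
    # robust bin-to-bin noise SD (successive differences, MAD-scaled);
    # downstream model fits use it to calibrate their state penalties
    noise_sd = None
    if diffs:
        all_diffs = np.concatenate(diffs)
        if len(all_diffs) >= 10:
            noise_sd = float(1.4826 * np.median(np.abs(all_diffs)) / np.sqrt(2.0))
    return SegmentedProfile(
        segments=segments,
        sample_id=profile.sample_id,
        alpha_used=alpha,
        bin_width_used=profile.bin_width_used,
        bin_noise_sd=noise_sd,
    )


def seg_write(profile: SegmentedProfile, path) -> None:
    """Write a SEG file (1-based inclusive starts, as the format expects)."""
    out = profile.segments.copy()
    out.insert(0, "ID", profile.sample_id)
    out["loc.start"] = out["start"] + 1
    out["loc.end"] = out["end"]
    out = out[["ID", "chrom", "loc.start", "loc.end", "n_bins", "mean_log2"]]
    out.columns = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    out.to_csv(path, sep="\t", index=False)


def seg_read(path) -> SegmentedProfile:
    """Read a SEG file back to internal 0-based half-open coordinates."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse SEG file {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    required = ["id", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    for want in required:
        if want not in cols:
            raise ValueError(f"{path}: missing SEG column {want!r}")
    for lineno, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            int(row[cols["loc.start"]]); int(row[cols["loc.end"]]); float(row[cols["seg.mean"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed SEG row ({exc})") from exc
    segments = pd.DataFrame(
        {
            "chrom": df[cols["chrom"]].astype(str),
            "start": df[cols["loc.start"]].astype(int) - 1,
            "end": df[cols["loc.end"]].astype(int),
            "n_bins": df[cols["num.mark"]].astype(int),
            "mean_log2": df[cols["seg.mean"]].astype(float),
        }
    )
    sample_id = str(df[cols["id"]].iloc[0]) if len(df) else "sample"
    return SegmentedProfile(segments=segments, sample_id=sample_id)
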