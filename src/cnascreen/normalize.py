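"""GC correction and reference normalization to log2 copy-ratio profiles.

Raw bin counts carry a smooth bias in GC content.  The correction fits a
deterministic trend (median count within 20 GC bins, linearly interpolated)
and divides it out, preserving the pre-correction median.  Counts are then
converted to log2 ratios against a panel-of-normals reference (per-bin panel
median) or, absent a panel, against the flat median expectation, and the
profile is median-centered over usable autosomal bins.

Bin width adapts to sequencing depth: the smallest width on a ladder whose
expected reads per bin stays above a floor (default 30, keeping the Poisson
coefficient of variation per bin below ~18%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .genome_bins import BinCounts, GenomeBins

logger = logging.getLogger(__name__)

DEFAULT_BIN_LADDER = (100_000, 250_000, 500_000, 1_000_000, 2_500_000, 5_000_000)
DEFAULT_GENOME_LENGTH = 3_100_000_000
PSEUDOCOUNT = 0.5  # reads added to both sides of the ratio
N_GC_BINS = 20


@dataclass
class CopyRatioProfile:
    """Per-bin log2 copy ratios (NaN on unusable bins), median-centered."""

    bins: GenomeBins
    log2ratio: np.ndarray
    weight: np.ndarray
    sample_id: str = "sample"
    bin_width_used: int = 0

    def __post_init__(self) -> None:
        self.log2ratio = np.asarray(self.log2ratio, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if len(self.log2ratio) != self.bins.n_bins or len(self.weight) != self.bins.n_bins:
            raise ValueError("profile vectors must match the bin grid")

    @property
    def usable(self) -> np.ndarray:
        return self.bins.table["usable"].to_numpy() & np.isfinite(self.log2ratio)


def write_profile_table(profile: CopyRatioProfile, path) -> None:
    """Write a log2-ratio profile TSV (chrom, start, end, log2ratio, weight)."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        fh.write(f"# bin_width_used={profile.bin_width_used}\n")
        for chrom, length in profile.bins.chrom_lengths.items():
            fh.write(f"# chrom_length={chrom}:{length}\n")
        fh.write("chrom\tstart\tend\tlog2ratio\tweight\n")
        tbl = profile.bins.table
        for i in range(len(tbl)):
            row = tbl.iloc[i]
            val = profile.log2ratio[i]
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"{'' if not np.isfinite(val) else repr(float(val))}\t"
                f"{float(profile.weight[i])!r}\n"
            )


def read_profile_table(path) -> CopyRatioProfile:
    """Read the TSV written by :func:`write_profile_table`."""
    from .genome_bins import GenomeBins

    meta: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                key, _, value = body.partition("=")
                if key.strip() == "chrom_length":
                    chrom, _, length = value.partition(":")
                    chrom_lengths[chrom.strip()] = int(length)
                else:
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if not header_seen:
                header_seen = True
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]),
                     float(parts[3]) if parts[3] else np.nan, float(parts[4]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    if not rows:
        raise ValueError(f"{path}: no profile rows found")
    import pandas as pd

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "log2ratio", "weight"])
    if not chrom_lengths:
        chrom_lengths = {c: int(g["end"].max()) for c, g in df.groupby("chrom", sort=False)}
    bin_width = int(meta.get("bin_width_used", (df["end"] - df["start"]).max()))
    bins = GenomeBins(
        table=df.assign(gc=np.nan, mappability=np.nan,
                        usable=np.isfinite(df["log2ratio"]))[
            ["chrom", "start", "end", "gc", "mappability", "usable"]
        ],
        bin_width=bin_width,
        chrom_lengths=chrom_lengths,
    )
    return CopyRatioProfile(
        bins=bins,
        log2ratio=df["log2ratio"].to_numpy(),
        weight=df["weight"].to_numpy(),
        sample_id=meta.get("sample_id", "sample"),
        bin_width_used=bin_width,
    )


def choose_bin_width(
    total_reads: int,
    ladder: tuple[int, ...] = DEFAULT_BIN_LADDER,
    min_mean_reads_per_bin: float = 30.0,
    genome_length: int = DEFAULT_GENOME_LENGTH,
) -> int:
    """Smallest ladder width with expected reads/bin >= the floor.

    Expected reads per bin is ``total_reads * width / genome_length``.  If no
    ladder width qualifies the largest is returned.
    """
    if not ladder:
        raise ValueError("bin-width ladder must not be empty")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    for width in sorted(ladder):
        if total_reads * width / genome_length >= min_mean_reads_per_bin:
            return int(width)
    return int(max(ladder))


def correct_gc(counts: BinCounts, n_gc_bins: int = N_GC_BINS) -> BinCounts:
    """Remove the smooth count-vs-GC trend, preserving the count median.

    The trend is the median count within GC-quantile groups, linearly
    interpolated at each bin's GC.  Applying the correction twice changes
    counts by well under 1% (the residual trend is flat).
    """
    usable = counts.bins.table["usable"].to_numpy()
    gc = counts.bins.table["gc"].to_numpy()
    mask = usable & np.isfinite(gc)
    if mask.sum() < 100:
        raise ValueError(f"GC correction needs >= 100 usable GC-annotated bins, have {mask.sum()}")
    x = gc[mask]
    y = counts.count[mask]
    if np.ptp(x) == 0:
        logger.warning("all usable bins share one GC value; GC correction is identity")
        return replace(counts, count=counts.count.copy())
    # GC-quantile groups; duplicate edges collapse for skewed GC distributions
    qs = np.quantile(x, np.linspace(0, 1, n_gc_bins + 1))
    qs = np.unique(qs)
    groups = np.clip(np.searchsorted(qs, x, side="right") - 1, 0, len(qs) - 2)
    centers, medians = [], []
    for g in range(len(qs) - 1):
        sel = groups == g
        if sel.sum() == 0:
            continue
        centers.append(np.median(x[sel]))
        medians.append(np.median(y[sel]))
    centers = np.asarray(centers)
    medians = np.asarray(medians)
    trend = np.interp(gc, centers, medians)
    overall = np.median(y)
    corrected = counts.count.copy().astype(float)
    ok = mask & (trend > 0)
    corrected[ok] = counts.count[ok] / trend[ok] * overall
    return replace(counts, count=corrected)


def to_log2ratio(
    counts: BinCounts,
    panel: list[BinCounts] | None = None,
    reference_counts: BinCounts | None = None,
) -> CopyRatioProfile:
    """Convert corrected counts to a median-centered log2 copy-ratio profile.

    The per-bin reference rate is the median across the panel of normals
    (each panel sample median-scaled first), or ``reference_counts`` when a
    single analytic/empirical reference is supplied, or flat (proportional
    to bin width) when neither is given.  A pseudocount of 0.5 reads is
    added to both sides of the ratio; bins with zero reference rate are
    marked unusable.  The profile is centered so the median over usable
    autosomal bins is exactly 0.
    """
    bins = counts.bins
    widths = bins.widths.astype(float)
    usable = bins.table["usable"].to_numpy().copy()

    if panel and reference_counts is not None:
        raise ValueError("give either a panel or a single reference, not both")
    if panel:
        rates = []
        for member in panel:
            if not member.bins.same_grid(bins):
                raise ValueError(f"panel sample {member.sample_id} is on a different bin grid")
            r = member.count / widths
            med = np.median(r[usable])
            if med <= 0:
                raise ValueError(f"panel sample {member.sample_id} has non-positive median rate")
            rates.append(r / med)
        ref_rate = np.median(np.vstack(rates), axis=0)
    elif reference_counts is not None:
        if not reference_counts.bins.same_grid(bins):
            raise ValueError("reference counts are on a different bin grid")
        ref_rate = reference_counts.count / widths
        med = np.median(ref_rate[usable])
        if med <= 0:
            raise ValueError("reference has non-positive median rate")
        ref_rate = ref_rate / med
    else:
        ref_rate = np.ones(bins.n_bins)

    zero_ref = usable & ~(ref_rate > 0)
    if zero_ref.any():
        logger.warning("%d bins with zero reference rate marked unusable", int(zero_ref.sum()))
        usable &= ref_rate > 0

    # scale the reference into read units matching the sample's usable total
    expected = ref_rate * widths
    scale = counts.count[usable].sum() / expected[usable].sum()
    expected = expected * scale

    log2 = np.full(bins.n_bins, np.nan)
    log2[usable] = np.log2(
        (counts.count[usable] + PSEUDOCOUNT) / (expected[usable] + PSEUDOCOUNT)
    )
    auto = usable & bins.is_autosome()
    center_mask = auto if auto.any() else usable
    log2[usable] -= np.median(log2[center_mask])

    table = bins.table.copy()
    table["usable"] = usable
    out_bins = replace(bins, table=table)
    return CopyRatioProfile(
        bins=out_bins,
        log2ratio=log2,
        weight=np.where(usable, 1.0, 0.0),
        sample_id=counts.sample_id,
        bin_width_used=bins.bin_width,
    )
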