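"""Genomic bin grid construction and binned read counting.

The pipeline works on a fixed-width tiling of the genome (default 500 kb
bins).  Aligned reads are assigned to bins by their leftmost aligned base
after quality filtering (non-duplicate, primary, MAPQ >= 37 by default), and
everything downstream operates on the per-bin count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 500_000
DEFAULT_MIN_MAPQ = 37
MIN_BIN_WIDTH = 10_000


@dataclass
class GenomeBins:
    """A sorted, non-overlapping, gap-free tiling of each chromosome.

    ``table`` columns: chrom, start, end (0-based half-open), gc (fraction
    in [0,1] or NaN), mappability (fraction or NaN), usable (bool).  All
    non-terminal bins of a chromosome share ``bin_width``; the terminal bin
    may be shorter.
    """

    table: pd.DataFrame
    bin_width: int
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gc", "mappability", "usable"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GenomeBins table missing columns: {sorted(missing)}")

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def widths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"]).to_numpy()

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def same_grid(self, other: "GenomeBins") -> bool:
        a, b = self.table, other.table
        return (
            len(a) == len(b)
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )

    def is_autosome(self) -> np.ndarray:
        return ~self.is_x()

    def is_x(self) -> np.ndarray:
        return self.table["chrom"].isin(["chrX", "X"]).to_numpy()


@dataclass
class BinCounts:
    """Filtered per-bin read counts for one sample."""

    bins: GenomeBins
    count: np.ndarray  # float once GC-corrected, integer before
    sample_id: str = "sample"
    total_reads: int = 0
    mean_read_length: float = 180.0
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.count = np.asarray(self.count, dtype=float)
        if len(self.count) != self.bins.n_bins:
            raise ValueError("count vector length does not match bin grid")
        if (self.count < 0).any():
            raise ValueError("bin counts must be non-negative")

    @property
    def effective_coverage(self) -> float:
        return self.total_reads * self.mean_read_length / self.bins.genome_length


def make_bins(genome_sizes: dict[str, int], bin_width: int = DEFAULT_BIN_WIDTH) -> GenomeBins:
    """Tile each chromosome with fixed-width bins (shorter terminal bin).

    ``genome_sizes`` maps chromosome name to length in bp; the bin order
    follows the mapping's insertion order.
    """
    if not genome_sizes:
        raise ValueError("empty genome: no chromosomes given")
    if bin_width < MIN_BIN_WIDTH:
        raise ValueError(f"bin_width must be >= {MIN_BIN_WIDTH} bp, got {bin_width}")
    chroms, starts, ends = [], [], []
    for chrom, length in genome_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        edges = np.arange(0, length + bin_width, bin_width)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        chroms.extend([chrom] * (len(edges) - 1))
        starts.extend(edges[:-1].tolist())
        ends.extend(edges[1:].tolist())
    table = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=int),
            "end": np.asarray(ends, dtype=int),
            "gc": np.nan,
            "mappability": np.nan,
            "usable": True,
        }
    )
    return GenomeBins(table=table, bin_width=int(bin_width), chrom_lengths=dict(genome_sizes))


def annotate_gc(bins: GenomeBins, reference, max_n_frac: float = 0.5) -> GenomeBins:
    """Annotate each bin with its GC fraction from a genome sequence source.

    ``reference`` is anything indexable as ``reference[chrom][start:end]``
    returning sequence text (e.g. a :class:`pyfaidx.Fasta` or a plain dict of
    strings).  GC is the G+C fraction of non-N bases; bins with more than
    ``max_n_frac`` N bases are marked unusable with GC left missing.
    """
    table = bins.table.copy()
    gc = np.full(len(table), np.nan)
    usable = table["usable"].to_numpy().copy()
    for chrom in bins.chroms:
        try:
            seq_src = reference[chrom]
        except KeyError as exc:
            raise KeyError(f"reference genome is missing chromosome {chrom!r}") from exc
        idx = np.flatnonzero((table["chrom"] == chrom).to_numpy())
        for i in idx:
            start, end = table.iloc[i]["start"], table.iloc[i]["end"]
            seq = str(seq_src[start:end]).upper()
            n_count = seq.count("N")
            denom = len(seq) - n_count
            if len(seq) == 0 or n_count > max_n_frac * len(seq) or denom == 0:
                usable[i] = False
                continue
            gc[i] = (seq.count("G") + seq.count("C")) / denom
    table["gc"] = gc
    table["usable"] = usable
    return replace(bins, table=table)


def annotate_mappability(bins: GenomeBins, values: np.ndarray, min_mappability: float = 0.0) -> GenomeBins:
    """Attach optional per-bin mappability; bins below the floor become unusable."""
    values = np.asarray(values, dtype=float)
    if len(values) != bins.n_bins:
        raise ValueError("mappability vector length does not match bin grid")
    if np.nanmin(values) < 0 or np.nanmax(values) > 1:
        raise ValueError("mappability values must lie in [0, 1]")
    table = bins.table.copy()
    table["mappability"] = values
    if min_mappability > 0:
        table["usable"] &= ~(values < min_mappability)
    return replace(bins, table=table)


def count_reads(
    alignments,
    bins: GenomeBins,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    drop_duplicates: bool = True,
    sample_id: str | None = None,
) -> BinCounts:
    """Assign filtered reads to bins by leftmost aligned base.

    ``alignments`` is a path to a coordinate-sorted SAM/BAM file or an open
    :class:`pysam.AlignmentFile`.  Unmapped, secondary, supplementary,
    duplicate-flagged (when ``drop_duplicates``) and low-MAPQ reads are
    excluded; exclusion tallies are kept on the result and logged.
    """
    import pysam

    close = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    try:
        ref_names = set(alignments.references or [])
        bin_chroms = set(bins.chroms)
        if ref_names and not (ref_names & bin_chroms):
            raise ValueError(
                "no chromosome names shared between alignments and bins; "
                f"alignment-only: {sorted(ref_names - bin_chroms)[:5]}, "
                f"bin-only: {sorted(bin_chroms - ref_names)[:5]}"
            )
        table = bins.table
        starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in bins.chroms:
            idx = np.flatnonzero((table["chrom"] == chrom).to_numpy())
            starts_by_chrom[chrom] = (
                table["start"].to_numpy()[idx],
                table["end"].to_numpy()[idx],
                idx,
            )
        counts = np.zeros(bins.n_bins, dtype=np.int64)
        excluded = {
            "unmapped": 0, "secondary": 0, "supplementary": 0,
            "duplicate": 0, "low_mapq": 0, "unmatched_chrom": 0,
            "outside_bins": 0,
        }
        total_len = 0
        n_assigned = 0
        for read in alignments:
            if read.is_unmapped:
                excluded["unmapped"] += 1
                continue
            if read.is_secondary:
                excluded["secondary"] += 1
                continue
            if read.is_supplementary:
                excluded["supplementary"] += 1
                continue
            if drop_duplicates and read.is_duplicate:
                excluded["duplicate"] += 1
                continue
            if read.mapping_quality < min_mapq:
                excluded["low_mapq"] += 1
                continue
            chrom = read.reference_name
            if chrom not in starts_by_chrom:
                excluded["unmatched_chrom"] += 1
                continue
            starts, ends, idx = starts_by_chrom[chrom]
            pos = read.reference_start
            j = int(np.searchsorted(starts, pos, side="right")) - 1
            if j < 0 or pos >= ends[j]:
                excluded["outside_bins"] += 1
                continue
            counts[idx[j]] += 1
            total_len += read.query_length or read.infer_query_length() or 0
            n_assigned += 1
        if any(excluded.values()):
            logger.info("count_reads exclusions: %s", excluded)
        mean_len = total_len / n_assigned if n_assigned else 0.0
        return BinCounts(
            bins=bins,
            count=counts,
            sample_id=sample_id or "sample",
            total_reads=n_assigned,
            mean_read_length=mean_len,
            excluded=excluded,
        )
    finally:
        if close:
            alignments.close()


def write_counts_table(counts: BinCounts, path) -> None:
    """Write a BinCounts to TSV with ``# key=value`` metadata header lines."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={counts.sample_id}\n")
        fh.write(f"# total_reads={counts.total_reads}\n")
        fh.write(f"# mean_read_length={counts.mean_read_length!r}\n")
        fh.write(f"# bin_width={counts.bins.bin_width}\n")
        for chrom, length in counts.bins.chrom_lengths.items():
            fh.write(f"# chrom_length={chrom}:{length}\n")
        fh.write("chrom\tstart\tend\tgc\tmappability\tusable\tcount\n")
        tbl = counts.bins.table
        for i in range(len(tbl)):
            row = tbl.iloc[i]
            c = counts.count[i]
            c_str = str(int(c)) if float(c).is_integer() else repr(float(c))
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"{'' if np.isnan(row['gc']) else repr(float(row['gc']))}\t"
                f"{'' if np.isnan(row['mappability']) else repr(float(row['mappability']))}\t"
                f"{int(bool(row['usable']))}\t{c_str}\n"
            )


def read_counts_table(path) -> BinCounts:
    """Parse the TSV written by :func:`write_counts_table` (round-trip safe)."""
    meta: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    rows = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    if key.strip() == "chrom_length":
                        chrom, _, length = value.partition(":")
                        chrom_lengths[chrom.strip()] = int(length)
                    else:
                        meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                expected = ["chrom", "start", "end", "gc", "mappability", "usable", "count"]
                if header != expected:
                    raise ValueError(
                        f"{path}:{lineno}: unexpected column header {header!r}"
                    )
                continue
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                gc = float(parts[3]) if parts[3] else np.nan
                mapp = float(parts[4]) if parts[4] else np.nan
                usable = bool(int(parts[5]))
                count = float(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            rows.append((chrom, start, end, gc, mapp, usable, count))
    if header is None or not rows:
        raise ValueError(f"{path}: no count rows found")
    df = pd.DataFrame(rows, columns=header)
    if not chrom_lengths:
        chrom_lengths = {c: int(g["end"].max()) for c, g in df.groupby("chrom", sort=False)}
    bin_width = int(meta.get("bin_width", (df["end"] - df["start"]).max()))
    bins = GenomeBins(
        table=df[["chrom", "start", "end", "gc", "mappability", "usable"]].reset_index(drop=True),
        bin_width=bin_width,
        chrom_lengths=chrom_lengths,
    )
    return BinCounts(
        bins=bins,
        count=df["count"].to_numpy(),
        sample_id=meta.get("sample_id", "sample"),
        total_reads=int(meta.get("total_reads", 0)),
        mean_read_length=float(meta.get("mean_read_length", 180.0)),
    )
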