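"""Synthetic cfDNA WGS engine: truth profiles, Poisson bin counts, in-silico
mixing and downsampling.

Counts are simulated at bin level (not as synthetic alignments): a bin with
tumor copy ``n`` in a sample of tumor fraction ``f`` draws from a Poisson
whose mean is proportional to ``width * (f*n + (1-f)*b)`` (``b`` the normal
copy: 2 on autosomes, 1 on male chrX), optionally shaped by a linear GC bias,
and normalized so the expected genome-wide total matches the requested
effective coverage at the given mean fragment length (180 bp default, the
typical cfDNA fragment size).

The stock truth profiles emulate common advanced-prostate and bladder cancer
copy-number landscapes (8p loss, 8q gain, focal AR or EGFR amplification,
focal 2-copy PTEN/RB1 deletions, interstitial 21q22.2 loss) on a
proportionally shrunk genome (default 1/20 of GRCh37 autosome+X lengths) so
the full pipeline runs at desk scale; all bin arithmetic is length-agnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations
from .genome_bins import BinCounts, GenomeBins, make_bins, write_counts_table

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 180.0  # bp, cfDNA-like fragment size
DEFAULT_GENOME_SCALE = 20
DILUTION_FRACTIONS = (0.5, 0.25, 0.1, 0.05, 0.01, 0.0)
_X_NAMES = frozenset({"chrX", "X"})


@dataclass
class TruthProfile:
    """Ground-truth tumor integer copy numbers as non-overlapping intervals.

    Uncovered regions are implicitly copy 2 (autosomes) or the sex baseline
    (1 on male chrX).  ``chrom_sizes`` defines the genome the truth lives on.
    """

    intervals: pd.DataFrame  # chrom, start, end, cn
    chrom_sizes: dict[str, int]
    sex: str = "male"
    label: str = "truth"

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "cn"}
        if not required <= set(self.intervals.columns):
            raise ValueError("truth intervals need chrom/start/end/cn columns")
        for chrom, grp in self.intervals.groupby("chrom"):
            grp = grp.sort_values("start")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping truth intervals on {chrom}")
            if chrom not in self.chrom_sizes:
                raise ValueError(f"truth interval on unknown chromosome {chrom}")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def normal_copy(self, chrom: str) -> int:
        return 1 if (chrom in _X_NAMES and self.sex == "male") else 2

    def bin_copy_numbers(self, bins: GenomeBins) -> np.ndarray:
        """Overlap-weighted mean tumor copy number per bin."""
        table = bins.table
        out = np.empty(bins.n_bins)
        for i, chrom in enumerate(table["chrom"]):
            out[i] = float(self.normal_copy(chrom))
        for _, iv in self.intervals.iterrows():
            sel = np.flatnonzero((table["chrom"] == iv["chrom"]).to_numpy())
            if len(sel) == 0:
                continue
            starts = table["start"].to_numpy()[sel]
            ends = table["end"].to_numpy()[sel]
            ov = np.clip(np.minimum(ends, iv["end"]) - np.maximum(starts, iv["start"]), 0, None)
            widths = (ends - starts).astype(float)
            frac = ov / widths
            out[sel] += frac * (iv["cn"] - self.normal_copy(iv["chrom"]))
        return out

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "sex": self.sex,
            "chrom_sizes": {c: int(v) for c, v in self.chrom_sizes.items()},
            "intervals": self.intervals.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TruthProfile":
        return cls(
            intervals=pd.DataFrame(payload["intervals"]),
            chrom_sizes=payload["chrom_sizes"],
            sex=payload["sex"],
            label=payload["label"],
        )


@dataclass
class DilutionSpec:
    """One simulated dilution point: tumor fraction and target coverage."""

    fraction: float
    target_coverage: float
    mean_read_length: float = DEFAULT_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        if self.target_coverage <= 0:
            raise ValueError("target coverage must be positive")


def _centered_interval(chrom: str, gene_start: int, gene_end: int, length: int,
                       chrom_len: int) -> tuple[str, int, int]:
    mid = (gene_start + gene_end) // 2
    start = max(0, min(mid - length // 2, chrom_len - length))
    return chrom, start, min(start + length, chrom_len)


def mcrpc_like(scale: int = DEFAULT_GENOME_SCALE) -> TruthProfile:
    """Advanced-prostate-like truth: 8p loss, 8q gain, chr7 gain, chr13/16
    loss with focal 2-copy RB1 deletion, focal 2-copy PTEN deletion, focal
    AR amplification (n=12) and interstitial 21q22.2 loss."""
    sizes = annotations.chrom_sizes(scale)
    genes = {name: (c, s // scale, e // scale) for name, (c, s, e) in annotations.GRCH37_GENES.items()}
    cen8 = annotations.GRCH37_CENTROMERES["chr8"] // scale
    rows: list[tuple[str, int, int, int]] = []
    rows.append(("chr7", 0, sizes["chr7"], 3))
    rows.append(("chr8", 0, cen8, 1))
    rows.append(("chr8", cen8, sizes["chr8"], 3))
    pten = _centered_interval(*genes["PTEN"], 2_000_000, sizes["chr10"])
    rows.append((*pten, 0))
    rb1 = _centered_interval(*genes["RB1"], 2_000_000, sizes["chr13"])
    rows.append(("chr13", 0, rb1[1], 1))
    rows.append((*rb1, 0))
    rows.append(("chr13", rb1[2], sizes["chr13"], 1))
    rows.append(("chr16", 0, sizes["chr16"], 1))
    rows.append(("chr18", 0, sizes["chr18"], 1))
    erg = annotations.erg_tmprss2_interval(scale)
    rows.append((erg[0], max(0, erg[1] - 50_000), min(sizes["chr21"], erg[2] + 50_000), 1))
    ar = _centered_interval(*genes["AR"], 3_000_000, sizes["chrX"])
    rows.append((*ar, 12))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    return TruthProfile(intervals=intervals, chrom_sizes=sizes, sex="male",
                        label=f"mCRPC-like/{scale}")


def vcap_like(scale: int = DEFAULT_GENOME_SCALE) -> TruthProfile:
    """Prostate cell-line-like truth: AR amplification plus broad 8p/8q/13
    events and the 21q22.2 interstitial loss."""
    sizes = annotations.chrom_sizes(scale)
    genes = {name: (c, s // scale, e // scale) for name, (c, s, e) in annotations.GRCH37_GENES.items()}
    cen8 = annotations.GRCH37_CENTROMERES["chr8"] // scale
    rows: list[tuple[str, int, int, int]] = []
    rows.append(("chr8", 0, cen8, 1))
    rows.append(("chr8", cen8, sizes["chr8"], 3))
    rows.append(("chr13", 0, sizes["chr13"], 1))
    erg = annotations.erg_tmprss2_interval(scale)
    rows.append((erg[0], max(0, erg[1] - 50_000), min(sizes["chr21"], erg[2] + 50_000), 1))
    ar = _centered_interval(*genes["AR"], 3_000_000, sizes["chrX"])
    rows.append((*ar, 12))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    return TruthProfile(intervals=intervals, chrom_sizes=sizes, sex="male",
                        label=f"VCaP-like/{scale}")


def umuc5_like(scale: int = DEFAULT_GENOME_SCALE) -> TruthProfile:
    """Bladder cell-line-like truth: 20-copy focal EGFR amplification plus
    chr9 loss and 8q gain."""
    sizes = annotations.chrom_sizes(scale)
    genes = {name: (c, s // scale, e // scale) for name, (c, s, e) in annotations.GRCH37_GENES.items()}
    cen8 = annotations.GRCH37_CENTROMERES["chr8"] // scale
    rows: list[tuple[str, int, int, int]] = []
    egfr = _centered_interval(*genes["EGFR"], 3_000_000, sizes["chr7"])
    rows.append((*egfr, 20))
    rows.append(("chr8", cen8, sizes["chr8"], 3))
    rows.append(("chr9", 0, sizes["chr9"], 1))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    return TruthProfile(intervals=intervals, chrom_sizes=sizes, sex="male",
                        label=f"UMUC-5-like/{scale}")


def simulate_counts(
    truth: TruthProfile,
    spec: DilutionSpec,
    bins: GenomeBins,
    gc_bias_strength: float = 0.0,
    sample_id: str | None = None,
) -> BinCounts:
    """Draw Poisson bin counts for a tumor/normal mixture at given coverage."""
    gc = bins.table["gc"].to_numpy()
    if gc_bias_strength != 0 and not np.isfinite(gc).any():
        raise ValueError("GC bias requested but bins carry no GC annotation")
    n_bin = truth.bin_copy_numbers(bins)
    baseline = np.array([truth.normal_copy(c) for c in bins.table["chrom"]], dtype=float)
    mix = spec.fraction * n_bin + (1.0 - spec.fraction) * baseline
    rate = bins.widths.astype(float) * mix
    if gc_bias_strength != 0:
        factor = 1.0 + gc_bias_strength * (np.where(np.isfinite(gc), gc, 0.5) - 0.5)
        if (factor < 0).any():
            logger.warning("extreme GC bias clipped at zero for %d bins", int((factor < 0).sum()))
            factor = np.clip(factor, 0.0, None)
        rate = rate * factor
    total_target = spec.target_coverage * truth.genome_length / spec.mean_read_length
    rate = rate * (total_target / rate.sum())
    rng = np.random.default_rng([spec.seed, 0x5EED])
    counts = rng.poisson(rate)
    return BinCounts(
        bins=bins,
        count=counts,
        sample_id=sample_id or f"{truth.label}_f{spec.fraction}_cov{spec.target_coverage}",
        total_reads=int(counts.sum()),
        mean_read_length=spec.mean_read_length,
    )


def expected_normal_counts(bins: GenomeBins, sex: str = "male",
                           total_reads: float = 1e6) -> BinCounts:
    """Noiseless copy-neutral reference counts (ideal panel of normals).

    Expected counts proportional to bin width times the sex baseline copy
    number; used as the normalization reference for simulated samples.
    """
    baseline = np.array(
        [1.0 if (c in _X_NAMES and sex == "male") else 2.0 for c in bins.table["chrom"]]
    )
    rate = bins.widths.astype(float) * baseline
    counts = rate * (total_reads / rate.sum())
    return BinCounts(bins=bins, count=counts, sample_id=f"expected_normal_{sex}",
                     total_reads=int(round(total_reads)))


def simulate_normal_panel(
    bins: GenomeBins, n_samples: int = 5, sex: str = "male",
    coverage: float = 0.5, seed: int = 0,
    read_length: float = DEFAULT_READ_LENGTH,
) -> list[BinCounts]:
    """Simulated copy-neutral control samples on a shared grid (sex-matched)."""
    sizes = bins.chrom_lengths
    flat = TruthProfile(
        intervals=pd.DataFrame(columns=["chrom", "start", "end", "cn"]),
        chrom_sizes=sizes, sex=sex, label=f"normal_{sex}",
    )
    panel = []
    for i in range(n_samples):
        spec = DilutionSpec(fraction=0.0, target_coverage=coverage,
                            mean_read_length=read_length, seed=seed * 1000 + i)
        panel.append(simulate_counts(flat, spec, bins, sample_id=f"control_{sex}_{i}"))
    return panel


def in_silico_mix(
    tumor: BinCounts, normal: BinCounts, f: float, total_reads: int, seed: int = 0
) -> BinCounts:
    """Mix two count profiles at tumor fraction ``f`` by binomial thinning.

    ``round(f * total_reads)`` reads are thinned from the tumor sample and
    the remainder from the normal; per-bin draws are independent binomials
    with the matching thinning probability.
    """
    if not tumor.bins.same_grid(normal.bins):
        raise ValueError("tumor and normal counts must share a bin grid")
    if not 0 <= f <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    n_tumor = int(round(f * total_reads))
    n_normal = total_reads - n_tumor
    t_avail = int(tumor.count.sum())
    n_avail = int(normal.count.sum())
    if n_tumor > t_avail or n_normal > n_avail:
        raise ValueError(
            f"requested {n_tumor} tumor + {n_normal} normal reads but only "
            f"{t_avail} + {n_avail} available"
        )
    rng = np.random.default_rng([seed, 0x111])
    p_t = n_tumor / t_avail if t_avail else 0.0
    p_n = n_normal / n_avail if n_avail else 0.0
    mixed = rng.binomial(tumor.count.astype(int), p_t) + rng.binomial(
        normal.count.astype(int), p_n
    )
    read_len = f * tumor.mean_read_length + (1 - f) * normal.mean_read_length
    return BinCounts(
        bins=tumor.bins, count=mixed,
        sample_id=f"mix_f{f}_{tumor.sample_id}_{normal.sample_id}",
        total_reads=int(mixed.sum()), mean_read_length=read_len,
    )


def downsample(counts: BinCounts, target_reads: int, seed: int = 0,
               allow_unchanged: bool = False) -> BinCounts:
    """Binomial thinning of a count profile to ~target_reads total."""
    if target_reads > counts.total_reads:
        if allow_unchanged:
            return counts
        raise ValueError(
            f"target {target_reads} exceeds available {counts.total_reads} reads"
        )
    p = target_reads / counts.total_reads
    rng = np.random.default_rng([seed, 0x222])
    thinned = rng.binomial(counts.count.astype(int), p)
    return BinCounts(
        bins=counts.bins, count=thinned, sample_id=counts.sample_id,
        total_reads=int(thinned.sum()), mean_read_length=counts.mean_read_length,
    )


def assign_synthetic_gc(bins: GenomeBins, seed: int = 0,
                        mean: float = 0.41, sd: float = 0.05) -> GenomeBins:
    """Attach smooth synthetic per-bin GC values (for GC-bias experiments)."""
    from dataclasses import replace

    rng = np.random.default_rng([seed, 0x6C])
    raw = rng.normal(0.0, 1.0, bins.n_bins)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(raw, kernel, mode="same")
    gc = np.clip(mean + sd * smooth, 0.2, 0.8)
    table = bins.table.copy()
    table["gc"] = gc
    return replace(bins, table=table)


def make_fixture_suite(out_dir, seed: int = 0,
                       fractions=DILUTION_FRACTIONS,
                       coverage: float = 0.1,
                       scale: int = DEFAULT_GENOME_SCALE,
                       bin_width: int = 100_000) -> list[Path]:
    """Write a deterministic dilution-grid fixture set (truths + counts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    truths = {"mcrpc": mcrpc_like(scale), "vcap": vcap_like(scale), "umuc5": umuc5_like(scale)}
    for name, truth in truths.items():
        truth_path = out / f"{name}.truth.json"
        truth_path.write_text(json.dumps(truth.to_dict(), indent=1))
        written.append(truth_path)
        bins = make_bins(truth.chrom_sizes, bin_width)
        for f in fractions:
            spec = DilutionSpec(fraction=f, target_coverage=coverage,
                                seed=seed * 100 + int(round(f * 1000)))
            counts = simulate_counts(truth, spec, bins, sample_id=f"{name}_f{f:g}")
            path = out / f"{name}_f{f:g}_cov{coverage:g}.counts.tsv"
            write_counts_table(counts, path)
            written.append(path)
    return written
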