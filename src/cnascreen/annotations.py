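"""GRCh37 reference annotation tables.

Chromosome lengths, centromere positions (for p/q arm intervals) and a small
panel of cancer genes relevant to copy-number screening of cfDNA.  These are
reference annotation, shipped in-code so the package needs no downloads; the
gene intervals are approximate hg19 gene spans, adequate for >=1 bp overlap
annotation against >=100 kb bins.

All coordinates are 0-based half-open.  ``scale`` arguments divide every
coordinate by an integer factor, producing the proportionally shrunk genome
used by the desk-scale simulator (see :mod:`cnascreen.simulate`).
"""

from __future__ import annotations

import pandas as pd

# hg19 chromosome lengths, autosomes + X (chrY and alt/decoy contigs are
# excluded from analysis by default: Y is unreliable at ultra-low coverage,
# while X carries AR and must stay).
GRCH37_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560,
}

# Approximate hg19 centromere midpoints (p/q boundary), in bp.
GRCH37_CENTROMERES: dict[str, int] = {
    "chr1": 125000000, "chr2": 93300000, "chr3": 91000000,
    "chr4": 50400000, "chr5": 48400000, "chr6": 61000000,
    "chr7": 59900000, "chr8": 45600000, "chr9": 49000000,
    "chr10": 40200000, "chr11": 53700000, "chr12": 35800000,
    "chr13": 17900000, "chr14": 17600000, "chr15": 19000000,
    "chr16": 36600000, "chr17": 24000000, "chr18": 17200000,
    "chr19": 26500000, "chr20": 27500000, "chr21": 13200000,
    "chr22": 14700000, "chrX": 60600000,
}

# Approximate hg19 gene spans (chrom, start, end).
GRCH37_GENES: dict[str, tuple[str, int, int]] = {
    "AR": ("chrX", 66764465, 66950461),
    "PTEN": ("chr10", 89623195, 89728532),
    "RB1": ("chr13", 48877887, 49056122),
    "EGFR": ("chr7", 55086714, 55324313),
    "FGFR1": ("chr8", 38268656, 38326352),
    "MYC": ("chr8", 128748315, 128753680),
    "BRCA1": ("chr17", 41196312, 41277500),
    "BRCA2": ("chr13", 32889611, 32973805),
    "TP53": ("chr17", 7571720, 7590868),
    "ERG": ("chr21", 39751949, 40033704),
    "TMPRSS2": ("chr21", 42836478, 42903043),
}

# Interstitial 21q22.2-3 span between ERG and TMPRSS2 whose deletion is the
# copy-number proxy for the TMPRSS2:ERG fusion in prostate cancer.
ERG_TMPRSS2_SPAN: tuple[str, int, int] = ("chr21", 39751949, 42903043)


def chrom_sizes(scale: int = 1) -> dict[str, int]:
    """Autosome+X chromosome lengths, optionally shrunk by ``scale``."""
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    return {c: length // scale for c, length in GRCH37_CHROM_LENGTHS.items()}


def gene_table(scale: int = 1) -> pd.DataFrame:
    """BED-like gene interval table: chrom, start, end, name."""
    rows = [
        (chrom, start // scale, max(end // scale, start // scale + 1), name)
        for name, (chrom, start, end) in GRCH37_GENES.items()
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def arm_table(scale: int = 1) -> pd.DataFrame:
    """BED-like chromosome-arm table: chrom, start, end, name (e.g. 8q)."""
    rows = []
    for chrom, length in chrom_sizes(scale).items():
        cen = GRCH37_CENTROMERES[chrom] // scale
        short = chrom.removeprefix("chr")
        rows.append((chrom, 0, cen, f"{short}p"))
        rows.append((chrom, cen, length, f"{short}q"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def erg_tmprss2_interval(scale: int = 1) -> tuple[str, int, int]:
    chrom, start, end = ERG_TMPRSS2_SPAN
    return chrom, start // scale, end // scale


def write_bed(table: pd.DataFrame, path) -> None:
    """Write a chrom/start/end[/name] table as 0-based BED."""
    table.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED into a chrom/start/end/name table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name="")
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = ""
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df
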