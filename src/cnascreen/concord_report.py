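"""Profile concordance, gene-level comparison, variant fractions and the
per-sample JSON report.

Two segmented profiles (e.g. cfDNA WGS vs tissue exome copy number) are
compared by projecting each onto a common fixed-width grid — every grid bin
takes the mean of the segment covering its midpoint — and correlating the
unmasked bins.  Gene-level comparison against a targeted-NGS log2 table is
restricted to genes the targeted assay calls confidently (|log2| >= 0.5).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cna_calls import FGAResult, FocalCNA
from .segment import SegmentedProfile
from .tumor_content import TumorContentEstimate

logger = logging.getLogger(__name__)

DEFAULT_GRID_WIDTH = 1_000_000
GENE_LEVEL_MIN_ABS_LOG2 = 0.5
REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class PairedGrid:
    """Two profiles projected onto one grid; masked bins are excluded."""

    table: pd.DataFrame  # chrom, start, end, value_a, value_b, mask (True = keep)

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.table[self.table["mask"]]


def _midpoint_lookup(profile: SegmentedProfile, chrom: str, midpoints: np.ndarray) -> np.ndarray:
    """Segment mean at each midpoint, NaN where no segment covers it."""
    out = np.full(len(midpoints), np.nan)
    segs = profile.segments
    on_chrom = segs[segs["chrom"] == chrom]
    for _, seg in on_chrom.iterrows():
        inside = (midpoints >= seg["start"]) & (midpoints < seg["end"])
        out[inside] = seg["mean_log2"]
    return out


def project_to_grid(
    a: SegmentedProfile, b: SegmentedProfile, bin_width: int = DEFAULT_GRID_WIDTH
) -> PairedGrid:
    """Project two segmented profiles onto a shared fixed-width grid."""
    chroms_a = set(a.segments["chrom"])
    chroms_b = set(b.segments["chrom"])
    shared = [c for c in dict.fromkeys(a.segments["chrom"]) if c in chroms_b]
    if not shared:
        raise ValueError(
            f"profiles share no chromosomes (a: {sorted(chroms_a)[:4]}, b: {sorted(chroms_b)[:4]})"
        )
    rows = []
    for chrom in shared:
        end_a = a.segments.loc[a.segments["chrom"] == chrom, "end"].max()
        end_b = b.segments.loc[b.segments["chrom"] == chrom, "end"].max()
        length = int(min(end_a, end_b))
        edges = np.arange(0, length + bin_width, bin_width)
        edges[-1] = min(edges[-1], length)
        if len(edges) > 1 and edges[-1] == edges[-2]:
            edges = edges[:-1]
        starts, ends = edges[:-1], edges[1:]
        mids = (starts + ends) / 2
        va = _midpoint_lookup(a, chrom, mids)
        vb = _midpoint_lookup(b, chrom, mids)
        for s, e, x, y in zip(starts, ends, va, vb):
            rows.append((chrom, int(s), int(e), x, y, bool(np.isfinite(x) and np.isfinite(y))))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "value_a", "value_b", "mask"])
    if not table["mask"].any():
        raise ValueError("no grid bin is covered by both profiles")
    return PairedGrid(table=table)


def profile_correlation(grid: PairedGrid, min_bins: int = 10) -> tuple[float, int]:
    """Pearson r over unmasked grid bins; NaN when either side is constant."""
    kept = grid.unmasked
    n = len(kept)
    if n < min_bins:
        raise ValueError(f"need >= {min_bins} unmasked bins, have {n}")
    x = kept["value_a"].to_numpy()
    y = kept["value_b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in one profile; correlation undefined")
        return float("nan"), n
    r = stats.pearsonr(x, y).statistic
    return float(r), n


def gene_level_compare(
    wgs: SegmentedProfile,
    targeted: pd.DataFrame,
    genes: pd.DataFrame,
    min_abs_log2: float = GENE_LEVEL_MIN_ABS_LOG2,
) -> tuple[pd.DataFrame, float, float]:
    """Compare WGS segment means with a targeted gene-level log2 table.

    ``targeted`` has columns gene, log2ratio; ``genes`` maps gene names to
    intervals.  Returns (paired table over genes with |targeted| >= cutoff,
    Pearson r, direction agreement fraction).
    """
    if not {"gene", "log2ratio"} <= set(targeted.columns):
        raise ValueError("targeted table needs gene and log2ratio columns")
    gene_pos = {row["name"]: row for _, row in genes.iterrows()}
    rows = []
    for _, rec in targeted.iterrows():
        name = rec["gene"]
        if name not in gene_pos:
            logger.info("gene %s absent from the interval annotation; dropped", name)
            continue
        pos = gene_pos[name]
        mid = np.array([(pos["start"] + pos["end"]) / 2])
        wgs_value = _midpoint_lookup(wgs, pos["chrom"], mid)[0]
        if not np.isfinite(wgs_value):
            logger.info("gene %s not covered by a WGS segment; dropped", name)
            continue
        rows.append((name, float(rec["log2ratio"]), float(wgs_value)))
    paired = pd.DataFrame(rows, columns=["gene", "targeted_log2", "wgs_log2"])
    paired = paired[np.abs(paired["targeted_log2"]) >= min_abs_log2].reset_index(drop=True)
    if len(paired) < 2:
        return paired, float("nan"), float("nan")
    r = float(stats.pearsonr(paired["targeted_log2"], paired["wgs_log2"]).statistic)
    agreement = float(
        np.mean(np.sign(paired["targeted_log2"]) == np.sign(paired["wgs_log2"]))
    )
    return paired, r, agreement


def variant_fraction(alt_reads: int, total_reads: int) -> float:
    """Variant fraction as a percentage, half-away-from-zero to 1 decimal.

    E.g. 105 variant-supporting of 504 covering reads -> 20.8.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError("alt_reads must lie in [0, total_reads]")
    pct = Decimal(100 * alt_reads) / Decimal(total_reads)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def render_report(
    sample_id: str,
    profile,
    segments: SegmentedProfile,
    tc: TumorContentEstimate,
    focal_calls: list[FocalCNA],
    fga: FGAResult,
    arm_status: dict[str, str] | None = None,
    t21q_deletion: bool | None = None,
    parameters: dict | None = None,
) -> dict:
    """Assemble the per-sample JSON report (bin/segment tables + events)."""
    for obj, label in ((profile, "profile"), (segments, "segments")):
        if obj is not None and getattr(obj, "sample_id", sample_id) != sample_id:
            raise ValueError(f"{label} sample_id {obj.sample_id!r} != {sample_id!r}")
    bins_table = []
    if profile is not None:
        tbl = profile.bins.table
        usable = profile.usable
        for i in np.flatnonzero(usable):
            bins_table.append(
                {
                    "chrom": str(tbl.iloc[i]["chrom"]),
                    "start": int(tbl.iloc[i]["start"]),
                    "end": int(tbl.iloc[i]["end"]),
                    "log2ratio": float(profile.log2ratio[i]),
                }
            )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "sample_id": sample_id,
        "parameters": parameters or {},
        "bins": bins_table,
        "segments": segments.segments.to_dict(orient="records"),
        "tumor_content": tc.to_dict(),
        "focal_calls": [c.to_dict() for c in focal_calls],
        "fga": fga.to_dict(),
        "arm_status": arm_status or {},
        "t21q_deletion": t21q_deletion,
    }
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Check the report against the versioned schema (required keys/types)."""
    schema = {
        "schema_version": str, "sample_id": str, "parameters": dict,
        "bins": list, "segments": list, "tumor_content": dict,
        "focal_calls": list, "fga": dict, "arm_status": dict,
    }
    for key, typ in schema.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for key in ("lss", "tc_fit", "classification"):
        if key not in report["tumor_content"]:
            raise ValueError(f"tumor_content missing {key!r}")
    if "fga" not in report or "fga" not in report["fga"]:
        raise ValueError("fga block missing its value")
    json.dumps(report)  # must be serializable
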