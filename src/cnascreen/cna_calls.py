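"""Focal, arm-level and deep-deletion CNA calling from segmented profiles.

Focal CNAs are segments 1.5-20 Mb long with |log2 ratio| >= 0.2 (bounds
inclusive, the symmetric threshold applied to losses so that focal deep
deletions are expressible).  Deep (2-copy) deletions are focal losses whose
nearest integer copy state at the fitted tumor fraction is 0.  Arm-level
status requires at least half an arm's length inside concordantly altered
segments.  The fraction of genome altered (FGA) is the length share of
segments beyond the log2 cutoff; above 15% a sample counts as having
elevated copy-number burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import SegmentedProfile
from .tumor_content import expected_log2

logger = logging.getLogger(__name__)

FOCAL_MIN_LEN = 1_500_000
FOCAL_MAX_LEN = 20_000_000
FOCAL_MIN_ABS_LOG2 = 0.2
ARM_MIN_FRAC = 0.5
ARM_MIN_ABS_LOG2 = 0.1
FGA_LOG2_CUTOFF = 0.2
FGA_ELEVATED_THRESHOLD = 0.15
_X_NAMES = frozenset({"chrX", "X"})


@dataclass
class FocalCNA:
    """One focal gain or loss with optional gene and copy-state annotation."""

    chrom: str
    start: int
    end: int
    mean_log2: float
    direction: str  # "gain" | "loss"
    genes: list[str] = field(default_factory=list)
    copy_state: int | None = None
    deep_deletion: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "start": int(self.start), "end": int(self.end),
            "mean_log2": float(self.mean_log2), "direction": self.direction,
            "genes": list(self.genes), "copy_state": self.copy_state,
            "deep_deletion": bool(self.deep_deletion),
        }


@dataclass
class FGAResult:
    fga: float
    log2_cutoff: float
    elevated: bool

    def to_dict(self) -> dict:
        return {"fga": self.fga, "log2_cutoff": self.log2_cutoff, "elevated": self.elevated}


def call_focal(
    profile: SegmentedProfile,
    min_len: int = FOCAL_MIN_LEN,
    max_len: int = FOCAL_MAX_LEN,
    min_abs_log2: float = FOCAL_MIN_ABS_LOG2,
) -> list[FocalCNA]:
    """Segments with min_len <= length <= max_len and |mean| >= threshold."""
    calls = []
    for _, seg in profile.segments.iterrows():
        length = seg["end"] - seg["start"]
        if not (min_len <= length <= max_len):
            continue
        if seg["mean_log2"] >= min_abs_log2:
            direction = "gain"
        elif seg["mean_log2"] <= -min_abs_log2:
            direction = "loss"
        else:
            continue
        calls.append(
            FocalCNA(
                chrom=seg["chrom"], start=int(seg["start"]), end=int(seg["end"]),
                mean_log2=float(seg["mean_log2"]), direction=direction,
            )
        )
    return calls


def annotate_genes(calls: list[FocalCNA], genes: pd.DataFrame) -> list[FocalCNA]:
    """Attach every gene overlapping a call by >= 1 bp (in place and returned).

    ``genes`` is a chrom/start/end/name table (see annotations.read_bed).
    """
    known_chroms = set(genes["chrom"])
    for call in calls:
        on_chrom = genes[genes["chrom"] == call.chrom]
        if call.chrom not in known_chroms:
            logger.debug("no annotated genes on %s", call.chrom)
        hits = on_chrom[(on_chrom["start"] < call.end) & (on_chrom["end"] > call.start)]
        call.genes = list(hits["name"])
    return calls


def classify_deep_deletion(call: FocalCNA, tc_fit: float, sex: str = "male",
                           n_max: int = 8) -> bool:
    """Deep (2-copy) iff the nearest integer state at tc_fit is n = 0."""
    if call.direction != "loss":
        return False
    if tc_fit <= 0:
        logger.warning("deep-deletion classification needs tc_fit > 0; returning False")
        return False
    normal = 1 if (call.chrom in _X_NAMES and sex == "male") else 2
    states = np.arange(0, n_max + 1)
    levels = expected_log2(states, tc_fit, normal_copy=normal)
    nearest = int(states[np.argmin(np.abs(call.mean_log2 - levels))])
    return nearest == 0


def assign_copy_states(calls: list[FocalCNA], tc_fit: float, sex: str = "male",
                       n_max: int = 40) -> list[FocalCNA]:
    """Set the nearest integer copy state (and deep-deletion flag) per call."""
    for call in calls:
        if tc_fit <= 0:
            call.copy_state = None
            continue
        normal = 1 if (call.chrom in _X_NAMES and sex == "male") else 2
        states = np.arange(0, n_max + 1)
        levels = expected_log2(states, tc_fit, normal_copy=normal)
        call.copy_state = int(states[np.argmin(np.abs(call.mean_log2 - levels))])
        call.deep_deletion = call.direction == "loss" and call.copy_state == 0
    return calls


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def arm_level_events(
    profile: SegmentedProfile,
    arms: pd.DataFrame,
    min_frac: float = ARM_MIN_FRAC,
    min_abs_log2: float = ARM_MIN_ABS_LOG2,
) -> dict[str, str]:
    """Per-arm status: gain/loss when >= min_frac of the arm length lies in
    segments at or beyond +/- min_abs_log2, else neutral."""
    if min_frac < 0.5:
        raise ValueError("min_frac must be >= 0.5 so gain and loss are exclusive")
    status: dict[str, str] = {}
    segs = profile.segments
    for _, arm in arms.iterrows():
        arm_len = arm["end"] - arm["start"]
        if arm_len <= 0:
            continue
        on_chrom = segs[segs["chrom"] == arm["chrom"]]
        gained = lost = 0
        for _, seg in on_chrom.iterrows():
            ov = _overlap(seg["start"], seg["end"], arm["start"], arm["end"])
            if ov == 0:
                continue
            if seg["mean_log2"] >= min_abs_log2:
                gained += ov
            elif seg["mean_log2"] <= -min_abs_log2:
                lost += ov
        if gained >= min_frac * arm_len:
            status[arm["name"]] = "gain"
        elif lost >= min_frac * arm_len:
            status[arm["name"]] = "loss"
        else:
            status[arm["name"]] = "neutral"
    return status


def detect_21q_deletion(
    profile: SegmentedProfile,
    interval: tuple[str, int, int],
    min_abs_log2: float = ARM_MIN_ABS_LOG2,
    min_overlap_frac: float = 0.5,
) -> bool:
    """Interstitial 21q22.2 loss consistent with a TMPRSS2:ERG-type fusion.

    True when loss segments (mean <= -min_abs_log2) cover at least half of
    the ERG-TMPRSS2 interval.
    """
    chrom, start, end = interval
    span = end - start
    if span <= 0:
        raise ValueError("empty 21q interval")
    segs = profile.segments
    on_chrom = segs[segs["chrom"] == chrom]
    covered = 0
    for _, seg in on_chrom.iterrows():
        if seg["mean_log2"] <= -min_abs_log2:
            covered += _overlap(seg["start"], seg["end"], start, end)
    return covered >= min_overlap_frac * span


def compute_fga(profile: SegmentedProfile, log2_cutoff: float = FGA_LOG2_CUTOFF) -> FGAResult:
    """Fraction of segmented genome length with |mean log2| >= cutoff."""
    lengths = profile.lengths
    total = lengths.sum()
    if total <= 0:
        raise ValueError("cannot compute FGA on a zero-length profile")
    means = profile.segments["mean_log2"].to_numpy()
    altered = lengths[np.abs(means) >= log2_cutoff].sum()
    fga = float(altered / total)
    return FGAResult(fga=fga, log2_cutoff=log2_cutoff, elevated=fga > FGA_ELEVATED_THRESHOLD)


def calls_to_bed(calls: list[FocalCNA]) -> pd.DataFrame:
    """Focal calls as a 0-based BED table: name=direction:genes, score=1000*|mean| capped."""
    rows = []
    for c in calls:
        name = c.direction + (":" + ",".join(c.genes) if c.genes else "")
        score = int(min(1000, round(1000 * abs(c.mean_log2))))
        rows.append((c.chrom, c.start, c.end, name, score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
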