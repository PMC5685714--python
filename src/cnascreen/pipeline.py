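"""End-to-end convenience chains: counts -> profile -> segments -> calls.

These helpers wire the module stages together for the CLI, the simulator
experiments and the acceptance checks; every stage remains usable on its
own.
"""

from __future__ import annotations

import logging

import numpy as np

from . import annotations
from .cna_calls import (
    annotate_genes,
    arm_level_events,
    assign_copy_states,
    call_focal,
    compute_fga,
    detect_21q_deletion,
)
from .concord_report import render_report
from .genome_bins import BinCounts, make_bins
from .normalize import CopyRatioProfile, choose_bin_width, correct_gc, to_log2ratio
from .segment import SegmentedProfile, cbs_segment
from .simulate import (
    DEFAULT_READ_LENGTH,
    DilutionSpec,
    TruthProfile,
    expected_normal_counts,
    simulate_counts,
)
from .tumor_content import CalibrationCurve, estimate_tumor_content

logger = logging.getLogger(__name__)


def profile_counts(
    counts: BinCounts,
    panel: list[BinCounts] | None = None,
    reference_counts: BinCounts | None = None,
    gc_correction: bool | None = None,
    sex: str = "male",
) -> CopyRatioProfile:
    """GC-correct (when GC is annotated) and normalize to log2 ratios.

    Without a panel or explicit reference, the sex-matched copy-neutral
    expectation is used so male chrX centers at zero rather than -1.
    """
    gc = counts.bins.table["gc"].to_numpy()
    usable = counts.bins.table["usable"].to_numpy()
    have_gc = int((usable & np.isfinite(gc)).sum()) >= 100
    if gc_correction is None:
        gc_correction = have_gc
    if gc_correction:
        counts = correct_gc(counts)
    if panel is None and reference_counts is None:
        reference_counts = expected_normal_counts(
            counts.bins, sex=sex, total_reads=max(counts.total_reads, 1)
        )
    return to_log2ratio(counts, panel=panel, reference_counts=reference_counts)


def annotation_scale_for(chrom_sizes: dict[str, int]) -> int:
    """Infer the integer shrink factor of a scaled GRCh37 genome."""
    ref = annotations.GRCH37_CHROM_LENGTHS
    chrom = next(iter(chrom_sizes))
    if chrom not in ref:
        raise ValueError(f"chromosome {chrom!r} is not a GRCh37 autosome/X name")
    return max(1, round(ref[chrom] / chrom_sizes[chrom]))


def analyze_sample(
    counts: BinCounts,
    sex: str = "male",
    panel: list[BinCounts] | None = None,
    reference_counts: BinCounts | None = None,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    curve: CalibrationCurve | None = None,
    genes=None,
    arms=None,
    t21_interval: tuple[str, int, int] | None = None,
    annotation_scale: int | None = None,
) -> dict:
    """Run the full screening chain on one count profile.

    Returns a bundle dict with keys counts, profile, segments, tc,
    focal_calls, arm_status, t21q_deletion, fga and report.  Gene/arm
    annotation defaults to the (scaled) GRCh37 tables matching the count
    grid's genome.
    """
    if annotation_scale is None:
        try:
            annotation_scale = annotation_scale_for(counts.bins.chrom_lengths)
        except ValueError:
            annotation_scale = None
    if genes is None and annotation_scale is not None:
        genes = annotations.gene_table(annotation_scale)
    if arms is None and annotation_scale is not None:
        arms = annotations.arm_table(annotation_scale)
    if t21_interval is None and annotation_scale is not None:
        t21_interval = annotations.erg_tmprss2_interval(annotation_scale)

    profile = profile_counts(counts, panel=panel, reference_counts=reference_counts, sex=sex)
    segments = cbs_segment(profile, alpha=alpha, n_perm=n_perm, seed=seed)
    tc = estimate_tumor_content(segments, sex=sex, curve=curve)
    focal = call_focal(segments)
    if genes is not None:
        annotate_genes(focal, genes)
    assign_copy_states(focal, tc.tc_fit, sex=sex)
    arm_status = arm_level_events(segments, arms) if arms is not None else {}
    t21q = detect_21q_deletion(segments, t21_interval) if t21_interval is not None else None
    fga = compute_fga(segments)
    report = render_report(
        sample_id=counts.sample_id,
        profile=profile,
        segments=segments,
        tc=tc,
        focal_calls=focal,
        fga=fga,
        arm_status=arm_status,
        t21q_deletion=t21q,
        parameters={"alpha": alpha, "n_perm": n_perm, "seed": seed, "sex": sex},
    )
    return {
        "counts": counts,
        "profile": profile,
        "segments": segments,
        "tc": tc,
        "focal_calls": focal,
        "arm_status": arm_status,
        "t21q_deletion": t21q,
        "fga": fga,
        "report": report,
    }


def simulate_sample(
    truth: TruthProfile,
    fraction: float,
    coverage: float,
    seed: int = 0,
    bin_width: int | None = None,
    gc_bias_strength: float = 0.0,
    read_length: float = DEFAULT_READ_LENGTH,
    min_mean_reads_per_bin: float = 30.0,
) -> tuple[BinCounts, BinCounts]:
    """Simulate one dilution sample plus its matched noiseless reference.

    The bin width adapts to the expected read yield unless given explicitly.
    """
    expected_reads = coverage * truth.genome_length / read_length
    if bin_width is None:
        bin_width = choose_bin_width(
            int(round(expected_reads)),
            genome_length=truth.genome_length,
            min_mean_reads_per_bin=min_mean_reads_per_bin,
        )
    bins = make_bins(truth.chrom_sizes, bin_width)
    if gc_bias_strength != 0:
        from .simulate import assign_synthetic_gc

        bins = assign_synthetic_gc(bins, seed=seed)
    spec = DilutionSpec(
        fraction=fraction, target_coverage=coverage,
        mean_read_length=read_length, seed=seed,
    )
    counts = simulate_counts(truth, spec, bins, gc_bias_strength=gc_bias_strength)
    reference = expected_normal_counts(bins, sex=truth.sex,
                                       total_reads=max(counts.total_reads, 1))
    return counts, reference


def simulate_and_analyze(
    truth: TruthProfile,
    fraction: float,
    coverage: float,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Simulate a dilution sample and run the full analysis chain on it."""
    sim_keys = {"bin_width", "gc_bias_strength", "read_length", "min_mean_reads_per_bin"}
    sim_kwargs = {k: v for k, v in kwargs.items() if k in sim_keys}
    ana_kwargs = {k: v for k, v in kwargs.items() if k not in sim_keys}
    counts, reference = simulate_sample(truth, fraction, coverage, seed=seed, **sim_kwargs)
    return analyze_sample(counts, sex=truth.sex, reference_counts=reference,
                          seed=seed, **ana_kwargs)


def lss_simulator_handle(truth: TruthProfile, coverage: float, **kwargs):
    """A ``(fraction, seed) -> LSS`` callable for calibration-curve building."""

    def handle(fraction: float, seed: int) -> float:
        bundle = simulate_and_analyze(truth, fraction, coverage, seed=seed, **kwargs)
        return bundle["tc"].lss

    return handle
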