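"""Tumor-fraction approximation from segmented copy-number profiles.

Two complementary estimators operate on the segment means of a profile:

* **LSS** — the length-weighted root-mean-square deviation of segment means
  from copy-neutral, ``sqrt(sum_s w_s * mean_s^2)`` with ``w_s`` the segment
  length over the segmented genome length.  It is a monotone proxy for
  tumor content; samples with LSS >= 0.1 (about 8.75% tumor content via the
  simulation-built calibration curve) are classified high tumor content.
* **Grid fit** — a two-component mixture model: a segment at tumor integer
  copy ``n`` in a sample with tumor fraction ``f`` sits at

      log2( (f*n + N*(1-f)) / N ),

  with normal copy ``N`` = 2 on autosomes and 1 on chrX for male samples.
  For each ``f`` on a grid, each segment takes the integer copy state
  minimizing its squared deviation from the model level, and ``f`` is chosen
  from the residual curve.

The mixture model is not identifiable from the residual alone: any solution
``(f, {n_s})`` has exact harmonics ``(f/k, {k*(n_s - N) + N})``, and as
``f -> 0`` the level grid becomes dense enough to over-fit noise.  The fit
therefore (a) adds a penalty for every segment assigned a non-neutral state,
scaled to the segment's sampling noise (``kappa * sd^2 / n_bins`` when the
profile carries a bin-noise estimate), which keeps segments below their own
detection floor from being chased by the dense small-``f`` grids, (b)
forbids the homozygous state n = 0 on segments spanning more than 2.5% of
the genome — homozygous deletions are focal events, and it is exactly the
whole-chromosome n = 0 assignment that every down-harmonic of a one-copy
loss requires — (c) takes the smallest ``f`` within 5% of the optimal
penalized residual that is itself a local minimum of the residual curve
(the 5% band's lower edge sits on a slope and would bias the estimate
down), and (d) resolves exactly tied residuals (the
signature of a single fitted segment, whose amplitude alone cannot separate
``f`` from its level family) by the least genome weight assigned n = 0,
then by proximity to the LSS-implied tumor content, a coarse but
independent prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .segment import SegmentedProfile

logger = logging.getLogger(__name__)

LSS_HIGH_THRESHOLD = 0.1
LSS_ANCHOR_TC = 0.0875  # tumor content mapped to the LSS decision threshold
DEFAULT_N_MAX = 40
DEFAULT_F_GRID_STEP = 0.005
DEFAULT_F_MAX = 0.95
DEFAULT_SLACK = 0.05
DEFAULT_STATE_PENALTY = 1e-4  # squared-log2 units per unit weight (fallback)
DEFAULT_STATE_PENALTY_KAPPA = 6.0  # penalty in units of segment-mean variance
DEFAULT_DEEP_DEL_MAX_FRAC = 0.025  # n=0 only on segments below this genome share
EXPECTED_LOG2_FLOOR = -8.0
_X_NAMES = frozenset({"chrX", "X"})


def expected_log2(n, f: float, normal_copy: int = 2):
    """Model log2 ratio of a segment at tumor copy ``n``, tumor fraction ``f``.

    ``log2((f*n + normal_copy*(1-f)) / normal_copy)``, clamped below at -8
    (the n = 0, f = 1 sentinel).  ``n`` may be an array.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"tumor fraction must lie in [0, 1], got {f}")
    if normal_copy not in (1, 2):
        raise ValueError("normal_copy must be 1 (male X) or 2")
    n = np.asarray(n, dtype=float)
    if (n < 0).any():
        raise ValueError("copy number must be >= 0")
    mix = (f * n + normal_copy * (1.0 - f)) / normal_copy
    with np.errstate(divide="ignore"):
        out = np.maximum(np.log2(mix), EXPECTED_LOG2_FLOOR)
    return float(out) if out.ndim == 0 else out


def compute_lss(profile: SegmentedProfile) -> float:
    """Length-weighted RMS deviation of segment means from copy-neutral."""
    if len(profile.segments) == 0 or profile.total_length <= 0:
        raise ValueError("cannot compute LSS on an empty profile")
    means = profile.segments["mean_log2"].to_numpy()
    return float(np.sqrt(np.sum(profile.weights * means**2)))


def classify_tumor_content(lss: float) -> str:
    """``high`` iff LSS >= 0.1, else ``low`` (exact at the threshold)."""
    return "high" if lss >= LSS_HIGH_THRESHOLD else "low"


def _segment_normal_copies(profile: SegmentedProfile, sex: str) -> np.ndarray:
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    on_x = profile.segments["chrom"].isin(_X_NAMES).to_numpy()
    return np.where(on_x & (sex == "male"), 1, 2)


def fit_tumor_fraction(
    profile: SegmentedProfile,
    sex: str = "male",
    f_step: float = DEFAULT_F_GRID_STEP,
    f_max: float = DEFAULT_F_MAX,
    n_max: int = DEFAULT_N_MAX,
    slack: float = DEFAULT_SLACK,
    state_penalty: float = DEFAULT_STATE_PENALTY,
    state_penalty_kappa: float = DEFAULT_STATE_PENALTY_KAPPA,
    deep_del_max_frac: float = DEFAULT_DEEP_DEL_MAX_FRAC,
    neutral_dominance: float = 0.99,
) -> tuple[float, float, np.ndarray]:
    """Fit tumor fraction by penalized least squares on an (f, n) grid.

    Returns ``(tc_fit, fit_residual, assignments)``; assignments are the
    per-segment integer copy states at ``tc_fit`` (the neutral state when
    ``tc_fit`` is 0).  If the chosen fit assigns the neutral state to at
    least 99% of the segmented genome length, ``tc_fit`` is 0.

    When the profile carries a bin-level noise estimate (set by the
    segmenter), the non-neutral state penalty is
    ``state_penalty_kappa * sd^2 / n_bins`` per segment — roughly a 2.4-sigma
    evidence requirement before a segment leaves the neutral state —
    otherwise the flat ``state_penalty`` applies.
    """
    n_seg = len(profile.segments)
    if n_seg == 0:
        raise ValueError("cannot fit tumor fraction on an empty profile")
    if n_seg < 3:
        logger.warning("fitting tumor fraction on only %d segments", n_seg)
    means = profile.segments["mean_log2"].to_numpy()
    weights = profile.weights
    normal = _segment_normal_copies(profile, sex)
    neutral_state = np.where(normal == 1, 1, 2)

    noise_sd = getattr(profile, "bin_noise_sd", None)
    if noise_sd is not None and noise_sd > 0:
        n_bins = np.maximum(profile.segments["n_bins"].to_numpy().astype(float), 1.0)
        penalty = state_penalty_kappa * noise_sd**2 / n_bins
    else:
        penalty = np.full(n_seg, state_penalty)
    no_deep = weights > deep_del_max_frac

    f_grid = np.round(np.arange(0.0, f_max + f_step / 2, f_step), 10)
    n_states = np.arange(0, n_max + 1)
    residuals = np.empty(len(f_grid))
    assignments_by_f = np.empty((len(f_grid), n_seg), dtype=int)
    for fi, f in enumerate(f_grid):
        if f == 0.0:
            assignments_by_f[fi] = neutral_state
            residuals[fi] = float(np.sum(weights * means**2))
            continue
        levels2 = expected_log2(n_states, f, normal_copy=2)
        levels1 = expected_log2(n_states, f, normal_copy=1)
        err2 = (means[:, None] - levels2[None, :]) ** 2
        err1 = (means[:, None] - levels1[None, :]) ** 2
        err = np.where((normal == 1)[:, None], err1, err2)
        err = err + penalty[:, None] * (n_states[None, :] != neutral_state[:, None])
        err[no_deep, 0] = np.inf
        best_n = np.argmin(err, axis=1)
        assignments_by_f[fi] = n_states[best_n]
        residuals[fi] = float(np.sum(weights * err[np.arange(n_seg), best_n]))

    r_min = residuals.min()
    near = residuals <= (1.0 + slack) * r_min
    exact_ties = np.flatnonzero(residuals <= r_min + 1e-12)
    if len(exact_ties) > 1:
        # harmonic families produce exactly tied residuals; prefer members
        # that invoke the homozygous state least, then the one nearest the
        # LSS-implied tumor content (an independent coarse prior)
        deep_weight = np.array(
            [float(np.sum(weights[assignments_by_f[i] == 0])) for i in exact_ties]
        ).round(12)
        lss_guess = (LSS_ANCHOR_TC / LSS_HIGH_THRESHOLD) * float(
            np.sqrt(np.sum(weights * means**2))
        )
        keep = exact_ties[deep_weight == deep_weight.min()]
        dist = np.abs(f_grid[keep] - lss_guess)
        order = np.lexsort((f_grid[keep], np.round(dist, 12)))
        chosen = int(keep[order[0]])
    else:
        candidates = np.flatnonzero(near)
        chosen = int(candidates.min())
        for i in candidates:
            left_ok = i == 0 or residuals[i] <= residuals[i - 1] + 1e-15
            right_ok = i == len(residuals) - 1 or residuals[i] <= residuals[i + 1] + 1e-15
            if left_ok and right_ok:
                chosen = int(i)
                break
    tc_fit = float(f_grid[chosen])
    fit_residual = float(residuals[chosen])
    assignments = assignments_by_f[chosen].copy()

    neutral_weight = float(np.sum(weights[assignments == neutral_state]))
    if tc_fit == 0.0 or neutral_weight >= neutral_dominance:
        return 0.0, float(np.sum(weights * means**2)), neutral_state.copy()
    return tc_fit, fit_residual, assignments


def flag_single_event(
    profile: SegmentedProfile,
    contribution_threshold: float = 0.8,
    max_altered_frac: float = 0.02,
    altered_log2: float = 0.1,
) -> bool:
    """Flag profiles whose LSS is driven by one isolated event.

    True when a single segment contributes more than 80% of the weighted
    squared-mean mass while less than 2% of the genome is non-neutral
    (|mean| >= 0.1) — the signature of, e.g., a lone hematopoietic-origin
    deletion rather than genuine tumor burden.  Flagged samples can be
    reclassified low tumor content by the caller.
    """
    means = profile.segments["mean_log2"].to_numpy()
    w = profile.weights
    contributions = w * means**2
    total = contributions.sum()
    if total <= 0:
        return False
    altered_frac = float(np.sum(w[np.abs(means) >= altered_log2]))
    return bool(contributions.max() > contribution_threshold * total
                and altered_frac < max_altered_frac)


@dataclass
class CalibrationCurve:
    """Monotone LSS -> tumor-content mapping as linear-interpolation knots."""

    lss_knots: np.ndarray
    tc_knots: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lss_knots = np.asarray(self.lss_knots, dtype=float)
        self.tc_knots = np.asarray(self.tc_knots, dtype=float)
        if len(self.lss_knots) != len(self.tc_knots) or len(self.lss_knots) < 2:
            raise ValueError("calibration curve needs >= 2 matched knots")
        if (np.diff(self.lss_knots) <= 0).any() or (np.diff(self.tc_knots) <= 0).any():
            raise ValueError("calibration knots must be strictly increasing in both coordinates")

    def to_dict(self) -> dict:
        return {
            "lss_knots": self.lss_knots.tolist(),
            "tc_knots": self.tc_knots.tolist(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CalibrationCurve":
        return cls(
            lss_knots=np.asarray(payload["lss_knots"]),
            tc_knots=np.asarray(payload["tc_knots"]),
            provenance=payload.get("provenance", {}),
        )


def lss_to_tc(lss: float, curve: CalibrationCurve) -> float:
    """Map an LSS value to tumor content by monotone interpolation."""
    if lss < 0:
        raise ValueError("LSS must be non-negative")
    if lss > curve.lss_knots[-1]:
        logger.warning(
            "LSS %.4f above last calibration knot %.4f; clamping", lss, curve.lss_knots[-1]
        )
        return float(curve.tc_knots[-1])
    return float(np.interp(lss, curve.lss_knots, curve.tc_knots))


def calibrate_lss(
    sample_lss,
    fractions,
    seeds,
    anchor: tuple[float, float] = (LSS_HIGH_THRESHOLD, LSS_ANCHOR_TC),
    provenance: dict | None = None,
) -> CalibrationCurve:
    """Build the LSS -> tumor-content curve from simulated dilutions.

    ``sample_lss(fraction, seed)`` is the simulator handle: it must run the
    full pipeline on one simulated sample and return its LSS.  For every
    fraction the median LSS over ``seeds`` becomes a knot; medians are made
    monotone by isotonic regression (with a warning if that was needed), the
    curve is forced through (0, 0) and the tumor-content axis rescaled so it
    passes through the anchor (LSS 0.1 -> 8.75% by default).
    """
    from scipy.optimize import isotonic_regression

    fractions = sorted(fractions)
    if fractions[0] != 0:
        raise ValueError("calibration fractions must include 0")
    medians = np.array(
        [np.median([sample_lss(f, s) for s in seeds]) for f in fractions]
    )
    iso = isotonic_regression(medians).x
    if not np.allclose(iso, medians):
        logger.warning("non-monotone median LSS across fractions; isotonic regression applied")
    lss_knots = np.concatenate([[0.0], iso[1:] if fractions[0] == 0 else iso])
    tc_knots = np.concatenate([[0.0], np.asarray(fractions[1:], dtype=float)])
    # enforce strict increase (duplicate medians get an epsilon staircase)
    for i in range(1, len(lss_knots)):
        if lss_knots[i] <= lss_knots[i - 1]:
            lss_knots[i] = lss_knots[i - 1] + 1e-9
    anchor_lss, anchor_tc = anchor
    raw_at_anchor = float(np.interp(anchor_lss, lss_knots, tc_knots))
    if anchor_lss > lss_knots[-1]:
        # extrapolate linearly from the last two knots to reach the anchor
        slope = (tc_knots[-1] - tc_knots[-2]) / (lss_knots[-1] - lss_knots[-2])
        raw_at_anchor = tc_knots[-1] + slope * (anchor_lss - lss_knots[-1])
        lss_knots = np.append(lss_knots, anchor_lss)
        tc_knots = np.append(tc_knots, raw_at_anchor)
    if raw_at_anchor <= 0:
        raise ValueError("calibration curve is degenerate at the anchor LSS")
    tc_knots = tc_knots * (anchor_tc / raw_at_anchor)
    return CalibrationCurve(
        lss_knots=lss_knots,
        tc_knots=tc_knots,
        provenance={"fractions": list(map(float, fractions)),
                    "seeds": list(map(int, seeds)),
                    "anchor": [anchor_lss, anchor_tc],
                    **(provenance or {})},
    )


@dataclass
class TumorContentEstimate:
    """Bundle of the LSS- and model-based tumor-content results."""

    lss: float
    tc_fit: float
    fit_residual: float
    assignments: np.ndarray
    classification: str
    single_event_flag: bool
    tc_lss: float | None = None

    def to_dict(self) -> dict:
        return {
            "lss": self.lss,
            "tc_lss": self.tc_lss,
            "tc_fit": self.tc_fit,
            "fit_residual": self.fit_residual,
            "assignments": [int(n) for n in self.assignments],
            "classification": self.classification,
            "single_event_flag": self.single_event_flag,
        }


def estimate_tumor_content(
    profile: SegmentedProfile,
    sex: str = "male",
    curve: CalibrationCurve | None = None,
    reclassify_single_event: bool = False,
    **fit_kwargs,
) -> TumorContentEstimate:
    """Run LSS, classification, artifact flagging and the grid fit together."""
    lss = compute_lss(profile)
    tc_fit, residual, assignments = fit_tumor_fraction(profile, sex=sex, **fit_kwargs)
    flag = flag_single_event(profile)
    classification = classify_tumor_content(lss)
    if flag and reclassify_single_event:
        classification = "low"
    return TumorContentEstimate(
        lss=lss,
        tc_lss=lss_to_tc(lss, curve) if curve is not None else None,
        tc_fit=tc_fit,
        fit_residual=residual,
        assignments=assignments,
        classification=classification,
        single_event_flag=flag,
    )
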