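"""Mixture levels, LSS, tumor-fraction grid fit, calibration and flags."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnascreen.tumor_content import (
    CalibrationCurve,
    calibrate_lss,
    classify_tumor_content,
    compute_lss,
    expected_log2,
    fit_tumor_fraction,
    flag_single_event,
    lss_to_tc,
)


class TestExpectedLog2:
    @pytest.mark.parametrize(
        "n,f,expected",
        [
            (2, 0.0, 0.0),
            (2, 0.7, 0.0),
            (4, 1.0, 1.0),
            (0, 0.5, -1.0),
            (3, 0.2, np.log2(1.1)),
            (0, 1.0, -8.0),  # clamped sentinel
        ],
    )
    def test_reference_points(self, n, f, expected):
        assert expected_log2(n, f) == pytest.approx(expected, abs=1e-12)

    def test_male_x_baseline(self):
        # on male chrX the neutral copy is 1
        assert expected_log2(1, 0.3, normal_copy=1) == 0.0
        assert expected_log2(2, 0.5, normal_copy=1) == pytest.approx(np.log2(1.5))

    @pytest.mark.parametrize("f", [-0.1, 1.5])
    def test_fraction_out_of_range(self, f):
        with pytest.raises(ValueError):
            expected_log2(2, f)

    @given(f=st.floats(0.01, 1.0), n=st.integers(0, 39))
    @settings(max_examples=60, deadline=None)
    def test_strictly_increasing_in_n(self, f, n):
        assert expected_log2(n + 1, f) > expected_log2(n, f) or (
            expected_log2(n, f) == -8.0
        )

    @given(f=st.floats(0.01, 0.98))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_f_around_neutral(self, f):
        step = 0.01
        assert expected_log2(3, f + step) > expected_log2(3, f)  # gains rise
        assert expected_log2(1, f + step) < expected_log2(1, f)  # losses sink


class TestComputeLss:
    def test_flat_profile_zero(self, segments_factory):
        prof = segments_factory([("chr1", 0, 10_000_000, 0.0), ("chr2", 0, 5_000_000, 0.0)])
        assert compute_lss(prof) == 0.0

    def test_single_segment_rms_is_identity(self, segments_factory):
        prof = segments_factory([("chr1", 0, 50_000_000, 0.3)])
        assert compute_lss(prof) == pytest.approx(0.3)

    def test_matches_sum_of_squares_oracle(self, segments_factory, rng):
        rows, lengths, means = [], [], []
        pos = 0
        for _ in range(10):
            length = int(rng.integers(1, 50)) * 1_000_000
            mean = float(rng.normal(0, 0.4))
            rows.append(("chr1", pos, pos + length, mean))
            lengths.append(length)
            means.append(mean)
            pos += length
        prof = segments_factory(rows)
        oracle = np.sqrt(sum(L * m * m for L, m in zip(lengths, means)) / sum(lengths))
        assert compute_lss(prof) == pytest.approx(oracle, abs=1e-12)

    @given(c=st.floats(0.01, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c):
        from conftest import make_segments

        rows = [("chr1", 0, 10_000_000, 0.2), ("chr1", 10_000_000, 30_000_000, -0.1)]
        scaled = [(ch, s, e, c * m) for ch, s, e, m in rows]
        assert compute_lss(make_segments(scaled)) == pytest.approx(
            c * compute_lss(make_segments(rows)), rel=1e-9
        )

    def test_empty_profile_rejected(self, segments_factory):
        import pandas as pd

        from cnascreen.segment import SegmentedProfile

        empty = SegmentedProfile(
            segments=pd.DataFrame(columns=["chrom", "start", "end", "n_bins", "mean_log2"])
        )
        with pytest.raises(ValueError):
            compute_lss(empty)


class TestClassification:
    def test_threshold_exactness(self):
        assert classify_tumor_content(0.1) == "high"
        assert classify_tumor_content(0.0999999999) == "low"
        assert classify_tumor_content(0.5) == "high"
        assert classify_tumor_content(0.0) == "low"


class TestFitTumorFraction:
    def test_flat_profile_zero(self, segments_factory):
        prof = segments_factory([(f"chr{i}", 0, 10_000_000, 0.0) for i in range(1, 6)])
        tc, residual, states = fit_tumor_fraction(prof, sex="female")
        assert tc == 0.0
        assert residual == pytest.approx(0.0, abs=1e-15)
        assert (states == 2).all()

    def test_noiseless_grid_recovery(self, segments_factory):
        """A profile built from the model at f0=0.25 is recovered exactly."""
        f0 = 0.25
        rows = [
            (f"chr{i+1}", 0, 40_000_000, expected_log2(n, f0)) for i, n in enumerate([1, 2, 3, 4])
        ]
        tc, residual, states = fit_tumor_fraction(segments_factory(rows), sex="female")
        assert tc == f0
        assert states.tolist() == [1, 2, 3, 4]

    def test_noiseless_recovery_with_male_x(self, segments_factory):
        f0 = 0.25
        rows = [
            ("chr1", 0, 40_000_000, expected_log2(1, f0)),
            ("chr2", 0, 40_000_000, expected_log2(2, f0)),
            ("chr8", 0, 40_000_000, expected_log2(3, f0)),
            ("chrX", 0, 3_000_000, expected_log2(12, f0, normal_copy=1)),
            ("chrX", 3_000_000, 40_000_000, 0.0),
        ]
        tc, _, states = fit_tumor_fraction(segments_factory(rows), sex="male")
        assert tc == f0
        assert states.tolist() == [1, 2, 3, 12, 1]

    def test_few_segments_warns_but_fits(self, segments_factory, caplog):
        rows = [("chr1", 0, 40_000_000, expected_log2(3, 0.5))]
        with caplog.at_level("WARNING"):
            tc, _, _ = fit_tumor_fraction(segments_factory(rows), sex="female")
        assert "segments" in caplog.text

    def test_empty_rejected(self):
        import pandas as pd

        from cnascreen.segment import SegmentedProfile

        empty = SegmentedProfile(
            segments=pd.DataFrame(columns=["chrom", "start", "end", "n_bins", "mean_log2"])
        )
        with pytest.raises(ValueError):
            fit_tumor_fraction(empty)


class TestFlagSingleEvent:
    def test_lone_19mb_deletion_flagged(self, segments_factory):
        """One 19 Mb deletion on an otherwise flat genome drives the LSS."""
        rows = [(f"chr{i}", 0, 150_000_000, 0.0) for i in range(1, 20)]
        rows.append(("chr20", 0, 20_000_000, 0.0))
        rows.append(("chr20", 20_000_000, 39_000_000, -1.0))
        rows.append(("chr20", 39_000_000, 60_000_000, 0.0))
        assert flag_single_event(segments_factory(rows)) is True

    def test_broad_alterations_not_flagged(self, segments_factory):
        rows = [
            ("chr1", 0, 150_000_000, 0.4),
            ("chr2", 0, 150_000_000, -0.4),
            ("chr3", 0, 150_000_000, 0.3),
            ("chr4", 0, 150_000_000, 0.0),
        ]
        assert flag_single_event(segments_factory(rows)) is False

    def test_two_equal_events_not_flagged(self, segments_factory):
        """Two events at ~45% of the squared mass each: neither dominates."""
        rows = [(f"chr{i}", 0, 300_000_000, 0.0) for i in range(1, 5)]
        rows.append(("chr5", 0, 10_000_000, -1.0))
        rows.append(("chr6", 0, 10_000_000, 1.0))
        assert flag_single_event(segments_factory(rows)) is False

    def test_all_neutral_not_flagged(self, segments_factory):
        rows = [("chr1", 0, 100_000_000, 0.0)]
        assert flag_single_event(segments_factory(rows)) is False


class TestCalibration:
    def _fake_handle(self, noise=0.0, warp=1.0):
        def handle(fraction, seed):
            rng = np.random.default_rng(seed)
            return warp * 0.8 * fraction + 0.01 + noise * rng.normal(0, 0.002)

        return handle

    def test_curve_passes_anchor_and_monotone(self):
        curve = calibrate_lss(self._fake_handle(), [0, 0.05, 0.1, 0.25, 0.5], seeds=range(3))
        assert lss_to_tc(0.0, curve) == 0.0
        assert lss_to_tc(0.1, curve) == pytest.approx(0.0875, abs=1e-9)
        assert (np.diff(curve.lss_knots) > 0).all()
        assert (np.diff(curve.tc_knots) > 0).all()

    def test_interpolation_is_monotone(self):
        curve = calibrate_lss(self._fake_handle(noise=1.0), [0, 0.05, 0.1, 0.25, 0.5], seeds=range(5))
        grid = np.linspace(0, curve.lss_knots[-1], 50)
        values = [lss_to_tc(v, curve) for v in grid]
        assert (np.diff(values) >= 0).all()

    def test_clamps_above_last_knot(self):
        curve = CalibrationCurve(lss_knots=[0.0, 0.1], tc_knots=[0.0, 0.0875])
        assert lss_to_tc(99.0, curve) == pytest.approx(0.0875)

    def test_negative_lss_rejected(self):
        curve = CalibrationCurve(lss_knots=[0.0, 0.1], tc_knots=[0.0, 0.0875])
        with pytest.raises(ValueError):
            lss_to_tc(-0.1, curve)

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(lss_knots=[0.0, 0.1, 0.1], tc_knots=[0.0, 0.1, 0.2])

    def test_fractions_must_include_zero(self):
        with pytest.raises(ValueError):
            calibrate_lss(self._fake_handle(), [0.1, 0.5], seeds=range(2))

    def test_round_trip_dict(self):
        curve = CalibrationCurve(lss_knots=[0.0, 0.1, 0.3], tc_knots=[0.0, 0.0875, 0.3],
                                 provenance={"seed": 1})
        back = CalibrationCurve.from_dict(curve.to_dict())
        assert np.allclose(back.lss_knots, curve.lss_knots)
        assert back.provenance == curve.provenance
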