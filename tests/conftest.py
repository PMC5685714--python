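import numpy as np
import pandas as pd
import pytest

from cnascreen import GenomeBins, make_bins, mcrpc_like
from cnascreen.normalize import CopyRatioProfile
from cnascreen.segment import SegmentedProfile


@pytest.fixture(scope="session")
def mini_truth():
    """Advanced-prostate-like truth on the 1/20-scale genome."""
    return mcrpc_like(20)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_profile(values, bin_width=100_000, chrom="chr1", sample_id="sample"):
    """One-chromosome CopyRatioProfile from a raw log2 vector."""
    values = np.asarray(values, dtype=float)
    bins = make_bins({chrom: len(values) * bin_width}, bin_width)
    return CopyRatioProfile(
        bins=bins,
        log2ratio=values,
        weight=np.ones(len(values)),
        sample_id=sample_id,
        bin_width_used=bin_width,
    )


def make_segments(rows, sample_id="sample", bin_width=100_000):
    """SegmentedProfile from (chrom, start, end, mean) tuples."""
    segs = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_log2"])
    segs["n_bins"] = ((segs["end"] - segs["start"]) // bin_width).clip(lower=1)
    return SegmentedProfile(
        segments=segs[["chrom", "start", "end", "n_bins", "mean_log2"]],
        sample_id=sample_id,
        bin_width_used=bin_width,
    )


@pytest.fixture()
def segments_factory():
    return make_segments


@pytest.fixture()
def profile_factory():
    return make_profile
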