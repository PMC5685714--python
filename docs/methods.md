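# Methods

This note documents the models, parameter choices and numerical behavior
of `cnascreen`, and what the synthetic-data experiments do and do not
establish.

## Binning and counting

The genome is tiled with fixed-width bins (0-based half-open coordinates
internally; SEG output is 1-based inclusive, BED stays 0-based).  Reads
are assigned to the bin containing their leftmost aligned base — at ≤ 200
bp reads against ≥ 100 kb bins the difference from midpoint assignment is
negligible and the left-end rule is the cheapest well-defined one.
Unmapped, secondary, supplementary, duplicate-flagged and MAPQ < 37 reads
are excluded and tallied.  chrY and alt/decoy contigs are excluded by
default (Y is unreliable at ultra-low coverage); chrX is kept because the
androgen receptor locus lives there.  Mappability annotation is optional;
when absent only GC correction applies.

**Adaptive bin width.**  The smallest width on the ladder 100 kb – 5 Mb
whose expected reads per bin (`total_reads × width / genome_length`) is at
least 30 is used.  Thirty reads keeps the per-bin Poisson coefficient of
variation under ~18%, which is what makes arm-level calls workable down to
0.005× effective coverage (where ~80,000 genome-wide reads land ~66 per
2.5 Mb bin).

## Normalization

GC correction divides counts by a trend of count versus GC — the median
count within 20 GC-quantile groups, linearly interpolated — rescaled to
preserve the pre-correction median.  This deterministic fit was chosen
over LOESS for testability; it is idempotent to well under 1% on grids of
≥ 1000 bins.  Counts are then converted to log2 ratios against, in order
of preference: a sex-matched panel of normals (per-bin median of
median-scaled panel rates), a single reference profile, or the sex-matched
copy-neutral expectation (bin width × baseline copy).  A pseudocount of
0.5 reads on both sides of the ratio avoids −∞ at ultra-low coverage.
Profiles are median-centered over usable autosomal bins.  Sex-matching of
the reference matters: on a flat (sex-blind) reference, male chrX sits at
−1 and corrupts both LSS and the model fit.

## Segmentation

Classic circular binary segmentation: within each chromosome the best
split over all circular arc pairs maximizes the pooled-SD two-sample
t-statistic, and is accepted when its permutation p-value (values shuffled
within the span under test, 1000 draws) is ≤ 0.01; accepted sub-spans are
recursed; adjacent segments with mean difference < 0.05 log2 units are
re-merged afterwards (an explicit stand-in for reference pruning rules).
The search is exhaustive (no heuristic candidate pruning), ties resolve to
the smallest left index, and t² is evaluated through the between-group sum
of squares (a strictly monotone transform with permutation-invariant
denominator terms), which is numerically safe at perfect splits.
Determinism contract: each tested span draws its own generator seeded by
(seed, chromosome index, span offsets) and materializes its full
permutation matrix in one call, so early stopping of the exceedance count
changes no decision and no later draw.  Minimum segment size is 2 bins.
No outlier smoothing is applied — at ≥ 100 kb bins counts are already
heavily aggregated.

The segmenter also records a robust bin-level noise SD (MAD of successive
differences / √2) on the output profile; the tumor-content fit consumes
it.

## Tumor content

**LSS** is the length-weighted RMS deviation of segment means from zero.
It is scale-equivariant, zero exactly on flat profiles, and maps to tumor
content through a monotone calibration curve built by simulating the
dilution ladder, taking median LSS per fraction, isotonic-regressing if
needed, and anchoring the curve through (0, 0) and (LSS 0.1 → 8.75%
tumor content).  LSS ≥ 0.1 classifies a sample high tumor content; a
profile whose squared-mean mass is > 80% concentrated in one segment
while < 2% of the genome is non-neutral is flagged as a suspect single
event (such samples can be reclassified low on request).

**Grid fit.**  For each fraction f on a 0.005-step grid to 0.95, each
segment takes the integer copy state n ∈ [0, 40] (n_max 40 accommodates
high-level amplifications) minimizing the squared deviation from
log2((f·n + N(1−f))/N); the weighted residual R(f) is minimized over f.
The raw problem is unidentifiable, and three regularizations make it
well-posed:

1. *Noise-scaled state penalty.*  Leaving the neutral state costs
   κ·sd²/n_bins per segment (κ = 6, i.e. ~2.4 σ of evidence).  Without it
   the level grid, whose spacing shrinks like f/ln 2, over-fits every
   noise segment as f → 0 and the estimate collapses to the grid floor.
   When no noise estimate is available a flat 10⁻⁴ penalty applies.
2. *Focal homozygous deletions.*  n = 0 is forbidden on segments spanning
   more than 2.5% of the genome.  Every exact down-harmonic
   (f, {n}) → (f/2, {2n−2}) of a one-copy loss requires whole chromosomes
   at n = 0, which is not a biologically admissible tumor genome, so this
   single constraint removes the harmonic ladder wherever broad losses
   exist.
3. *Selection rule.*  Among fractions whose residual is within 5% of the
   minimum, the smallest one that is a local minimum of the residual
   curve is chosen (the band's lower edge sits on a slope and would bias
   the estimate down by about the band half-width, ~0.02 at f = 0.5).
   Exactly tied residuals — the signature of a single fitted segment,
   e.g. an isolated amplification whose amplitude alone cannot separate f
   from its level family — resolve by least genome weight at n = 0, then
   proximity to the LSS-implied fraction as an independent coarse prior.
   If the chosen fit leaves ≥ 99% of the genome neutral, tc_fit is 0.

On simulated prostate-like profiles at 0.1× coverage the median
|tc_fit − f| is ≤ 0.015 for f ∈ {0.10, 0.25, 0.50} and ≤ 0.035 at
f = 0.05 (where broad events sit below the segmentation detection floor
and only the amplification constrains f), and medians are monotone across
the 0/1/5/10/25/50% ladder.  Below ~5% tumor fraction the estimate is a
detection statement, not a measurement — which is exactly why the LSS 0.1
threshold marks the floor for trusting tumor-content estimates.

## CNA calling

Focal CNAs: segment length in [1.5 Mb, 20 Mb] (inclusive) and
|mean log2| ≥ 0.2.  The loss side uses the same symmetric threshold so
focal deep deletions are expressible.  Deep (2-copy) deletion: the
nearest model level at tc_fit is n = 0 (unclassifiable at tc_fit = 0).
Arm-level events: ≥ 50% of arm length inside segments at |mean| ≥ 0.1;
both thresholds are explicit stand-ins for "detectable" arm events.
21q22.2: loss segments covering ≥ 50% of the ERG–TMPRSS2 span.  FGA:
length fraction of segments with |mean| ≥ 0.2 (the focal cutoff, kept as
one coherent altered/neutral definition and exposed as a flag); elevated
strictly above 0.15.  Gene, arm and interval coordinates ship as in-code
GRCh37 tables (approximate gene spans, adequate for ≥ 1 bp overlap against
≥ 100 kb bins); they are reference annotation, not results.

## Synthetic data

The simulator draws per-bin Poisson counts with mean proportional to
bin width × (f·n + (1−f)·baseline), optionally shaped by a linear GC bias,
normalized so the expected total matches the requested effective coverage
at 180 bp mean fragment length (the typical cfDNA size).  Poisson rather
than negative binomial: at ≥ 100 kb bins and ≤ 1× coverage counting noise
dominates; overdispersion can be emulated through the GC-bias hook.
In-silico mixing and downsampling operate by per-bin binomial thinning of
integer count profiles — a bin-level equivalent of read-level dilution.

Stock truth profiles emulate advanced prostate cancer (8p loss, 8q gain,
chr7 gain, chr13/16/18 loss, focal 2-copy PTEN/RB1 deletions, focal AR
amplification n = 12, interstitial 21q22.2 loss; male), an AR-amplified
prostate cell line, and an EGFR-amplified (n = 20) bladder cell line.
Focal event sizes are absolute (2–3 Mb) so they exercise the 1.5–20 Mb
focal filter regardless of genome scale.

**Problem sizes.**  Experiments run on proportionally shrunk genomes
(GRCh37 autosomes + X divided by an integer factor) so bin arithmetic and
coordinates stay realistic while the full pipeline runs in seconds.  The
default factor is 20 (~155 Mb).  Reads-per-bin depends only on
coverage × width, but bins-per-chromosome shrinks with the genome, so the
0.005×-coverage arm-detection experiment uses factor 2 (~1.5 Gb), which
preserves both the ~66 reads per 2.5 Mb bin of a real 0.005× run and ~29
bins on chr8.  Whole-chromosome events on the factor-20 genome fall inside
the focal length window — an artifact of scaling to keep in mind when
reading simulated focal call lists.

**What passing tests do not show.**  The simulator draws ideal Poisson
counts on a correct grid with (at most) a known linear GC bias and
normalizes against a noiseless sex-matched reference.  Real cfDNA adds
mappability artifacts, replication-timing and fragmentation biases,
germline CNVs, panel-of-normals mismatch and subclonal heterogeneity; the
recovery and detection rates here are therefore upper bounds on real-data
performance, and the concordance experiment (two independent simulations
from one truth, r ≥ 0.9 at 0.25×) validates the comparison machinery, not
cross-platform agreement.

## Degenerate inputs and edge behavior

Empty genomes, empty ladders, non-positive bin widths, malformed
TSV/SEG/BED rows (reported with line numbers), chromosome-name mismatches,
negative counts, tumor fractions outside [0, 1] and zero-length profiles
are rejected with messages.  All-equal GC makes the correction an identity
with a warning; zero-reference bins become unusable; chromosomes with
fewer than 2 usable bins become single segments with a warning;
correlation on a zero-variance profile is reported as undefined (NaN);
LSS extrapolation above the last calibration knot clamps with a warning.
All stochastic components take explicit seeds; there is no hidden global
random state.
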