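# Methods

This note documents the models behind `fiberkit`, the parameters that
matter, the numerical choices made where the design was open, and what
the synthetic generators do and do not emulate.

## Fragment-length-distribution model and correction chain

### Generative model

Correlated-cleavage fragment lengths are modeled as a Gaussian mixture
over a uniform background:

    L ~ Σ_j w_j · N(c_j, σ_j²)  +  w_bg · U{bg_min .. bg_max}

with default contact-peak centers c = (78, 180, 270, 360) nt and widths
σ = 12 nt, a 50% background on 50–700 nt, and mixture weights summing to
one. The peaks are phenomenological: they stand for the single-wrap,
full-nucleosome, and stacked-gyre contact geometries without any 3D fiber
or radical-diffusion physics. The relative peak weights are free
parameters (equal by default); no published quantitative model fixes
them, and nothing downstream depends on their exact values. Sequencing
capture bias thins each drawn fragment with probability exp(−k·L),
k = 0.005 /nt by default; `depth` counts fragments drawn before thinning,
so the kept-row count is binomial around depth · E[exp(−k·L)].

The irradiated-gDNA control is the same model with every peak weight
forced to zero — uncorrelated breaks only. The uniform background law is
a deliberate maximally-uninformative choice; the true random-break length
law is unknown, and the gDNA-ratio step only requires that cell and
control share it.

The spike-in ladder is an equal-weight comb of Gaussian rungs at
multiples of 154 nt (a typical fission-yeast nucleosome repeat; the
spacing is configurable), σ = 15 nt, 6 rungs. Its pre-sequencing
distribution is returned exactly (the analytic mixture per integer nt
scaled to depth), emulating a capillary-electrophoresis quantification;
the post-sequencing counterpart is sampled and bias-thinned with the
same seed.

### Bias fit

The length bias is a single exponential a·exp(k·(L − 300)) fitted by
ordinary least squares to log(post/pre) of the spike-in pair at
L ≥ 300 nt and extrapolated back over the whole grid; correction divides
a histogram by the model value at each length. Weighted fits are
available but off by default. Two numerical guards matter:

* Bins with fewer than `min_count = 5` post-sequencing reads are excluded
  along with zero bins. A log-ratio regression conditioned on near-empty
  bins being nonzero is biased toward zero slope, because the empty bins
  that would have pulled the fit down cannot enter a logarithm; with the
  floor, the rate is recovered without bias (verified to within a few
  percent at k = 0.005–0.01 and ladder depth 10⁶). Exact or analytic
  inputs with realistic count magnitudes are unaffected.
* Technical-replicate fits within a biological replicate are averaged
  (rates arithmetically, amplitudes in log space) into one falloff
  profile per biological replicate.

### Scaling, normalization, comparison

Spike-in depth scaling multiplies each technical replicate by
REF_b / D_i (REF_b the group's mean spike-in depth, D_i the sample's
own); after scaling every spike-in total equals REF_b, which makes the
operation idempotent. Corrected histograms are linearly interpolated onto
a common integer grid (55–450 nt by default; lengths absent from a
histogram count as zero), smoothed with a centered rolling mean that
shrinks at the boundaries, and divided by the smoothed value at 180 nt,
so the mononucleosome signal is exactly 1. The divisor is the value at
exactly 180 nt by default; a peak-maximum mode (maximum within ±25 nt of
180) is available, since both normalization conventions are in use for
such data. Smoothing windows are context presets: 10 nt for cell FLDs,
5 nt for spike-in diagnostics, 30 nt recommended for sparse region
subsets.

The cell/gDNA ratio uses a pseudocount of 10⁻⁶ of the larger curve
maximum, which keeps zero bins finite and makes the ratio exactly
invariant under any common positive rescaling of both inputs.

Replicate aggregation reports mean ± t₀.₉₇₅,ₙ₋₁·SD/√n per position
(undefined for n = 1 and flagged). Between conditions, a two-sided Welch
t-test runs at every grid position across replicate curves and
significant runs are maximal contiguous stretches with p < α (0.05) of
length ≥ 5 positions. The run filter is applied to per-bp tests rather
than to 5-nt-windowed means; the windowed-mean reading is available by
smoothing the inputs. Positions with zero variance in both conditions
(the normalization anchor, by construction) get NaN p-values and never
enter runs.

**Calibration conditions.** The null calibration of the comparison stage
(50 trials, 4 vs 4 replicates from one generator configuration) is run on
*unsmoothed* replicate curves at depth 10⁵ fragments per replicate. Both
choices are assumptions of the test being calibrated, not tuning: rolling
smoothing correlates neighboring p-values by construction, so null
excursions would routinely span ≥ 5 bp and the run filter's false-call
rate would measure the smoothing kernel rather than the test; and per-bin
counts must be large enough (~dozens) for the Welch normality assumption,
below which the test is visibly conservative. Under these conditions the
per-bp significant fraction is 0.043–0.048 against α = 0.05 and the
median number of ≥ 5 bp runs is zero.

## Short-range contact model and statistics

### Generative model

Latent dyad–dyad distances follow a truncated comb,

    d ~ Σ_n w_n · N(n·NRL, σ²)   restricted to [d_min, d_max],
    w_n ∝ n^(−γ) · (1 + A·[n odd, n ≥ 3]),

with γ = 1.2, σ = 12 bp, 8 steps, and window 50–1500 bp by default. The
truncation is global (out-of-window draws are redrawn step and all), so
interior peak heights keep their w_n proportions and are strictly
decreasing when the zig-zag amplitude A is zero. Ligation orientation is
assigned in equal thirds (configurable; no published proportions exist),
and the *measured* distance is shifted by +147 bp for inward and −147 bp
for outward pairs, reflecting that read positions sit at nucleosome
entry/exit points and therefore include or exclude nucleosome lengths
depending on orientation. Strand columns encode orientation
(position-ordered: +/− inward, −/+ outward, same-strand tandem).

### Curves, peaks, NRL, odd/even ratio

Contact curves drop trans pairs, take |pos2 − pos1|, optionally subset by
the same span-overlap rule as the FLD chain, and normalize the histogram
on [d_min, d_max] to sum to one. d_min = 50 bp excludes
self-ligation-scale artifacts.

Peaks are called where the second difference of the smoothed curve
(15 bp centered rolling mean) is negative: within each maximal negative
run, the smoothed-curve maximum is the peak. Numerical hardening for
desk-scale depths (10⁵–10⁶ pairs), where the bare definition — written
for much deeper libraries — breaks down:

* the curvature sign is taken after locally averaging the second
  difference at the same 15 bp scale (raw second differences of a noisy
  curve flip sign many times inside one broad peak);
* candidate peaks closer than twice the smoothing window are merged,
  keeping the higher (two maxima within the smoothing scale are one
  noise-split peak, not two resolvable peaks);
* candidates within one smoothing window of either curve end are
  discarded (boundary window shrinkage fabricates curvature);
* peaks at or below the height floor are discarded. The floor is the
  median of the *positive* part of the smoothed curve: on
  everywhere-positive curves this is the plain median, while on sparse
  synthetic curves with exactly-zero valleys it stays positive and keeps
  isolated stray counts from becoming phantom peaks.

Step labels N+1, N+2, … are assigned consecutively, anchored by rounding
the first peak position over the median peak spacing. The NRL is the mean
basepair distance between successive peak maxima (for an evenly spaced
comb this equals both the spacing and the least-squares slope of position
on step index); all called peaks enter the average by default, with a
configurable cap. The odd/even ratio is
(h_{N+3} + h_{N+5}) / (h_{N+2} + h_{N+4}) with h the curve value at each
labeled peak position (the stored smoothed heights are available as an
option, as is a ±10 bp integrated-height mode through the curve itself).
NRL and the ratio default to the tandem-orientation curve, whose
distances exclude the ±nucleosome-length offsets carried by inward and
outward reads.

**Detrending.** The raw ratio of a smoothly decaying comb is below one
(≈ 0.66 at γ = 1.2), because the power-law decay depresses the later odd
steps. `detrend=True` fits c·n^(−g) to the four step heights and divides
it out, giving exactly 1 for a pure power-law comb and a
monotone-increasing response to the zig-zag amplitude (measured ≈ 1.00 /
1.19 / 1.39 at A = 0 / 0.25 / 0.5, depth 5·10⁵). The raw formula remains
the default so that printed height arithmetic holds verbatim; the
detrended form is the right statistic whenever the question is "is there
odd-step enrichment over the decay", and is what the amplitude-sweep
analyses use.

## Compartment scores

Orientation computes per-chromosome Spearman rank correlation (average
ranks on ties; p from the t approximation with n − 2 df — the estimator
is not otherwise specified in common use) between the c-score track and a
reference active-mark track on shared bins: chromosomes with p ≥ 0.01 are
excluded (and dropped from the shift census, reported in the orientation
table), negatively correlated chromosomes are sign-flipped. Chromosomes
with fewer than 5 bins are an error.

Shift classification between two oriented conditions uses
Δ = c_B − c_A per bin: |Δ| ≤ threshold is stable; negative→nonnegative is
B-to-A, nonnegative→negative is A-to-B; within the same sign an increase
is A-shifted and a decrease B-shifted. Exactly zero counts as
nonnegative, which keeps the classification exactly antisymmetric under
swapping conditions. The threshold defaults to 0.25; 0.2 is also in
circulation for the same analysis, and both are exposed. Bins missing in
either track are dropped and counted.

## Synthetic generators: what they do and do not emulate

The generators reproduce the *statistical structure* the pipeline
assumes — quartet FLD peaks over background with exponential capture
bias, a ladder with known pre-sequencing truth, comb-distributed contact
distances with orientation offsets, state-labeled intervals with
state-specific parameters, correlated bin tracks — with full seed
determinism (identical config + seed gives byte-identical tables).
They do **not** emulate: sequence composition or GC bias, read-level
artifacts (no FASTQ, no alignment, no duplicates), MNase accessibility
bias, chromosome-scale heterogeneity of fragment density, or any
mechanistic fiber geometry. Passing tests therefore demonstrate that the
quantification chain recovers known structural parameters from data with
the assumed structure — not that real libraries satisfy those
assumptions; in particular the known MNase-digestion dependence of the
zig-zag signature within a sample is a caveat of the assay, not something
the pipeline corrects.

## Problem sizes

The standard desk-scale runs are: 2·10⁵ fragments for quartet recovery
(two technical replicates, spike-in ladders of 5·10⁵–10⁶), 5·10⁵
ligation pairs per condition for NRL and zig-zag statistics, 50 trials of
4 + 4 replicates at 10⁵ fragments each for the null calibration, and
10²–10³ randomized instances for the oracle-equivalence suites. At these
sizes the recovered quartet centers are within ±3 nt of the injected
78/180/270/360, and recovered NRLs within ±2.5 bp of 163/186/212, across
seeds.

## Known limitations

* The exponential is the only bias family; strongly non-log-linear
  capture bias would need a different model (the fit diagnostics expose
  this as curvature in the log-ratio).
* Peak calling assumes approximately comb-like curves; closely spaced
  features under half the merge distance (30 bp by default) are reported
  as one peak.
* The per-bin counting noise of corrected FLD curves in thinned tails and
  inter-peak valleys is ~3% (relative, after smoothing) at 10⁶ fragments;
  claims finer than that need deeper simulation or wider smoothing.
* The Spearman p-value uses the large-sample t approximation; for
  chromosomes with very few bins an exact permutation p would be
  preferable to the hard 5-bin floor.
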