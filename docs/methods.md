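# Methods

## The measurement model

Single-cell RT-qPCR on a microfluidic chip reports, for each cell *i* and
target *j*, a quantification cycle Ĉq. Two exogenous RNA spikes per cell
carry purely technical variation (dominated by reverse-transcription
efficiency). We model that technical component as an additive per-cell
offset in Cq space shared by all of a cell's channels, which makes the
spike normalisation

    Cq_ij = Ĉq_ij − (C̄q_i − C̄q_0)

exactly corrective for relative offsets: C̄q_i is the mean over the cell's
valid spikes (or the single valid spike when one failed) and C̄q_0 the mean
over all valid spike measurements of retained cells. Because C̄q_0 is a
dataset-level reference, a constant shift common to *all* cells is, by
construction, absorbed rather than removed; only the between-cell
component is corrected, which is the component that matters for
cross-cell analyses.

Molecule numbers follow from the assay geometry — one cell extract diluted
over 96 wells, 1/45 of a well sampled by the PCR, 22 pre-amplification
cycles, and a detection limit of one molecule at Cq = 30:

    m_ij = 96 · 45 · 2^(30 − 22 − Cq_ij),

with the machine code 999 (no detection) mapped to 0 molecules and the
quality-failure code UD to "missing". All four constants are
configuration (`AssayConstants`) with these defaults. Linear analyses
(correlations, averaging) operate on ln(m + 1).

Cell filtering has two stages: cells without any valid spike are dropped;
then cells whose count of undetected/UD genes exceeds
median + k·MAD (default k = 3) across cells, or 90 % of the panel
outright, are dropped as empty wells. The MAD is floored at one count so
that a single undetected gene never condemns a cell in (near-)noise-free
data, and the absolute 90 % rule covers the degenerate situation in which
most wells are empty and the relative rule is blind.

## Two-state transcription and Poisson-Beta inference

The mechanistic model is the telegraph process: a promoter switches
OFF→ON at rate kon and ON→OFF at koff (h⁻¹); mRNA is made at s0
(molecules·h⁻¹) while ON and degraded at d0 (h⁻¹) per molecule. Its
stationary marginal is the Poisson-Beta mixture D(a, b, c):
Z ~ Beta(a, b), X ~ Poisson(cZ), with a = kon/d0, b = koff/d0, c = s0/d0.
Only the three ratios are identifiable from snapshot data; d0 is estimated
separately from transcription-arrest decay series as the negative
least-squares slope of ln(count) against time.

Moment inference uses the factorial moments e1 = E[X],
e2 = E[X(X−1)], e3 = E[X(X−1)(X−2)] and their ratios r1 = e1,
r2 = e2/e1, r3 = e3/e2, which satisfy r1 = ca/(a+b),
r2 = c(a+1)/(a+b+1), r3 = c(a+2)/(a+b+2). The closed-form inversion

    a = 2 r1 (r3 − r2) / (r1 r2 − 2 r1 r3 + r2 r3)
    b = 2 (r1 − r2)(r1 − r3)(r2 − r3) / ((r1 − 2 r2 + r3)(r1 r2 − 2 r1 r3 + r2 r3))
    c = (2 r1 r3 − r1 r2 − r2 r3) / (r1 − 2 r2 + r3)

takes absolute values at the end (the parameters are positive, so the
modified estimators remain consistent). The test suite checks the closed
form against an independent numerical solve of the three moment equations
to 1e−6 relative, and calibrates recovery over a grid
a, b ∈ {0.3, 1, 3} × c ∈ {50, 500} at n = 20 000 draws (median relative
error ≤ 10 % for c, ≤ 25 % for the shapes). Degenerate inputs — fewer than
20 samples, zero variance, vanishing moments or denominators — raise an
estimator-failure signal; the imputation layer deletes such genes with a
reason instead of imputing silently.

Missing-value replacement fits (a, b, c) per gene per time-point on the
observed cells (requiring ≥ 20, configurable) and replaces each missing
entry by an independent draw from c·Beta(a, b). The Poisson layer is
skipped by default: fitted c values are large, so counts are effectively
continuous; a configuration switch restores it for sensitivity analysis.
Observed entries are never altered; imputed entries are flagged in an
audit mask.

## Entropy as the heterogeneity observable

For each gene at each time-point we histogram expression across cells into
N = ⌊n_cells/2⌋ equal-width bins over the observed range and report
E = −Σ p log2 p (bits). E is zero for a gene expressed identically in all
cells and log2 N for cells spread uniformly over the range. Because
equal-width binning over the sample range is not scale-invariant, the
scale is explicit: entropies are computed on molecule counts by default,
with ln(m+1) available by configuration.

This is a *shape* statistic: OFF-dominated bursty laws (a < 1), whose mass
concentrates at low counts with a long tail, score low; laws spreading
cells evenly over their range (a ≈ b ≈ 1) score near the maximum. The
synthetic surge scenario exploits exactly this axis (below).

Entropy-shift significance between two time-points subsamples 85 % of
cells per time-point without replacement (fraction shared with the network
analysis), recomputes per-gene entropies with bins from the subsample
size, and applies a Wilcoxon test across genes — paired signed-rank by
default, since the same genes are measured at both time-points; rank-sum
is available by configuration. The reported statistic is the percentage of
iterations (default 1 000) with p < 0.05. Comparing a time-point with
itself reuses the same subsample on both sides and is therefore never
significant. Note the bootstrap-like caveat: under the null the support
inherits the observed sample's chance imbalance, so individual null
datasets can score a few tens of percent; the decision threshold sits far
above that.

Pseudo-populations average random, size-balanced cell groups per
time-point and emulate bulk samples from single-cell data.

## Correlation networks and the DNB score

Per time-point, Spearman correlations (Pearson on midranks; p from the
t-approximation) are computed on ln(m+1) data and Bonferroni-adjusted over
the G(G−1)/2 pairs. The robust network keeps an edge only if it is
significant (adjusted p < 0.05) *with the same sign* in every one of the
subsampling iterations (85 % of cells, default 10 000 iterations; scaled
down in tests). Edge weights are full-data correlations; zero-variance
genes yield NA correlations and no edges. With frac = 1 and one iteration
the construction reduces exactly to thresholding the plain correlation
matrix, which the tests assert.

The dynamical-network-biomarker score for a gene set D of size n_D among n
genes is

    I = CV · PCCin / PCCout,
    CV = (1/n_D) Σ_{i∈D} CV_i,
    PCCin = (1/n_D²) Σ_{i,j∈D} C_ij,
    PCCout = (1/(n_D(n−n_D))) Σ_{i∈D, j∉D} C_ij,

evaluated literally: signed Pearson correlations and the self-terms of the
double sum included (so n_D = 1 gives PCCin = 1). Flags expose the
rectified (|C|) and diagonal-free variants common in the biomarker
literature. PCCout = 0 makes I undefined (reported as NaN, never a crash);
a zero-mean or zero-spread gene in D is an error naming the gene.
Candidate selection between two time-points takes genes that (1) sit in at
least one pair whose correlation rises by ≥ 0.5 and (2) have rising CV;
Spearman is the default screening statistic with Pearson available, since
the screening correlation is not pinned down by the score definition.

## Waves and enrichment

For ordered time-points, a gene belongs to the wave at time T if a change
is detected between T and at least one earlier time-point and the gene is
in no earlier wave. Detection requires a two-sided Mann-Whitney p < 0.05
in strictly more than 90 % of 1 000 bootstrap resamples (cells resampled
with replacement within each time-point at original sizes). Group sizes
≤ 8 use the exact test; larger groups use the normal approximation with
midranks, tie and continuity corrections, vectorised over replicates.
Fully tied data takes p = 1 by convention, so constant genes produce no
wave. Enrichment of wave genes in a category uses the exact hypergeometric
law via big-integer combinatorics (`math.comb` with exact rationals),
checked against brute-force enumeration of all draws for small universes.
For the configuration "6 hits among 7 draws with 10 category members of
90" the exact point probability is C(10,6)·C(80,1)/C(90,7) ≈ 2.25 × 10⁻⁶.

## Gillespie simulation of differentiation

Trajectories are exact stochastic simulations of the four reactions, with
time-varying rates handled by holding them piecewise-constant on an
update grid (default 0.1 h) inside the exact loop — accurate for the
slowly varying, linearly interpolated schedules used here; the overshoot
of a segment boundary discards the sampled waiting time, which is exact by
memorylessness. Each population run precedes differentiation with a 100 h
burn-in at the first-anchor rates, after which rates follow the linear
interpolation between anchor time-points (e.g. at 4 h, the mean of the 0 h
and 8 h values). Asynchronous differentiation delays each cell's onset by
an independent Uniform(0, 24 h) lag; with lag 0 the modes coincide
exactly (asserted). The central consistency check — after burn-in at
constant rates, the simulated marginal equals D(kon/d0, koff/d0, s0/d0) by
a two-sample KS test against direct draws — ties the simulator to the
imputation model and is part of the acceptance suite. The inner loop is
JIT-compiled (numba) with a pure-Python fallback.

## The synthetic-data generator

The generator emulates a ~90-gene, 6-time-point (0/8/24/33/48/72 h) design
with ~50–75 cells per time-point, two spike channels, dropout (999),
quality failures (UD) and empty wells. Baseline kinetics are drawn per
gene from kon, koff ~ U(0.5, 2) h⁻¹, s0 ~ U(80, 300) h⁻¹,
d0 ~ U(0.3, 0.7) h⁻¹, giving shape parameters of order 1–6 and scales of
hundreds of molecules — the bursty, high-copy regime typical of fitted
single-cell qPCR panels. Scenarios:

* **constant** — time-invariant rates; negative control.
* **entropy_surge** — 80 % of genes move from an OFF-dominated bursty
  baseline (kon/d0 ≈ 0.3–0.6, low binned entropy) to balanced switching
  (a = b = 1, 1.5× synthesis; near-maximal binned entropy) at the single
  8 h anchor and back, producing an interior rise-then-fall of mean
  entropy of ~0.7 bits. The surge occupies one anchor so that, under
  asynchronous onset lags spread over 24 h, only a minority of cells surge
  at any instant and the population profile genuinely flattens; a wide
  surge window or a strong scale separation would instead shift or invert
  the contrast, because range-adaptive binned entropy responds nonlinearly
  to mixtures of regimes.
* **waves** — anchors 0/2/4/8 h; exactly 2 genes change synthesis first at
  2 h and 5 more first at 4 h (sustained 4-fold shifts, alternating up and
  down), with ground-truth wave labels.
* **dnb** — a 12-gene set (scaled for small panels) whose kon drops
  4-fold at 8 h (higher CV) while a Gaussian-copula factor raises its
  internal correlation from the global baseline 0.15 to 0.85, relaxing
  afterwards; all genes share the weak global factor (a cell-state proxy)
  so that the outside correlation is stable and the I-score is
  well-defined.

Degradation to Cq inverts the molecule formula, applies the shared
per-cell offset (SD 0.5 cycles), optional extra gene measurement noise
(default off), spike channels at Cq ≈ 13 with 0.1-cycle residuals and 2 %
failures, 3 % random UD, 2 % empty wells, and the Cq = 30 detection limit.
With noise disabled the degrade → preprocess round trip reproduces counts
to floating-point accuracy (asserted).

What the generator does **not** emulate: chip-layout or melt-curve
artifacts, cell-cycle and cell-size covariates, amplification-efficiency
differences between genes, and any mechanistic gene-regulatory coupling —
the copula induces correlation without dynamics. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated model, not the biological claims themselves.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down designs chosen as the
smallest sizes at which each property is cleanly decidable: networks at
10 000 subsampling iterations in production default vs 200 in
calibration runs; wave bootstraps 1 000 vs 200; entropy significance
1 000 vs 200 iterations; stationarity checks at 1 000 cells; the
synchrony contrast at 10 genes × 100 cells over 10 paired seeds. The
synchrony contrast's margin varies with the random baseline kinetics of a
schedule draw, so measured win fractions around 0.7–1.0 across schedule
seeds are expected; the effect direction is stable.

All stochastic operations take explicit seeds; there is no global random
state. Pipeline stages derive their seeds deterministically from the
global seed and the stage name (CRC-mixed into a `SeedSequence`), so
re-running a configuration reproduces every artifact byte for byte.
Tie-breaks are deterministic (hub ranking by degree then name). Degenerate
inputs follow the rules above: codes pass through conversions unchanged,
fully tied test data is "no detection", and undefined ratios are reported
as undefined rather than raised — except where a silent default would
corrupt downstream results (zero-mean CV, estimator failures), which are
errors or audited deletions.

## Known limitations

* The moment estimator is unbiased only asymptotically; at n ≲ 50 cells
  the shape parameters carry large variance (hence the ≥ 20-cell floor and
  the audit trail for deletions).
* Binned entropy depends on the bin rule and scale; conclusions should be
  checked under the `log` scale switch.
* The normalisation removes only between-cell technical variation; a
  chip-wide offset is absorbed into the reference and multi-chip data are
  merged by concatenation after normalisation, with no explicit
  chip-effect model.
* Robust-network survival depends on the subsampling fraction and
  iteration count; edge sets are comparable only at matched settings.
* The Gillespie piecewise-constant approximation biases rates within one
  update step (0.1 h) of sharp schedule kinks; exact thinning is not
  implemented.
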