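# Methods

## Model and procedure

The scan tests, at every focal position on a genetic-map grid, whether
case-case haplotype pairs share detected IBD segments more often than
control-control pairs. The pipeline is:

1. **Rates.** For each group, the IBD rate at position *m* is the number of
   distinct haplotype pairs with at least one segment overlapping *m*,
   divided by the number of eligible pairs. Eligible pairs are unordered
   pairs of haplotypes from *distinct* individuals: `n_pairs = C(2n, 2) − n`
   for `n` diploids. Segment intervals are half-open `[start_bp, end_bp)`;
   a pair contributes at most one count per position however many of its
   segments overlap it, so the rate is a sharing probability in [0, 1].
   Within-individual segments (homozygosity by descent) are dropped on read.
2. **Robust standardization.** Per group: initial median and sd over all
   positions define an outlier cutoff at median + 4·sd; positions where
   either group's rate exceeds its cutoff are masked; revised mean and sd
   over unmasked positions standardize the whole track (masked positions
   get Z values too — they are excluded from moments, not from reporting).
   The difference of standardized tracks (asymptotic variance 2 for
   independent groups) is re-standardized by its unmasked mean and sd to a
   unit-variance test track.
3. **Decay estimation.** Autocovariances of the test track are computed at
   lags `step, 2·step, … ≤ 4 cM` within chromosomes, skipping any pair that
   touches a masked position, in the mean-zero product form. A no-intercept
   OLS of log autocovariance on lag (Morgans) gives the decay estimate
   `θ̂ = −slope`; non-positive autocovariances are dropped before logs (the
   log-linear model has no image for them). The regression presumes the
   variance-1 standardized track — on any other scale the no-intercept model
   is misspecified, which is why standardization precedes estimation.
4. **Thresholds.** The genome-wide critical value solves the OU excursion
   approximation (README) by bracketed Brent root-finding on z ∈ [1, 10],
   widened to [0.1, 20] on failure, residual < 1e−10. ν(·) uses Siegmund's
   two-term rational approximation, with the exact truncated series kept in
   the tests as an independent oracle. The simulation threshold draws
   maxima of re-standardized OU difference tracks and takes the conservative
   upper order statistic ⌈(1−α)·n⌉ — never interpolating downward; default
   1000 simulations. When case and control decay rates differ, the analytic
   method uses the θ fitted directly to the difference track rather than an
   average of the per-group fits.
5. **Regions.** Maximal runs of consecutive positions with Z ≥ z* per
   chromosome; a k-position run at spacing δ reports size k·δ cM (so a
   single significant grid point at 0.05 cM spacing reports 0.05 cM). BED
   output is 0-based half-open with end = last significant bp + 1.

A one-sample mode (selection scan) applies steps 1–3 to a single sample
set; under its null the whole cohort shares one genome-wide mean rate, and
rejections indicate excess sharing from selection, structure, or artifacts.
A randomized-phenotype mode permutes labels half/half (seeded Fisher–Yates;
odd cohorts give the extra sample to controls) and reruns the scan on the
same segments: signals that survive relabelling are phenotype-blind and
therefore confounded.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| grid step δ | 0.05 | cM | test spacing; 0.02 cM used in FWER experiments |
| detection cutoff | 2.0 | cM | minimum segment length kept on read |
| outlier multiplier | 4 | sd | mask cutoff = median + 4·sd |
| max autocovariance lag | 4.0 | cM | 80 lags at the default step |
| family-wise level α | 0.05 | — | |
| θ | estimated | per Morgan | typical human-cohort values 24–73 |
| simulation draws | 1000 | genomes | "hundreds to thousands" regime |

## OU simulator

Tracks are exact stationary Gaussian AR(1) sequences: lag-one coefficient
`a = exp(−θδ)`, innovation variance `1 − a²`, stationary start per
chromosome, chromosomes independent — the discretized OU process with no
Euler error. The case/control pair shares per-step innovations with
correlation `r = ρ(1 − a₁a₀)/√((1−a₁²)(1−a₀²))`, which makes the
same-position cross-correlation exactly ρ (for θ₁ = θ₀ the expression
reduces to r = ρ and the construction is exact at all lags; for θ₁ ≠ θ₀ the
cross-lag structure is the one induced by shared innovations, and infeasible
(θ₁, θ₀, ρ) combinations raise an error). Threshold simulation streams
per-genome sums, sums of squares and extremes chromosome by chromosome, so
thousands of genomes run in seconds without materializing full tracks.

## Synthetic data generator

The generator emulates detector *output*, not population genetics: each
between-individual haplotype pair receives segment starts as a Poisson
process (default 0.025 per Morgan) with lengths `cutoff + Exp(2.0 cM)`,
giving a closed-form stationary sharing probability of
`1 − exp(−λ·E[len]) ≈ 1e−3` — sparse, realistic for ≥ 2 cM segments — used
as an oracle in tests. Starts are drawn on a window extended left of each
chromosome so coverage is stationary everywhere; boundary-clipped records
may fall below the cutoff, as a detector truncating at a contig end would
report. The default cohort is 1250 + 1250 samples on ten 100 cM chromosomes
with a linear 1 cM/Mb map. Risk loci add one overlapping segment to a
random fraction q of case-case pairs; carrier confounders designate
⌊f·2n⌋ carrier haplotypes ignoring phenotype and add a segment to every
carrier-carrier pair.

What the generator does **not** emulate: coalescent length distributions
(no demography), linkage between loci, detection error (no false/missed
segments, no endpoint noise), ascertainment, or relatedness structure. Its
rate tracks have exponentially-tailed (not Gaussian-process) fluctuations
whose correlation length is set by the segment-length law, so passing tests
show the scan machinery is correct and calibrated under a clean null — not
that real cohorts satisfy the OU assumptions; the robust masking and the
selection/permutation cross-checks exist precisely because real data
deviate.

## Numerical choices and edge cases

- Standard deviations use ddof = 1 throughout.
- Genetic-map queries outside the anchor span clamp to the terminal anchor
  (constant extrapolation); grids are anchored at each chromosome's first
  map position, so scanning never extrapolates.
- Grid sizes use `floor(span/step + 1e−9) + 1` to absorb float jitter.
- gzip inputs are detected by magic bytes, not file extension.
- Degenerate inputs fail loudly: identical case/control rates (zero
  difference variance), all-masked tracks, zero revised sd, all
  non-positive autocovariances, fewer than two samples per group,
  single-anchor chromosomes.
- The empirical-quantile order statistic and the bitwise-seeded PCG64
  generator make every stochastic path reproducible from the logged seed.

## Design choices where the design was open

- **Masked positions and regions.** Masked positions are excluded from
  moments and θ estimation but still carry reported Z values; by default
  they cannot form or extend regions, with an explicit
  `include_excluded` / `--test-excluded` switch. Strong true signals trip
  the median + 4·sd mask by construction, so scans hunting such signals
  (and the power tests here) set the flag; the conservative default keeps
  the automatic region list free of positions whose moments were distrusted.
- **Two-sided scans.** Two constructions are provided and documented as an
  option: doubling the excursion terms in the analytic formula, or taking
  quantiles of maxima of |Z| in simulation (the default); for symmetric
  processes the simulated two-sided level-α threshold matches the one-sided
  α/2 threshold within Monte-Carlo error.
- **Region size.** A k-position run reports k·δ cM rather than (k−1)·δ, so
  a single-point hit has the minimum reportable size δ instead of 0.
- **Autocovariance pairs at masked positions** are skipped entirely rather
  than re-centred; the lag's estimate is the mean over surviving pairs.

## Test and experiment scales

Tests run on desk-scale problem sizes chosen so the whole suite finishes in
well under a minute of simulation time per property: FWER calibration uses
500 OU genomes of 10 × 100 cM at 0.02 cM; θ recovery uses 20 genomes of
35 × 100 cM at 0.05 cM per θ ∈ {25, 50, 100}; end-to-end generator checks
use 60–250 samples per group on 3–20 chromosomes. The Gaussian-shape sanity
bounds on the difference track (|skew| < 0.3, excess kurtosis < 0.6) are
~3σ for the effective number of independent positions at those genome
lengths — the track's correlation length, not the sample count, limits how
sharply skew and kurtosis can be measured.

## Known limitations

- The analytic correction assumes the OU model; heavy-tailed IBD-rate
  processes (e.g., around strong sweeps) violate it, which is why the
  selection scan and randomized-phenotype check accompany the case-control
  scan rather than being optional extras.
- θ̂ from a single 10-Morgan genome has ~10% scatter; thresholds inherit
  that noise. Seed-averaged estimates are unbiased to within a few percent.
- The shared-innovation 2-D OU construction pins only the same-position
  cross-correlation when θ₁ ≠ θ₀; cross-lag covariances are a modelling
  choice, recorded in the result metadata.
- Siegmund's rational ν approximation sits within ~2% of the exact series
  on the operating range (peak deviation near y = 1); the series is kept
  available (`nu_series`) for applications needing it.
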