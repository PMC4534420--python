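# Methods

## The statistical model

Each voxel of a background-suppressed PCASL acquisition yields an ordered
series of control − label differences d₁ … d_N (one per label/control
pair). The working hypothesis per voxel is one-sided: the mean difference
is greater than zero (an ASL effect exists). On the first n pairs,

    u = mean(d₁…d_n),  σ̂ = sample s.d. (n−1 denominator),  T = u√n / σ̂,

with the one-sided p-value from the Student-t upper tail on n−1 degrees of
freedom. Evaluating T on every cumulative prefix of the series turns a
single acquisition into a power curve: the NSA (equivalently scan time,
2·TR per pair) at which each voxel first crosses the threshold. The prefix
engine uses running sums (cumulative sum and sum of squares, centered sum
of squares clipped at zero against cancellation), which matches a naive
per-prefix recomputation to 10⁻⁹ and costs O(N) per voxel.

Degenerate prefixes with σ̂ = 0 take the limiting t: +∞ (p = 0) for u > 0,
0 (p = 0.5) for u = 0, −∞ (p = 1) for u < 0. This makes the noiseless
phantom behave correctly: every responder is significant at n = 2, no
non-responder ever is.

Thresholds: uncorrected α (default 0.05, also 0.01) or Bonferroni α/m with
m the voxel count of the analyzed WM mask — the mask is the test family.
Time-to-significance uses the first crossing, not sustained significance.
Non-responders are defined strictly: t < 0 at *every* grid NSA.

## The synthetic generator and what it emulates

No raw data accompany the study design this pipeline re-implements, so the
generator is a first-class, tested module whose defaults *are* the study
conditions:

- **Geometry**: 32×32×8 voxels of 3.75×3.75×5 mm³ (the 8-slice
  partial-brain EPI readout); elliptical head, GM shell, WM core
  (~2500 WM voxels), ventricle-like CSF block in slices 2–5. A random 30%
  of the WM voxels touching GM are relabeled mixed-tissue, so both
  mixed-intensity voxels and direct WM–GM contact exist (a continuous
  mixed ring would make the peripheral sub-mask empty by construction).
- **Kinetics**: single-compartment continuous-labeling model, all decay at
  blood T1 (1650 ms), labeling efficiency 0.85, combined
  background-suppression efficiency 0.75, λ = 0.9 mL/g, M0 = 100 signal
  units. With readout at t = LD + PLD and bolus duration τ = LD the
  expected difference is the piecewise bolus form (zero before arrival,
  inflow wash-in during the bolus, pure decay after), continuous in t and
  nonnegative. Under these defaults a typical WM voxel (CBF 20 mL/100g/min,
  ATT 1500 ms) gives ΔM ≈ 23 units under the 2150/1500 protocol.
- **Tissue draws**: CBF ~ N(60, 6) GM, N(20, 4) WM, N(40, 6) mixed
  (truncated at 0), mL/100g/min; ATT ~ N(900, 100) GM, N(1500, 150) WM,
  ms. The WM/GM CBF ratio (1/3) sits in the physiological 1/4–1/2 band,
  which the config validates.
- **Noise**: independent Gaussian per volume per voxel, sd 40 units; the
  difference series then has sd ≈ 56.6. The per-pair effect-to-noise ratio
  for a typical WM responder is ≈ 0.4, which was chosen a priori so that a
  majority (~70–80%) of WM responders reach α = 0.05 within the first ~40
  pairs (~5 min) under the 2150/1500 protocol and ~94% by 400 pairs — the
  qualitative regime the analysis is designed to probe. A single per-pair
  WM difference is ~0.4 s.d. of the noise: far below detection, as it
  should be.
- **Static residual**: control and label volumes share a static offset
  20 + 2·z (slice index z), mimicking progressively incomplete background
  suppression in an ascending 2D readout. It cancels exactly in the
  subtraction.
- **Non-responders**: 6% of WM voxels (exact count) have their expected
  difference replaced by −|N(0, s)| with s = 0 by default, i.e. exactly
  zero effect. The 6% mirrors a fitted response asymptote of ~94%.
- **SIR volume**: class-wise intensities (fractions of 1000): WM 1.0,
  mixed 0.5, GM 0.10, CSF 0.02, noise sd 10 — GM suppressed, WM bright,
  CSF near-nulled, as a single inversion recovery timed to null GM
  produces.
- **Determinism**: one `numpy.random.Generator` seeded once; draws occur
  in a fixed documented order (phantom: interface relabeling, CBF, ATT,
  non-responder selection; simulation: non-responder effects, control
  noise, label noise, SIR noise). Noise arrays are drawn even at sd = 0 so
  the stream position never depends on the settings.

### What the generator does *not* emulate

Passing tests on this phantom demonstrate the statistical machinery, not
anatomical realism. Known divergences from real data:

- No partial-volume or point-spread blurring, no motion, no physiological
  (cardiac/respiratory) noise, no temporal autocorrelation: the paired
  t-test's independence assumption holds by construction here and only
  approximately in vivo.
- The WM effect-size distribution is a narrow truncated normal. Real WM
  t-histograms develop a long *right* tail with NSA (a broad spread of
  effect sizes, partly GM contamination at the interface); this phantom
  instead develops a *left* shoulder (non-responders and low-CBF voxels
  lag behind a compact bulk), so its high-NSA skewness is negative. The
  histogram and skewness operations are validated on constructed
  distributions with the realistic right-tail structure.
- With the default zero-mean non-responder mechanism, the strict
  "t < 0 at all NSA" detector flags only the few non-responders whose
  noise trajectory happens to stay negative throughout; set
  `nonresponder_scale > 0` to give non-responders a genuinely negative
  expected difference and make detection sharp.
- Which asymptotic model best fits the simulated percent-significant curve
  is data-dependent (the exponential-recovery form often wins under the
  defaults); the fractional model's defining property — asymptote
  100·(1−q) under non-responder fraction q as noise → 0 — is exercised
  directly in the acceptance suite.

## Scan-time conventions

`scan_time_minutes` truncates to one decimal (400 pairs at TR 3500 ms =
46.67 min → 46.6), reproducing the tabulated per-protocol times;
`total_scan_time_minutes` truncates each run to whole minutes before
summing (2×46 + 2×53 = 198), reproducing the quoted session total;
`nsa_to_minutes` is unrounded for analysis.

## Masking choices

Segmentation bands are fractions of a robust maximum (99th percentile of
positive voxels): WM ≥ 0.8, mixed band [0.3, 0.8) excluded, GM band
[0.05, 0.3) inside the brain, ventricles < 0.05 inside the brain. The
brain support is hole-filled so enclosed dark ventricles count as inside.
"Bordering" and "one voxel outwards in all directions" default to 3D
26-connectivity; 6-connectivity and slice-wise 2D 8-connectivity are
selectable because 5 mm slices make through-plane adjacency debatable.
Where a voxel qualifies as both periventricular and peripheral,
periventricular wins, making the periventricular/peripheral/deep split an
exact partition of the WM mask (asserted at construction). A manual
ventricle or GM mask can be supplied in place of the SIR-derived estimate.

## Histograms and curve fits

t-histograms use the fixed range [−10, +50] with 60 unit-width bins
(configurable); out-of-range and infinite t-values are clipped into the
end bins so each per-subject histogram keeps unit area; group curves are
bin-wise means across subjects (equal subject weighting). Skewness is the
adjusted Fisher–Pearson sample statistic.

Response-curve candidates y = a(1−e^(−bx)), y = a·ln x (natural log; the
base only rescales a) and y = ax/(b+x) are fitted by (non)linear least
squares with nonnegativity bounds and fixed starts (a₀ = max y;
b₀ = 1/median x for the exponential, median x for the fractional);
selection is by smallest sum of squared residuals among converged fits,
with 95% parameter CIs from the linearized covariance at the optimum
(t-quantile, n−p df). The mean-t fit y = K√NSA is through the origin,
since T = u√N/σ has no intercept. Non-convergence flags the candidate and
excludes it from selection rather than failing the run.

## Problem sizes

Default analyses use the 32×32×8 phantom (~2500 WM voxels, 400 pairs).
The test suite's calibration check uses a 10 368-voxel null phantom at
NSA = 400; the curve-shape checks average 25 replicate 24×24×8 phantoms;
the asymptote check uses a 64×64×8 phantom (>10⁴ WM voxels) in the
noiseless limit. These sizes give binomial/Monte-Carlo standard errors of
~0.002–0.01 on the reported fractions.
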