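# Methods

## Data model

A track table is long-format, tab-separated text with one row per focus per
frame: `cell_id, frame, t_min, channel, focus_id, x_rel, cell_length_um`.
`x_rel` is the long-axis position as a fraction of cell length from
mid-cell, which removes cell growth from the coordinates; rows outside
[−0.5, 0.5] are dropped (not clamped, which would bias tail statistics).
Two channels are carried: the tracked locus and an optional fiducial marker
used only for left–right orientation.

**Split detection.**  The splitting event — one focus resolving into two —
defines t = 0.  Real focus tracking produces transient double-detections
and dropouts, so a splitting event is defined as a block of two-focus
frames containing at least `sustain = 2` consecutive two-focus frames;
shorter two-focus runs and one-focus gaps shorter than the sustain window
are treated as detection noise.  t = 0 is the first frame of the first
sustained run.  Full-cycle analysis keeps only trajectories with exactly
one splitting event and no sustained re-merge; everything else is excluded
with a recorded reason.

**Orientation.**  Cells whose fiducial-channel mean position is negative
are mirrored (x → −x for all channels), putting every cell in a common
left–right chromosome frame.  Post-split daughter foci are given stable
identities by nearest-neighbour linking frame to frame, then labelled
left = 0 / right = 1 by mean position; mirroring swaps the labels so the
convention survives reflection.  Orientation and synchronization commute.

**Intervals.**  Four half-open windows relative to the split:
Pre-Replication (t < −10 min), Cohesion (−10 ≤ t < 0), Rapid-Translocation
(0 ≤ t < 10) and Post-Segregation (t ≥ 10).  Boundaries go to the later
interval, so t = 0 (the first two-focus frame) is Rapid-Translocation.
MSD analysis of post-split motion starts at t = 1 min, because the exact
split frame cannot be resolved; step and drift analyses use the full
windows.

## Estimators

**MSD.**  MSD(τ) is the combined time-and-ensemble average of
(x(t+τ) − x(t))² over all tracks and start times with both endpoints inside
the interval window — combined averaging maximizes pairs inside 10-min
windows.  Displacements never span the branch point; both daughters
contribute post-split (MSD uses displacements, so no mirroring is needed).
The power law is fit by least squares on log MSD vs log τ, default lags
1–10 min (1–20 for the open-ended Pre-Replication window); the reported
D is the raw intercept, with no factor-2 convention imposed.  The standard
error of α comes from a bootstrap resampling whole cells (1000 replicates
by default) — cells, not displacement pairs, are the exchangeable unit,
and a cell's two daughters are dependent.

**Steps.**  δx = x(t + lag·δt) − x(t), default lag 1 frame; larger-lag
checks use the same code path.  v = ⟨δx⟩/δt, D_eff = var(δx)/(2δt) with
normal-theory standard errors.  After the split the default selection
keeps the right-destined focus only (the convention for the biased-step
analysis); `mirror` pooling reflects the left focus instead, doubling n
without changing the mean under left–right symmetry.  The excess-tail
statistic is the empirical probability of |δx − μ| > cσ minus the Gaussian
tail mass beyond the same cut, with a bootstrap CI; c = 2.5 by default and
the maximum over c ∈ {2, 2.5, 3} is also reported, since "large step" has
no canonical definition.  Step autocorrelation is the pooled normalized
autocovariance of within-track step sequences; for fractional Brownian
motion the lag-1 value is 2^(α−1) − 1, for a sampled Ornstein–Uhlenbeck
process −(1 − e^(−δt/τ))/2.

**Drift field.**  Steps are binned by their start position (bin width 0.05
relative units, minimum 25 steps per bin; bins below the minimum are
flagged absent, never zero).  v(x) = ⟨δx⟩/δt per bin, SE = sd/√n/δt.  Fits
and oracle comparisons use the per-bin *mean* start position rather than
the geometric centre: when occupancy varies across a bin (it is roughly
Gaussian around each equilibrium), the mean-position abscissa removes a
binning bias of order bin²/12 · d(log p)/dx that would otherwise inflate
the recovered relaxation time by ~8% at the default settings.  Equilibria
are zero crossings of v between adjacent populated bins (linear
interpolation); stability is the sign of the locally fitted slope.  The
relaxation time inverts the discrete-sampling relation
slope = −(1 − e^(−δt/τ))/δt, i.e. τ = −δt / log(1 + slope·δt), which
reduces to −1/slope as δt → 0; the weighted fit uses bins within 0.15 of
the equilibrium.

**Occupancy.**  Per-time-bin position histograms (rows normalized to 1
where data exist), the mean trajectory, and a mode count per focus group
after light kernel smoothing — the unimodality diagnostic that argues
against multiple discrete segregation pathways.

**Force.**  In the overdamped Langevin picture ⟨ẋ⟩ = F̄/γ, so F(x) =
γ·v(x) with γ = k_BT/D_eff (Einstein relation), T fixed at the 30 °C
growth temperature (303 K, k_BT computed from CODATA constants) and a
representative cell length converting relative units to SI.  This is an
order-of-magnitude device: the cytoplasm is active and viscoelastic, γ is
assumed constant, and fluctuations are assumed not significantly larger
than thermal.  The output annotates the peak force against a 1 pN motor
reference rather than asserting a comparison.

## Synthetic generator

The generator produces the study conditions the analyses assume: 400 cells
by default, 1-min sampling, ~120-min generation time, split times drawn
N(60, 10) min truncated to the cycle, spring relaxation time τ = 10 min,
equilibrium at 0 before the split and ±0.25 after, D = 2.5·10⁻⁴
(relative units)²/min, localization noise σ_loc = 0.005 relative units
(small and configurable; the source data do not quantify it), exponential
length growth L(t) = 2.5 µm · 2^(t/120 min).

Three modes, because no single tractable process reproduces every
observable at once:

1. **White-noise OU** (damped linear spring): used for drift, equilibrium
   and relaxation-time tests.  The update uses the exact OU transition
   density — x' = x_eq + (x − x_eq)e^(−δt/τ) plus noise of variance
   Dτ(1 − e^(−2δt/τ)) — so the conditional step mean equals
   −(x − x_eq)(1 − e^(−δt/τ)) at any δt and the drift-field oracle is
   exact rather than first-order; an Euler variant is available for
   comparison.  A white-noise spring cannot produce sub-diffusive MSD
   scaling, so per-interval α values from this mode reflect the spring
   crossover, not fractional exponents.
2. **Fractional Brownian motion**: stationary Gaussian increments with the
   fractional covariance (Hurst H = α/2), giving MSD(τ) = D·τ^α exactly;
   used for scaling-exponent and step-memory tests.  Sampling is by
   circulant embedding (Davies–Harte), exact and O(n log n), with the
   exact O(n²) Durbin–Levinson recursion as fallback when the embedding
   is not non-negative definite; the metadata records which sampler ran.
3. **Spring + fractional noise**: the exact OU update driven by
   standardized fractional increments.  This is an approximation — it is
   not the stationary solution of a fractional Langevin equation — but
   provides end-to-end ensembles with both a restoring drift and
   anti-correlated steps.  Daughter tracks draw independent noise
   sequences (no memory is carried across the branch point).

Determinism: one `numpy` generator seeded from the config drives every
draw in a fixed order, so identical configs give identical track tables.

**What the generator does not emulate:** focus-detection dropouts and
spurious detections (the split-detection logic handles them but the
default ensembles contain none), short-axis motion, cell-division
asymmetries, intensity-dependent localization error, and nucleoid
structural transitions.  Passing tests therefore demonstrate estimator
correctness under the stated stochastic models, not robustness to every
artifact of real microscopy data.

## Problem sizes, tolerances and numerical choices

Recovery checks use 400 tracks of 30–120 frames — matching the ~400-cell
scale of the motivating dataset — where the MSD exponent estimator has a
standard error well under 0.01 and the relaxation-time estimator ~3%.
Calibration tests average 20 independent replicates per exponent.
Coverage-style checks (per-bin drift within 2 SE of the exact conditional
mean for ≥ 95% of bins) are run at pinned seeds: with ~8–17 populated bins
the nominal 95% criterion sits exactly at expected coverage, so an
unpinned run fails by one unlucky bin with appreciable probability even
for a correct estimator.

Degenerate inputs are errors, not silent results: negative D, non-positive
τ, zero step variance in the excess statistic, non-restoring profiles in
the relaxation fit, slopes too steep to invert at the sampling interval
(1 + slope·δt ≤ 0), and drift profiles with no bin reaching the occupancy
minimum.  τ ≤ 2δt warns that the sampled spring is poorly resolved.  Split
times that cannot be drawn inside the cycle in 100 tries abort.

## Known limitations

- The localization-noise default (σ_loc = 0.005) inflates every interval's
  D_eff by the same additive term, which dilutes *ratios* of effective
  diffusion constants: a configured 50% elevation is recovered near ~45%
  under the defaults.  This is a property of the estimator applied to
  noisy positions, not of the generator, and the recovery stays within the
  stated ±10-point band.
- The ~30-frame post-split exponent recovery carries a small finite-length
  downward bias (~0.01) from time-averaging over short tracks.
- Relative coordinates hide absolute motion; physical conversions use one
  representative length (or the table's mean observed length) rather than
  per-frame lengths of each contributing cell.
- Fractional-noise split cycles approximate, rather than solve, a
  fractional Langevin equation (see above).
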