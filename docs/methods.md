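# Methods

## Signal model

A cell transiting a node-pore channel is modelled as a moving blockage.
While the cell occupies a narrow segment of width `w`, length `L` and
height `h`, the relative current drop follows the standard resistive-pulse
sizing relation for a sphere of diameter `d` in a pore of effective
diameter `D_e`:

```
dI/I = d³ / (D_e² L) · 1 / (1 − 0.8 (d/D_e)³),      D_e = 2 √(w h / π)
```

Rectangular cross-sections are mapped to `D_e` by equal area, the usual
convention in resistive-pulse work. The relation is strictly increasing in
`d`, so sizing inverts it uniquely (bisection to |Δd| < 10⁻⁴ µm over
`(0, 0.95 D_e)`).

Inside the contraction segment the cell is squeezed below its free
diameter; its blockage is rendered with an effective diameter
`min(d₀, 0.93 · D_e,contraction)`. The cap only affects the contraction
subpulse amplitude, which is used for edge detection and plausibility
checks, never for sizing.

**Recovery.** After deformation the cell relaxes from an ellipsoid back to
a sphere. The observable is the normalized amplitude deficit in recovery
pore `i` at time `t_i` after contraction exit,

```
q(t) = q₀ · exp(−t / τ),        q_i = (a_expected − a_i) / a_expected
```

a single-exponential — the minimal model consistent with a scalar recovery
constant, shared by the simulator and the fitter so parameter recovery is a
testable contract. `a_expected` is the sizing relation evaluated at the
measured `d₀` for the *recovery-pore* geometry: on devices where recovery
and reference pores share a length this equals the reference amplitude, but
on the AP-1060 design (290 µm recovery vs 800 µm reference pores) the
lengths differ and predicting the recovered amplitude through the sizing
relation is the consistent generalization. `t_i` is taken at the subpulse
midpoint. τ comes from ordinary least squares of `ln q_i` on `t_i` over
points above a noise floor (default 2×10⁻³); with fewer than two usable
points, or a non-negative slope, τ is reported absent rather than invented.
The log-linear fit is exact on the shared exponential model and
scale-equivariant in time.

**Recovery time and category.** ΔT_r is the time of the first recovery
pore whose deficit is within tolerance (0 if the first already is), with a
`prolonged` marker when none within the 100 ms window qualifies. The
tolerance defaults to `max(0.02, 3 σ_amp / a_expected)`, tying
"recovered" to the measured amplitude noise so that ΔT_r = 0 is well
defined on noisy data. Categories partition ΔT_r: 0 → instantaneous,
(0, 100 ms) → finite, otherwise prolonged; the 100 ms boundary itself maps
to prolonged (open interval).

## Preprocessing

Raw 50 kHz current → 200-sample centered rectangular moving average
(shrinking windows at the edges; a centered filter avoids a systematic lag
of pulse boundaries) → decimation by 20 to 2.5 kHz (the moving average has
already suppressed the aliasing band) → asymmetric least squares (AsLS)
baseline → normalized drop `x_t = (baseline_t − signal_t)/baseline_t`.

AsLS minimizes `Σ w_i (y_i − z_i)² + λ Σ (Δ² z_i)²` with weights reassigned
each iteration: 0.99 above the running baseline, 0.01 below (pulses are
downward), 10 iterations with early exit when the weight pattern is stable.
The defaults at the 2.5 kHz rate are `λ = 10¹¹`, `p = 0.01`. λ sets the
bending length scale (≈ λ^¼ samples ≈ 0.13 s); it must bridge individual
subpulses yet follow multi-second drift, and 10¹¹ balances the two across
the velocity range the devices produce. All five chain parameters are
configuration-exposed and logged per run. The penalized solves are done on
the mean-centered signal with a symmetric banded solver; centering keeps
the right-hand side small and sidesteps the poor conditioning of
`W + λ DᵀD` at large λ.

**Two-pass baseline.** A full cell transit occupies ~1 s in which the
asymmetric weighting alone lets the baseline sag slightly toward the pulse
train; that residual (~10⁻³ of baseline) is negligible for detection but
not for recovery deficits of order 10⁻². Detection therefore runs twice:
the first pass locates pulse windows, the baseline is then re-fit with
those windows given zero weight — the penalized smoother bridges each
event with its minimum-curvature (cubic) segment anchored by quiet data —
and the second pass runs on the re-normalized trace. Residual offsets are
further cancelled per window by measuring the quiet lead-in/lead-out
margins and subtracting a linear interpolant from plateau levels.

## Detection

The first difference of the normalized trace is thresholded at 2×10⁻⁴ for
pores and 1×10⁻³ for contraction segments (normalized-drop units; with the
default noise level, 5×10⁻⁵ of baseline, the pore cutoff sits at ≈4σ of
the raw noise). Runs of consecutive supra-threshold samples of one sign
merge into a single edge at the extremum; a positive difference of the
normalized drop is a cell *entering* a segment. Edges closer than a
maximum gap group into candidate windows; the default gap is 1.2× the
contraction transit of the slowest plausible cell (the longest quiet
stretch inside one pulse), so one well-separated cell yields one window
while coincident cells merge and are rejected as `overlap`.

Within a window, edges must strictly alternate entering/exiting and are
paired greedily in order. Subpulse kinds are assigned by position against
the device's segment plan. Boundaries are refined to the half-amplitude
crossing of the filtered edge ramp with linear interpolation, giving
sub-sample timing (the 2.5 kHz grid alone would quantize durations by
±0.4 ms, visible in wCDI); amplitude is the mean normalized drop over the
central 50 % of the refined subpulse. Windows are auto-rejected with a
reason when the subpulse count is short (`missing subpulse` — truncated or
interfered pulses), long (`overlap`), when edges cannot be paired, when
any duration falls outside `[0.2 L/v_max, 5 L/v_min]` for the configured
velocity range (defaults 2–40 µm/ms), or when the contraction subpulse
amplitude is below the contraction threshold. An optional interactive mode
renders each pending window as text for save/skip review, mirroring the
semi-manual workflow; the default is fully automated. Per-window automatic
thresholds (0.5× the median entering-edge magnitude per threshold class,
floored at 3× the robust noise sd of the first difference) are available
as `auto_set_thresholds`.

## QC filters

Statistical outliers are values more than 3 median absolute deviations
from the sample median; MAD is **unscaled** (no 1.4826 consistency factor),
the convention implied by counting "median absolute deviations"; the
scale factor is configurable. Outliers are flagged but retained. Erroneous
measurements are defined through the velocities: per velocity variable
(reference and contraction), 3-MAD outliers are excluded, the median and
MAD of the remainder set a ±4-MAD cutoff applied to all records, and a
record outside the cutoff in either velocity is erroneous; erroneous
records are excluded from downstream statistics by default. The procedure
is order-invariant.

## Reliability and comparison statistics

Observations of the same recording are aligned by window start time
(single-linkage clustering of pooled start times, 5 ms default tolerance);
only cells saved in at least one observation form rows. Percent agreement
counts unanimous save/skip rows. Fleiss's κ is computed from the
item×category count table with the large-sample variance under the null of
chance agreement, giving the z test, normal-approximation 95 % CI, and the
conventional interpretation bands (≤0 poor, then slight / fair / moderate /
substantial / almost perfect at 0.21/0.41/0.61/0.81); "percent agreement
above chance" is reported as 100·κ — an interpretation, not a separate
computation. ICC(A,1) — two-way model, single rater, absolute agreement —
is computed from the two-way ANOVA mean squares,
`(MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E)/n)`, with the
F-based confidence interval in the McGraw–Wong parameterization and the
p-value for ICC = 0 from `F = MS_R/MS_E`; the test suite cross-checks
estimate, CI and p against pingouin. Missing data are handled complete-case
by default, with a `pairwise` mode that estimates the mean squares from an
unbalanced two-way least-squares fit (exact on complete data, an
approximation under light missingness). Value agreement uses the scaled
tolerance 10⁻¹⁰ × the minimum absolute observed value of the phenotype; a
cell agrees only if saved everywhere and pairwise within tolerance.

Group comparisons: Lilliefors normality with a seeded Monte-Carlo null
(default 10⁴ draws — reproducible and accurate where printed tables are
not); Kruskal–Wallis omnibus; pairwise Dunn-type mean-rank comparisons with
the studentized-range critical value `q_{α,k,∞}/√2` (tie-corrected),
matching the Tukey–Kramer post-hoc convention; pairwise two-sample KS at
Bonferroni-adjusted α (0.05/21 ≈ 0.0024 for seven groups); Pearson χ² with
Cramér's V `√(χ²/(n·(min(r,c)−1)))` for categorical recovery data.

## Synthetic-data generator

The simulator emulates what the analysis chain assumes about real
recordings: a baseline with slow drift (1 % amplitude, 10 s timescale —
sum of a low-frequency sinusoid and a linear term, slow relative to events
so detrending is exercised but identifiable), additive Gaussian noise
(default sd 5×10⁻⁵ of baseline), ideal rectangular subpulses with
fractional-sample edges (the 200-sample filter itself creates the realistic
ramps), multiplicative blockage (a cell blocks a fraction of the
instantaneous current, so normalized amplitudes are drift-free), exponential
recovery deficits, and two artifact classes: truncated pulses
(`artifact_partial`, a leading subset of subpulses) and coincident cells
(`artifact_coincident`, scheduled inside another cell's transit). The
population model is lognormal in diameter (median at the device's nominal
diameter, σ_log 0.06), lognormal in velocity (median 10 µm/ms ≈ 1 cm/s —
slow enough that a 50 µm node outlasts the 4 ms filter ramp, so adjacent
subpulses resolve), a uniform contraction-slowdown ratio v_c/v₀ in
(0.35, 0.65), lognormal τ (median 20 ms, σ_log 0.3), uniform q₀ in
(0.1, 0.3) with a 15 % instantaneous-recovery fraction. Recovery timestamps
assume a constant post-contraction velocity equal to v₀.

What it does **not** emulate: electrokinetics and hydrodynamics (no
pressure-to-velocity physics, no cell–cell interactions), off-axis
amplitude corrections, non-Gaussian interference (line pickup, bubbles),
node-region current structure (nodes are zero-amplitude gaps), and the
shape evolution of a deforming cell beyond the scalar deficit. Passing
round-trip tests therefore demonstrates the correctness and numerical
accuracy of the analysis under its own signal model, not robustness to
every failure mode of a physical rig.

## Numerical and design choices

- Indices are 0-based, windows half-open `[start, end)`.
- Geometry in µm, time in ms internally, current dimensionless after
  normalization; velocities in µm/ms.
- Reference-pore counts are not fixed by the published designs; defaults
  are 2 reference and 6 recovery pores, both configurable (a τ fit needs
  at least 2 recovery time points).
- Edge pairing is greedy in index order with alternating direction; ties
  broken by the earlier index.
- The τ study population sets the instantaneous-recovery fraction to 0:
  a cell without an amplitude deficit carries no recovery constant.
- Degenerate inputs fail loudly: undeformed cells (d₀ ≤ w_c), amplitudes
  outside the invertible sizing range, all-equal ICC matrices, single-
  category κ tables, traces shorter than the filter.

## Problem sizes

The test and acceptance runs use 20-cell noiseless and 50–100-cell noisy
recordings (≈25–250 s of 50 kHz signal), a 10⁶-sample pure-noise trace for
the false-positive check, and 500 replicates of 7×150 draws for the
null calibration of the comparison suite; together they complete in well
under a minute. Larger recordings only lengthen the banded solves
linearly.

## Known limitations

- The recovery observable is amplitude-based; a physically derived shape
  relaxation model could map τ differently, so τ should be compared across
  conditions measured with the same pipeline rather than read as an
  absolute material constant.
- Coincident cells are rejected wholesale; no attempt is made to recover
  either cell from an overlap window.
- The NA-tolerant ICC mode is a least-squares approximation, not a REML
  variance-components fit; with heavy missingness prefer complete-case.
- Auto-thresholding ("0.5× median peak height") is validated by
  equivalence of detection with hand-set thresholds, not against any
  published definition.
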