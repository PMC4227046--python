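# Methods

## The measurement model

The pipeline reimplements the standard current-clamp characterization of
neonatal spinal motoneurons in slices:

- **Resting potential** — mean voltage over the 200 ms preceding current
  onset. The acquisition literature rarely states this window; 200 ms is our
  declared choice and is asserted as a precondition (shorter baselines raise).
- **Input conductance** — small 500 ms pulses (−100 to +20 pA in 30 pA
  steps, 10 repeats each); the steady-state deflection is the mean over the
  last 100 ms of the pulse (membrane time constants are ~10 ms, two orders
  below the window), repeats averaged, and G_in is the inverse slope of the
  least-squares V-on-I line.
- **Rheobase** — 5 s square pulses climbing a 50 pA grid from 0, switching
  to 100 pA steps above 0.9 nA; the first tested amplitude eliciting at
  least one spike is the rheobase. The grid quantizes upward: measured
  rheobase exceeds the cell's true threshold current by at most one step,
  about +25 pA on average in the fine regime.
- **Spikes** — local voltage maxima above 0 mV (overshoot criterion) with
  at least 1 ms separation and at least 10 mV prominence. The prominence
  requirement exists because a depolarized near-threshold plateau carries
  recording noise; without it a noisy plateau top could be mistaken for a
  spike.
- **Spiking threshold** — on the first spike of the 5 s pulse, the voltage
  at the first upstroke sample where dV/dt ≥ 10 mV/ms. The derivative is a
  central difference after a 0.2 ms boxcar (raw first differences at 10 kHz
  are noise-dominated). The implementation walks backward from the spike
  peak through the contiguous run where the criterion holds, which is robust
  to isolated noise excursions far from the spike.
- **Spike shape** — 30 trials of 1 ms suprathreshold pulses are aligned on
  the spike-peak sample and averaged (trials whose peak strays more than
  5 ms from the median are rejected); amplitude is peak minus pre-pulse
  baseline, half-width the time at or above baseline + amplitude/2 with
  linear interpolation at the flanks.
- **AHP** — V(t) = baseline − A·exp(−(t−t_trough)/τ) is least-squares
  fitted from the post-spike trough until the voltage recovers to within 5%
  of the trough depth (or the next stimulus). Troughs shallower than 0.5 mV
  are rejected as "no AHP".
- **Firing pattern** — on the rheobase sweep: *delayed* iff first-spike
  latency exceeds 500 ms, or exceeds 200 ms with a rising
  instantaneous-frequency trend (Theil–Sen slope of f against time > 0, at
  least 3 spikes); otherwise *immediate*. No numeric criterion exists in the
  literature; 500 ms sits far above immediate-onset latencies (tens of ms)
  and far below at-rheobase delays (seconds). Both cutoffs are configurable.
- **Ramps** — 0.1 nA/s triangular ramps to 1.5× the estimated rheobase
  (minimum 1 nA), three trials. Recruitment is the current at the first
  ascending spike (trial-averaged), derecruitment the current at the last
  descending spike; the frequency "0.5 s after recruitment" is the inverse
  of the ISI containing t_first + 0.5 s (an instantaneous reading, not a
  window average).
- **MMOs and the gain** — within each ISI (excluding 10 ms after the
  preceding spike and 5 ms before the next threshold crossing), subthreshold
  local maxima with ≥ 1 mV prominence below the measured threshold are
  counted on a 2.5 ms-boxcar-smoothed trace (MMOs live around 50–150 Hz,
  far below the smoothing corner; single-sample noise is suppressed). A
  cell is MMO-positive when ≥ 2 oscillations occur in each of ≥ 2 ISIs.
  The sub-primary/primary boundary is the current at the end of the last
  MMO-containing ascending ISI; the gain is the least-squares slope of
  frequency on current above that boundary, reported only when at least
  3 points span ≥ 0.05 nA of current (otherwise no linear primary range is
  identifiable — typical for delayed cells, whose ISIs at higher drive are
  too short to host countable oscillations).
- **Morphometry** — SWC trees; a *primary dendrite* is a soma-child
  subtree; a dendrite is excluded entirely if any of its nodes plunges
  deeper than 50 µm below the slice surface (coordinate convention: surface
  at z = 0, depth positive downward). Branching points are nodes with ≥ 2
  children (a trifurcation counts once); total length sums Euclidean
  inter-node distances; dendritic paths run from each terminal tip to the
  soma attachment node; terminal segments run from the tip to the nearest
  branch point. Soma area is an externally measured scalar passed through,
  never derived from SWC.
- **Statistics** — two-tailed Mann–Whitney U (exact below combined n = 20
  without ties, tie-corrected normal approximation otherwise), two-tailed
  Fisher exact by the probability-mass rule, two-sample two-sided KS, and a
  zero-intercept regression I = (U/1000)·G with U in mV. The slope standard
  error is sqrt(SSR/(n−1)/ΣG²) — the zero-intercept model spends one degree
  of freedom — and two slopes are compared by t = ΔU/√(SE²_A+SE²_B) with
  df = n_A+n_B−2, plus a Chow F test contrasting the pooled single-slope
  fit against separate fits, F(1, n_A+n_B−2). Both tests hold their nominal
  5% size under a Gaussian null (verified by simulation in the test suite).
  No multiple-testing correction is applied anywhere; each comparison
  reports a raw p. Liquid junction potential is not corrected.

## The synthetic population model

Each (genotype, pattern) group is parameterized by published summary rows
(mean ± SD, observed range, N). A naive truncated normal with the printed
mean/SD realizes a biased mean once truncated to the printed range, so all
scalar properties are drawn from **moment-matched truncated normals**: the
underlying (µ, σ) are solved so the realized truncated mean and SD equal the
printed values. For several rows the printed SD exceeds the supremum any
truncated normal supports on the printed interval (the uniform limit,
(max−min)/√12 — printed ranges are small-sample ranges and can be narrower
than ±2 SD); there the mean is matched exactly and the SD saturates at its
feasible maximum.

Conductance and rheobase are coupled through a Gaussian copula whose
correlation is calibrated — deterministically, on a fixed internal
quadrature sample, independent of the user's seed — so that the derived
voltage distance to threshold, ΔV = 1000·I/G (capped at 50 mV, see below),
reproduces the printed group ΔV mean. This keeps Ohm's law I = G·ΔV/1000
exact per cell, matches the strongly positive rheobase–conductance
correlation seen in such populations, and makes the conductance, rheobase
and ΔV rows simultaneously recoverable end to end for the immediate-firing
groups (calibrated ρ: WT-immediate +0.79, mSOD1-immediate −0.31,
WT-delayed +0.17).

ΔV is capped at 50 mV: published ΔV ranges top out at 49–50 mV and an
uncapped ratio tail would place spike thresholds above 0 mV, colliding with
the overshoot detection criterion. The rheobase is capped along with it so
the Ohmic relation stays exact. For the delayed groups the three rows
(G 52 nS, I 1.2 nA, ΔV 31 mV) are **mutually infeasible** under bounded
thresholds and exact per-cell Ohmic consistency — the covariance required
of (G, ΔV) exceeds the Cauchy–Schwarz bound — so the generator realizes the
conductance row exactly and lands ΔV near 27 mV with rheobase near 0.95 nA.
This mirrors the published observation that the effective zero-intercept
slope U (19–22 mV) sits well below the measured delayed-cell ΔV (31–33 mV):
delayed-cell thresholds measured on an accommodated first spike are
depolarized relative to the current–conductance relation.

Other generator conditions: first-spike latency of delayed cells at
rheobase drawn from 2.5 ± 1.0 s on [0.5, 4.5] s (a 5 s pulse must contain
the first spike); latency decays linearly with current,
latency(I) = delay_scale·max(0, (2·rheobase − I)/rheobase), vanishing at
2× rheobase; delayed discharge accelerates from 0.6× to 1.0× of its
steady rate across the pulse while immediate cells fire at a constant rate
(minimum rate 12 Hz at rheobase). MMO prevalence per group follows the
published counts (49/50, 31/31, 13/15, 3/11); oscillations are rendered as
2 mV damped 100 Hz wavelets inside ISIs, only below rheobase + 0.25 nA for
immediate cells (the sub-primary range) and at all currents for delayed
cells. AHP trough depth is 5 ± 1 mV on [2, 8] (not tabulated anywhere; a
typical neonatal value), trace noise 0.3 mV white, membrane time constant
10 ms. Spike waveforms are piecewise-linear (rise to peak, fall to the AHP
trough, then exponential recovery) with the rise kept steeper than
15 mV/ms so the threshold criterion always fires on the upstroke, and the
rise duration snapped to the sample grid so rendered peaks are exact.
Steps and brief pulses are sampled at 10 kHz; ramps at 2 kHz (spike timing,
not waveform detail, is what ramps are analyzed for).

`mechanistic` mode integrates (Euler, at the sweep's dt) a leaky
integrate-and-fire cell with C = G_in·τ_m; delayed cells add a potassium
conductance g_K = 1.5·G_in (E_K = V_rest − 15 mV) that is fully available
at rest and inactivates with time constant delay_scale/3 upon
depolarization, producing delayed, accelerating discharge dynamically. Its
asymptotic rheobase equals G·ΔV/1000, so template and mechanistic searches
agree within one grid step (asserted in the tests). MMOs are not modeled
mechanistically.

Synthetic trees draw the number of primary dendrites, bifurcation count and
post-filter total length from the published morphology rows; bifurcations
are spread across dendrites and each dendrite grows by repeatedly splitting
a random terminal segment. Raw segment lengths come from the
terminal-segment row and are rescaled so the in-plane total equals the
drawn target exactly; nodes are 10 µm steps with angular jitter, depths
bounded by a per-dendrite excursion (≤ 45 µm). With probability 0.3 an
extra dendrite plunges past the 50 µm limit to exercise the slice filter.
The mSOD1-delayed branching row is not published; it is reconstructed from
the published length-vs-branching regression (8.7 mm at 0.18 mm/branch →
48 ± 16).

## What the synthetic data does and does not show

The generator reproduces the *summary structure* of the study populations
(group means/SDs/ranges, the Ohmic rheobase–conductance law, the firing-
pattern phenomenology, MMO prevalence, slice-truncated morphology) but not
the biophysics behind them: no channel kinetics, no synaptic noise, no
electrode/bridge artifacts, no correlated drift, and spike waveforms are
stereotyped rather than conductance-generated. Passing recovery tests
therefore demonstrates that the measurement pipeline is unbiased and
correctly calibrated for data with the published statistics — not that it
is robust to every artifact of real recordings.

## Problem sizes and numerical choices

Recovery tests use 500-cell populations for step/I–V criteria, 200 cells
for ramp criteria and 400 trees for morphometry; these sizes put the Monte
Carlo standard error of each recovered mean several times below its stated
tolerance. All randomness is threaded through explicit integer seeds
(per-cell seeds are drawn once at sampling time, below 2³¹), so identical
seeds give bit-identical sweeps, trees and tables. Degenerate inputs fail
loudly with typed errors (validation vs analysis), and the CLI maps them to
exit codes 2 and 3 respectively. Curve fits are initialized from the data
(trough depth, one-third window for τ) and the AHP fit is linear in all but
τ, making convergence failures essentially impossible on in-contract
input.

## Known limitations

- The printed SDs of a few rows are unreachable on their printed ranges
  (see above); sampled SDs saturate below the printed value there.
- Delayed-group rheobase and ΔV cannot both match their printed rows under
  exact per-cell Ohmic consistency; conductance is prioritized.
- The exact two-tailed Fisher p for the published pattern-proportion table
  (63/31 vs 31/18) recomputes to 0.71; the source prints 0.5 (likely
  rounding or a different tabulation). The test suite asserts the
  recomputed value.
- Descending-phase gain, Sholl-type morphometrics and per-animal clustering
  are out of scope.
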