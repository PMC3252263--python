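# Methods

## Model and assumptions

Each neuron is treated as a limit-cycle oscillator of intrinsic period
`P_i` whose state between spikes is summarized by a phase `φ ∈ [0, 1)`
growing at rate `1/P_i`. Coupling is pulsatile: a presynaptic spike
delivers, after a conduction delay, a single perturbation whose entire
effect is the first-cycle phase resetting `f(φ)` — the normalized change
in the length of the cycle containing the input. This presumes (a) each
neuron remains a pacemaker inside the circuit, (b) the effect of one
input dies out before the next arrives (the neuron is back on its limit
cycle when the next input lands), and (c) inputs inside the closed loop
resemble the open-loop stimuli used to measure the PRC. Positive
resetting delays the next spike; negative advances it. Advances are
bounded by the causal limit `f(φ) ≥ φ − 1` (an input cannot evoke a spike
before itself); evaluation clamps the fitted polynomial to that floor,
and on the clamped branch the slope is exactly 1 (the slope at the
junction is reported as the causal-side value, since near-limit stability
is the question of interest there).

Second-cycle resetting is out of scope: the lockings analyzed here feed
back within `k` cycles through the loop, which the periodicity
constraints account for explicitly.

## PRC measurement sets and fitting

A measurement set is a list of (phase, resetting) pairs from repeated
single-pulse stimulation. Fitting reproduces the standard protocol:
100 equal-width phase bins, bins with fewer than 3 values pooled with
both immediate neighbors (repeatedly, until every surviving bin is full;
a merged bin is centered on its samples' mean phase); polynomials of
degree 2, 3 and 4 are fitted to the binned means by least squares and the
degree is selected by AIC on the binned means, ties to the lower degree.
A literal "lower squared error for the quadratic" rule cannot select
degrees among nested least-squares fits (the error is monotone in
degree), so parsimony is enforced through the AIC penalty instead; the
binned means carry an O(width²) curvature bias, which is why "exact"
recovery of a noiseless generating polynomial means ~1e-5, not machine
precision. Envelope polynomials of the same degree are fitted to the
binned mean ± one binned standard deviation; the noise s.d. used for
simulation is half the envelope difference, floored at zero.

For excitatory sets, positive resetting values at phases later than 0.9
(configurable) are removed before binning: advances longer than the time
remaining to the next spike cannot be observed, which biases very late
phases toward small spurious delays.

Classification is phenomenological: the fitted mean curve is sampled on
(0.01, 0.99); it is Type II when values of both signs exceeding 2% of the
curve's maximum magnitude occur, Type I otherwise (the threshold keeps
fit jitter around zero from flipping the label; a zero curve is Type I by
convention).

Noisy resetting draws are Gaussian with the model mean and σ(φ); draws
below the causal limit are rejected and redrawn (error after 1000
rejections, signaling an inconsistent envelope). At a locking point on
the limit this truncation halves the effective noise — the mechanism
behind the tightness of near-causal-limit synchrony.

## Synthetic templates: the study conditions

Four archetypes cover what dynamic-clamp measurements of entorhinal
cortical cells show. The polynomial coefficients are this package's
parameterization of the published *shapes*; amplitudes are free because
absolute resetting depends on the synaptic conductance used. Defaults
were designed against the qualitative mode structure the theory predicts
(below) and then frozen; they are the package's study conditions.

- `exc_I` — `f(φ) = −4s·φ(1−φ)`, `s = 0.4`: advances only, ≈0 at the
  endpoints, single extremum; clamps onto the causal limit for
  `φ ≥ 1/(4s) = 0.625`. Consequences: bistable leader/follower modes at
  short delays (the follower, reset on the limit, fires after exactly the
  conduction delay), stable antiphase at intermediate delays, and a
  `k = 2` synchronous mode at long delays.
- `exc_II` — `s/0.105 · φ(φ−0.2)(φ−1)`, `s = 0.16`: small delays before
  φ = 0.2 (peak ≈ 8.6% of the amplitude — "weakly" Type II), advances
  elsewhere; rides just *above* the causal limit near φ = 0.9 (slope
  0.72) and clamps onto it for φ ≳ 0.92. Keeping the curve slightly off
  the limit matters: exactly on it the synchronous multiplier
  `|1 − 2f′| = 1` is neutral and the lag random-walks within a reflecting
  band, smearing the histogram; just above it the mode contracts each
  cycle and synchrony is tight.
- `inh_I` — `f(φ) = (s−g) + g(0.3φ + 0.7φ²)`, `s = 0.45`: delays only,
  monotonically increasing, not returning to zero at φ → 1. The
  endpoint discontinuity `g = f(1⁻) − f(0⁺)` is a parameter (default:
  the full amplitude `s`). The amplitude must dominate the `inh_II`
  curve at every phase — otherwise a mixed I+II circuit finds
  near-exact synchrony at mid delays, which the theory for these cells
  excludes.
- `inh_II` — quartic whose derivative has roots at 0.10, 0.85 and 1.4,
  scaled to peak delay `s = 0.15`: small early advances (to φ ≈ 0.25),
  rising delays, and a second region of negative slope at very late
  phases. That late downturn is what destabilizes antiphase at longer
  delays; the early negative slope is what forbids synchrony at very
  short ones. Net structure over normalized delay: antiphase only near
  0.09, bistability (antiphase + synchrony) around 0.19, synchrony only
  by 0.31.

Noise envelopes (the measured quantity the sources do not print
numerically): excitatory σ(φ) = 0.05·(1 − 0.9φ) — substantial early
variability, strongly quieted approaching the causal limit, where an
excitatory input triggers a spike almost deterministically; inhibitory
σ = 0.02, phase-independent. The excitatory late-phase quieting is chosen
so the map reproduces the observed contrast between broad antiphase
histograms and narrow causal-limit synchrony peaks.

Measurement phases are sampled uniformly on [0, 1): the wet protocol's
every-sixth-cycle timing matters only through the (phase, resetting)
pairs it produces. What the generator does *not* emulate: slow drift of
the intrinsic period, non-Gaussian resetting noise, second-cycle
resetting, and conductance-waveform effects — passing tests show the
theory-to-map pipeline is self-consistent under the stated noise model,
not that these omitted features are negligible in tissue.

## Locking existence

With stimulus interval `ts_i = P_i φ_i` and recovery interval
`tr_i = P_i (1 − φ_i + f_i(φ_i))`, a 1:1 locking with feedback index `k`
(the number of cycles for a spike's effect to return to its emitter)
satisfies both of

    δ12 + δ21 + tr_1 = ts_2 + (k−1)(ts_2 + tr_2)
    δ12 + δ21 + tr_2 = ts_1 + (k−1)(ts_1 + tr_1)

which jointly force the two network periods `P_N,i = ts_i + tr_i` to be
equal. Time lags follow as `tl_1 = (ts_1 − δ21) mod P_N`,
`tl_2 = P_N − tl_1`. Roots are located by evaluating both residuals on an
n×n phase grid (default 800), refining every cell whose corners show both
signs in both residuals by nested bisection (the inner variable solved by
Brent's method on a bracket widened by one cell) to a residual below
1e-10·P_slow, and deduplicating phases closer than 1e-5 (refined roots of
the same mode from adjacent cells scatter at ~1e-6). Non-transversal
intersections — e.g. the solution continuum of an uncoupled
zero-resetting pair — are detected by a vanishing residual Jacobian,
logged, and skipped. Solutions with negative recovery intervals are
discarded. `k` runs to 3 by default, enough for delays up to about one
period.

Modes are labeled synchrony when `min(tl)/P_N < 0.02` (the sweep
increment), antiphase when the lags differ by less than 0.02·P_N, and
leader/follower when the short lag is within 0.1·P_N of the mean
conduction delay.

## Stability

The graphical rule — the locking is stable when one neuron's
interval-return curve is steeper than the partner's reversed curve at the
intersection — is applied analytically. For `k = 1` the interval map
`ts_2[n+1] = 2δ + tr_1((2δ + tr_2(ts_2[n]/P_2))/P_1)` has multiplier
`(f_1′ − 1)(f_2′ − 1)`; the general curve-slope comparison is

    |(f_1′ − 1)(f_2′ − 1)|  <  |(1 + (k−1) f_1′)(1 + (k−1) f_2′)|

with the slopes taken at the locking phases (slope 1 on the causal
branch). Marginal modes (multiplier within 1e-6 of 1) are reported
unstable: knife-edge solutions are not attracting. Synchronous modes must
additionally satisfy `|1 − (f_1′ + f_2′)| < 1` — positive slopes
stabilize, negative and very large positive slopes destabilize. Two
special rules:

- **Causal limit.** Exactly on the limit both slopes are 1 and the
  synchrony criterion is marginal; such lockings are reported stable and
  flagged `neutral-at-limit` (physically the limit cannot quite be
  reached, and the approach from above is contracting).
- **Inhibitory discontinuity.** A strong inhibitory PRC ends higher than
  it starts (`f(1⁻) > f(0⁺)`, gap > 0.01). For a synchronous locking
  phase within 0.02 of 0 or 1, the slope criterion is overridden to
  unstable: the neuron that fires slightly early delays its partner by
  ~`P·f(1⁻)`, so perturbations from zero-delay synchrony grow. A short
  conduction delay moves the locking point off the discontinuity and
  returns control to the slopes.

## Heterogeneity lag

Linearizing both PRCs about the homogeneous synchronous locking point
(`δ/P_i` for each neuron, `δ` the mean delay) and equating the two
network periods gives the near-synchronous lag of neuron 2 behind
neuron 1,

    ε = Δδ/2 + [P_2 (1 + f_2(δ/P_2)) − P_1 (1 + f_1(δ/P_1))] / [f_1′ + f_2′]

with `Δδ = δ12 − δ21`. Identical neurons with equal delays give ε = 0
exactly. With both locking points on the causal limit the bracket is
`δ − δ = 0` for *any* intrinsic periods or PRCs, and the slopes are 1, so
ε = Δδ/2 — near-causal-limit synchrony is intrinsically robust to period
heterogeneity. The expression is valid while the perturbed locking
points stay in a linear neighborhood; the function refuses
configurations whose homogeneous synchronous point is absent or
unstable.

## The event-driven map

Simulation state is the two phases, the elapsed time, and a queue of
emitted-but-undelivered pulses. The next event is the earlier of the next
spike (`P_j (1 − φ_j)` away) and the next queued arrival; at a spike the
phase resets to 0 and an emission is enqueued; at an arrival
`φ ← φ − f(φ)` with `f` drawn noisily (or the mean, noise off). An
arrival pushing the phase to ≥ 1 fires the neuron at the arrival time —
the causal-limit "input evokes a spike immediately" behavior. Arrivals
tied with a spike are processed after it (the input acts at `f(0⁺)` of
the new cycle; a switch exposes the opposite convention for probing the
discontinuity mechanism); queued arrivals apply in emission order; an
arrival at negative phase (possible after strong inhibition) evaluates
the PRC at 0. A guard aborts if the event rate diverges.

Lags are measured spike by spike, as in a recording: `tl_1` from each
spike of neuron 1 to the next spike of neuron 2, `tl_2` symmetrically.
(Measuring within hard cycle windows instead censors the partner-leads
side whenever jittered near-synchrony flips the firing order, biasing
the mean phase — the per-spike definition is unbiased.) Lags beyond 1.75
times the faster rhythm's mean interval mean the partner skipped a cycle
(a doublet); they are excluded and counted. Default 5000 cycles per run
after a 200-cycle burn-in — enough for ±0.01 reproducibility of peak
locations across seeds at desk scale.

Histograms plot `+tl_1` and `−tl_2` in units of the slower neuron's
period on (−1.5, 1.5) (network periods under inhibition exceed the
intrinsic period, so the support passes ±1). Peaks are counted with a
prominence threshold of 10% of the tallest peak and a 3-bin minimum
separation — enough to separate substantive mode peaks from
minority-leader remnants. Bistable circuits are sampled by pooling two
runs started on either side of the basin boundary
(`run_map_pooled`, initial offsets 0.5 and 0.05): a single run samples
the second basin only through rare noise-driven hops, making peak counts
a seed lottery, while pooling makes every coexisting attractor's peaks
structural — the analogue of an experimental histogram containing
episodes of both firing patterns. Homogeneous bistable sampling then
shows 2 antiphase + 3 synchrony peaks (the 3 because either neuron can
lead); 4% period heterogeneity fixes the leader, removing one peak from
each synchrony-containing histogram.

## Circular statistics

Each lag maps to an angle `θ = 2π·tlag/P_net` with `P_net` the mean
network period of the series; `X` and `Y` are the *means* of cos θ and
sin θ (so `R² = X² + Y² ∈ [0, 1]`; sum conventions would not be bounded),
the mean network phase is `atan2(Y, X)/2π mod 1`, and R² measures locking
tightness. Both lag directions are pooled by default (`tl_1/P_net` and
`1 − tl_2/P_net` address the same circle point in a perfect locking);
single-direction pooling is available. A vanishing resultant is flagged
rather than assigned a phase.

## Numerical choices and limitations

- Delay sweeps use a 0.02 normalized-delay increment and normalize all
  outputs by the slower neuron's intrinsic period; signed lags
  (`tl_1 > 0`, `tl_2 < 0`) support bifurcation-style diagrams.
- Solver grids: 800 (default) / 600 (sweeps) / 400 (large randomized
  batteries); at 400 the coarsest structure resolved is ~2.5e-3 in
  phase, ample for modes separated by ≥ 0.02.
- The zero-noise map and the solver agree on stability across a
  randomized battery (≥ 95% required in the test suite; residual
  disagreements sit at criterion boundaries, e.g. near-marginal slopes).
- Problem sizes (2000-sample measurement sets, 5000-cycle runs, 200-case
  batteries) are desk-scale choices that keep the full suite and the
  acceptance script in the minutes range.
- Only two oscillators, delta-pulse coupling, and first-cycle resetting
  are modeled; conductance waveforms, refractoriness, and N > 2 networks
  are out of scope.
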