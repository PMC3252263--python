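# prcsync

Phase-resetting-curve (PRC) based prediction and simulation of
synchronization in circuits of two reciprocally pulse-coupled neuronal
oscillators with axonal conduction delays.

Distant neural populations manage to fire in near-synchrony despite the
milliseconds it takes a spike to travel between them. For two pacemaker
neurons coupled by brief synaptic pulses, everything needed to predict the
circuit's rhythm is contained in each neuron's PRC: the normalized change
in cycle period, `f(φ) = (P_pert − P) / P`, caused by a single input at
phase `φ = ts / P` (positive resetting = delay, negative = advance; an
advance is bounded by the *causal limit* `f(φ) ≥ φ − 1`, where an input
fires the cell immediately). `prcsync` implements that program end to end
for people studying pulse-coupled oscillator circuits:

- **`prcsync.prc`** — fit polynomial PRC models (with ±σ noise envelopes)
  to noisy (phase, resetting) measurements, classify them as Type I
  (single-signed) or Type II (mixed advances and delays), evaluate them
  with the causal limit enforced, and draw causality-respecting noisy
  resetting samples.
- **`prcsync.templates`** — synthetic-data generators: the four canonical
  PRC archetypes seen in entorhinal cortical cells under dynamic clamp
  (`exc_I`, `exc_II`, `inh_I`, `inh_II`), measurement-set simulation, and
  two-neuron circuit construction with period heterogeneity and unequal
  delays.
- **`prcsync.locking`** — existence and stability of 1:1 phase-locked
  modes. A locking with feedback index `k` satisfies, for both neurons,
  `δ₁₂ + δ₂₁ + tr_i = ts_j + (k−1)·P_N` with `ts_i = P_i φ_i`,
  `tr_i = P_i (1 − φ_i + f_i(φ_i))`, and `P_N` the network period.
  Stability comes from the PRC slopes at the two locking points
  (slope-comparison rule; for synchrony additionally
  `|1 − (f₁′ + f₂′)| < 1`, plus the rule that an inhibitory PRC with an
  endpoint discontinuity `f(1⁻) > f(0⁺)` destabilizes zero-delay
  synchrony). Includes delay sweeps and the closed-form near-synchronous
  lag under small heterogeneity,
  `ε = Δδ/2 + [P₂(1+f₂(δ/P₂)) − P₁(1+f₁(δ/P₁))] / [f₁′ + f₂′]`.
- **`prcsync.pulsemap`** — an event-driven noisy iterated map of the two
  delayed oscillators (spikes and delayed pulse arrivals as events;
  resetting drawn from the PRC's noise envelope), with per-cycle time-lag
  series and signed lag histograms.
- **`prcsync.circstats`** — circular statistics of the lags: mean network
  phase and locking strength `R² = X² + Y²`.

## Worked example

Two identical unit-period neurons with weakly Type II excitatory PRCs
(small delays before phase 0.2, advances elsewhere, causal-limit branch
late in the cycle):

```bash
prcsync make-data --template exc_II --period 1.0 --seed 3 --out-prefix demo
prcsync simulate demo.circuit.json --delay-norm 0.55 --n-cycles 5000 --seed 1 --out-prefix demo055
prcsync simulate demo.circuit.json --delay-norm 0.9  --n-cycles 5000 --seed 1 --out-prefix demo09
```

prints

```
exc_II: 2000 samples, model and circuit -> demo.*
4999 cycles (0 doublet cycles dropped); mean network phase 0.502, R^2 0.901 -> demo055.*
5000 cycles (0 doublet cycles dropped); mean network phase 0.000, R^2 0.995 -> demo09.*
```

At a conduction delay of 0.55 periods the circuit locks in **antiphase**
(mean network phase 0.5) and the locking is loose (R² ≈ 0.90): the locking
point falls on the noisy early branch of the PRC. Lengthening the delay to
0.9 periods moves the locking point into the quiet causal-limit region,
and the circuit snaps into **tight zero-lag synchrony** (phase 0.00,
R² ≈ 0.99) — delays *longer than half a period* are what make mutual
excitation synchronize. Refitting the generated samples recovers the
model:

```bash
prcsync fit demo.samples.csv --coupling excitatory --out demo.refit.json
# fitted Type II excitatory PRC (degree 4, endpoint gap +0.015) -> demo.refit.json
```

and `prcsync sweep demo.circuit.json --out sweep.csv` tabulates the
stable 1:1 modes on a 0.02 grid of normalized delays (the bifurcation
diagram behind the histograms). The library calls behind the CLI:

```python
from prcsync import make_template, make_circuit, find_lockings

t = make_template("exc_I")
pair = make_circuit(t, t, period_a=1.0)
for m in find_lockings(pair.with_normalized_delay(0.04)):
    print(m.k, m.mode_class, round(m.tl_1, 3), round(m.tl_2, 3), m.stable)
# 1 leader_follower 0.04 0.842 True
# 1 antiphase 0.316 0.316 False
# 1 leader_follower 0.842 0.04 True
# 2 synchrony 0.939 0.0 False
```

— at short delays the excitatory Type I pair is bistable between two
leader/follower patterns whose short lag equals the conduction delay.

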