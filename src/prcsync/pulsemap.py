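"""Event-driven noisy iterated map of two delayed pulse-coupled oscillators.

Each neuron is a phase oscillator: its phase grows linearly at rate
``1/P_j`` and it spikes at phase 1, resetting to 0 and emitting a pulse
that arrives at the partner after the directional conduction delay.  The
simulation advances event by event: the next event is whichever comes
first of (a) a spike, after ``P_j (1 - phi_j)``, or (b) the arrival of a
queued pulse.  An arriving input at phase ``phi`` subtracts the resetting
from the current phase, ``phi <- phi - f(phi)``, with ``f`` drawn from the
PRC's Gaussian noise envelope when noise is on (draws violating causality
rejected) or taken as the mean when off.  An input that pushes the phase
to or past 1 evokes a spike immediately — the causal-limit behavior.

Tie-breaks: an arrival coinciding exactly with a spike is processed after
the spike, so the input acts at phase 0 of the new cycle (switchable, for
probing the inhibitory endpoint-discontinuity mechanism); simultaneous
arrivals apply in emission order.  An arrival while the phase is negative
(a preceding strong inhibition pushed it below 0) evaluates the PRC at
phase 0.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .locking import CircuitSpec
from .prc import evaluate_prc, sample_noisy_resetting

__all__ = ["LagSeries", "run_map", "run_map_pooled", "lag_histogram", "count_peaks"]

DEFAULT_BURN_IN = 200
_MAX_EVENTS_PER_CYCLE = 50  # period-collapse guard


@dataclass
class LagSeries:
    """Per-cycle time lags between the two neurons, in ms.

    ``tl_1[n]`` is the interval from the n-th retained spike of neuron 1 to
    the next spike of neuron 2 (wherever it falls), and ``tl_2[n]`` the
    interval from the n-th retained spike of neuron 2 to the next spike of
    neuron 1 — the two directly measurable lags of a hybrid-circuit
    recording.  In a 1:1 locking ``tl_1 + tl_2`` equals the network
    period; the mean network period is estimated from the interspike
    intervals.  Doublet cycles (a lag exceeding ~1.75 network periods,
    i.e. the partner skipped a cycle) are excluded and counted.
    """

    tl_1: np.ndarray
    tl_2: np.ndarray
    period_norm: float           # slower neuron's intrinsic period (ms)
    n_doublets: int = 0
    mean_network_period_: float | None = None

    def __post_init__(self) -> None:
        self.tl_1 = np.asarray(self.tl_1, dtype=float)
        self.tl_2 = np.asarray(self.tl_2, dtype=float)

    def __len__(self) -> int:
        return min(self.tl_1.size, self.tl_2.size)

    @property
    def network_periods(self) -> np.ndarray:
        n = len(self)
        return self.tl_1[:n] + self.tl_2[:n]

    @property
    def mean_network_period(self) -> float:
        if self.mean_network_period_ is not None:
            return self.mean_network_period_
        return float(self.network_periods.mean())


def run_map(
    spec: CircuitSpec,
    n_cycles: int = 5000,
    noise: bool = True,
    seed: int | np.random.Generator | None = None,
    phi_init: tuple[float, float] = (0.0, 0.5),
    burn_in: int = DEFAULT_BURN_IN,
    arrival_before_spike: bool = False,
) -> tuple[dict[int, np.ndarray], LagSeries]:
    """Simulate the circuit for ``n_cycles`` cycles (after ``burn_in``).

    Returns ``(spike_log, lags)`` where ``spike_log`` maps neuron index
    (1, 2) to spike-time arrays in ms and ``lags`` is the per-cycle
    :class:`LagSeries` with burn-in cycles discarded.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not (0 <= phi_init[0] < 1 and 0 <= phi_init[1] < 1):
        raise ValueError("phi_init must lie in [0, 1)^2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    periods = (spec.period_1, spec.period_2)
    prcs = (spec.prc_1, spec.prc_2)
    delays = {0: spec.delay_12, 1: spec.delay_21}  # delays[i]: i -> other
    phi = [float(phi_init[0]), float(phi_init[1])]
    t = 0.0
    heap: list[tuple[float, int, int]] = []  # (arrival time, seq, target)
    seq = 0
    spikes: dict[int, list[float]] = {0: [], 1: []}
    total = n_cycles + burn_in
    max_events = _MAX_EVENTS_PER_CYCLE * total * 2

    def resetting(j: int, ph: float) -> float:
        ph = min(max(ph, 0.0), 1.0 - 1e-12)
        if noise:
            return sample_noisy_resetting(prcs[j], ph, rng)
        return evaluate_prc(prcs[j], ph)

    def fire(j: int, now: float) -> None:
        nonlocal seq
        spikes[j].append(now)
        phi[j] = 0.0
        heapq.heappush(heap, (now + delays[j], seq, 1 - j))
        seq += 1

    events = 0
    while min(len(spikes[0]), len(spikes[1])) < total + 1:
        events += 1
        if events > max_events:
            raise RuntimeError(
                "event rate diverged (period collapse); aborting at "
                f"t={t:.3f} ms with {len(spikes[0])}/{len(spikes[1])} spikes")
        t_spike = [t + periods[j] * (1.0 - phi[j]) for j in (0, 1)]
        j_spk = 0 if t_spike[0] <= t_spike[1] else 1
        t_next_spike = t_spike[j_spk]
        t_arr = heap[0][0] if heap else np.inf

        if t_arr < t_next_spike or (t_arr == t_next_spike and arrival_before_spike):
            t_arr, _, target = heapq.heappop(heap)
            dt = t_arr - t
            for j in (0, 1):
                phi[j] += dt / periods[j]
            t = t_arr
            phi[target] -= resetting(target, phi[target])
            if phi[target] >= 1.0:
                fire(target, t)
        else:
            dt = t_next_spike - t
            for j in (0, 1):
                phi[j] += dt / periods[j]
            t = t_next_spike
            fire(j_spk, t)

    s1 = np.array(spikes[0])
    s2 = np.array(spikes[1])
    lags = _lags_from_spikes(s1, s2, burn_in, spec.period_slow)
    return {1: s1, 2: s2}, lags


def _next_partner_lags(anchor: np.ndarray, partner: np.ndarray) -> np.ndarray:
    """Interval from each anchor spike to the next partner spike."""
    j = np.searchsorted(partner, anchor, side="left")
    valid = j < partner.size
    return partner[j[valid]] - anchor[valid]


def _lags_from_spikes(s1: np.ndarray, s2: np.ndarray, burn_in: int,
                      period_norm: float) -> LagSeries:
    """Measure both lag directions spike by spike.

    tl_1 is taken from every neuron-1 spike after burn-in to the next
    neuron-2 spike, tl_2 symmetrically.  Lags longer than 1.75 mean network
    periods mean the partner skipped a cycle (a doublet); those are
    excluded and counted.
    """
    a1 = s1[burn_in:-1]
    t0 = a1[0] if a1.size else (s1[0] if s1.size else 0.0)
    a2 = s2[s2 >= t0]
    tl1 = _next_partner_lags(a1, s2)
    tl2 = _next_partner_lags(a2[:-1] if a2.size else a2, s1)
    isis = []
    if a1.size > 1:
        isis.append(np.diff(a1).mean())
    if a2.size > 1:
        isis.append(np.diff(a2).mean())
    pn = float(np.mean(isis)) if isis else period_norm
    # cut on the faster rhythm: robust when the pair is not 1:1 locked
    cut = 1.75 * (float(np.min(isis)) if isis else period_norm)
    doublets = int((tl1 > cut).sum() + (tl2 > cut).sum())
    return LagSeries(tl1[tl1 <= cut], tl2[tl2 <= cut], period_norm,
                     doublets, mean_network_period_=pn)


def run_map_pooled(
    spec: CircuitSpec,
    n_cycles: int = 5000,
    noise: bool = True,
    seed: int | None = None,
    phi_inits: tuple[tuple[float, float], ...] = ((0.0, 0.5), (0.0, 0.05)),
    burn_in: int = DEFAULT_BURN_IN,
) -> LagSeries:
    """Pool lag series from runs started at several initial conditions.

    A bistable circuit visits whichever attractor its initial condition
    selects; pooling runs started on either side of the basin boundary
    samples every coexisting mode, the way experimental histograms at a
    sharp transition contain episodes of both firing patterns.
    """
    parts = []
    for j, init in enumerate(phi_inits):
        s = None if seed is None else seed * 131 + j
        _, lags = run_map(spec, n_cycles=n_cycles, noise=noise, seed=s,
                          phi_init=init, burn_in=burn_in)
        parts.append(lags)
    return LagSeries(
        np.concatenate([p.tl_1 for p in parts]),
        np.concatenate([p.tl_2 for p in parts]),
        parts[0].period_norm,
        sum(p.n_doublets for p in parts),
        mean_network_period_=float(np.mean([p.mean_network_period for p in parts])),
    )


def lag_histogram(
    series: LagSeries,
    bins: int = 121,
    lag_range: tuple[float, float] = (-1.5, 1.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed normalized lags (tl_1 positive, tl_2 negative).

    Lags are normalized by ``series.period_norm``.  Returns
    ``(bin_centers, density)`` with the density integrating to one; the
    two lag directions are pooled, so synchrony in a homogeneous circuit
    shows three peaks (0 and +/- the network period) and antiphase two.
    """
    if len(series) < 100:
        raise ValueError("need >= 100 cycles for a lag histogram")
    vals = np.concatenate([series.tl_1, -series.tl_2]) / series.period_norm
    density, edges = np.histogram(vals, bins=bins, range=lag_range, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def count_peaks(
    density: np.ndarray,
    min_prominence_frac: float = 0.10,
    min_separation_bins: int = 3,
) -> int:
    """Number of histogram peaks, by prominence relative to the tallest.

    A mode of the circuit shows up as a peak; bistable sampling shows the
    peaks of both modes at once.
    """
    from scipy.signal import find_peaks

    d = np.asarray(density, dtype=float)
    if d.max() <= 0:
        return 0
    # pad so peaks in the first/last bin are countable
    padded = np.concatenate([[0.0], d, [0.0]])
    peaks, _ = find_peaks(
        padded,
        prominence=min_prominence_frac * d.max(),
        distance=min_separation_bins,
    )
    return int(peaks.size)
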