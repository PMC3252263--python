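"""Existence and stability of 1:1 phase-locked modes with conduction delays.

Two pacemaker neurons, pulse-coupled with conduction delays, admit 1:1
periodic firing patterns characterized by the phases ``(phi_1, phi_2)`` at
which each neuron receives its partner's input.  With stimulus interval
``ts_i = P_i phi_i`` and recovery interval
``tr_i = P_i (1 - phi_i + f_i(phi_i))``, periodicity demands, for both
orderings of the pair::

    delay_12 + delay_21 + tr_i = ts_j + (k - 1) * P_N,j

where ``P_N,j = ts_j + tr_j`` is the network period and the integer
feedback index ``k`` counts the cycles a spike's effect takes to loop back
to its emitter.  Both constraints together force ``P_N,1 = P_N,2``.

Stability follows the graphical slope rule: each constraint defines an
interval-return curve per neuron, and a locking is stable when the curve of
one neuron is steeper than the reversed curve of the other at the
intersection.  Analytically the per-cycle perturbation multiplier is::

    lambda = (f_1' - 1)(f_2' - 1) / [(1 + (k-1) f_1')(1 + (k-1) f_2')]

evaluated at the locking phases (derived from the interval map
``ts_2[n+1] = 2*delay + tr_1((2*delay + tr_2(ts_2[n]/P_2))/P_1)`` for k=1,
whose multiplier is the numerator).  Synchronous modes additionally require
``|1 - (f_1'(phi*) + f_2'(phi*))| < 1``; exactly on the causal limit the
slopes are one and synchrony is neutrally stable (flagged, reported
stable).  A strong inhibitory PRC with endpoint discontinuity
``f(1-) > f(0+)`` destabilizes zero-delay synchrony regardless of slopes: a
neuron firing slightly early delays its partner by ``~f(1-)``, and the
perturbation grows.  A short conduction delay moves the locking point away
from the discontinuity and restores the slope criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root as _root2d

from .prc import PRCModel, evaluate_prc, prc_slope

__all__ = [
    "CircuitSpec",
    "LockingMode",
    "interval_curves",
    "find_lockings",
    "assess_stability",
    "delay_sweep",
    "heterogeneity_lag",
]

logger = logging.getLogger(__name__)

#: modes are synchronous (antiphase) when min(tl)/P_N (lag asymmetry) is
#: below this; matches the 0.02 sweep increment of the graphical method
CLASS_TOL = 0.02
#: synchronous locking phases within this distance of 0 or 1 trigger the
#: endpoint-discontinuity rule for inhibitory PRCs
JUNCTION_TOL = 0.02
#: smallest endpoint gap counted as a genuine discontinuity
GAP_TOL = 0.01
#: residual tolerance for accepted lockings, relative to the slow period
RESIDUAL_RTOL = 1e-10
#: (phi_1, phi_2) closer than this are the same mode (refinement drives the
#: residual below 1e-10*P, which can still leave ~1e-6 phase scatter between
#: the same root found from adjacent cells)
DEDUP_TOL = 1e-5


@dataclass
class CircuitSpec:
    """Two oscillators, their PRCs, and directional conduction delays (ms)."""

    period_1: float
    period_2: float
    prc_1: PRCModel
    prc_2: PRCModel
    delay_12: float
    delay_21: float

    def __post_init__(self) -> None:
        if self.period_1 <= 0 or self.period_2 <= 0:
            raise ValueError("periods must be positive")
        if self.delay_12 < 0 or self.delay_21 < 0:
            raise ValueError("delays must be >= 0")

    @property
    def coupling_sign(self) -> str:
        return self.prc_1.coupling_sign

    @property
    def period_slow(self) -> float:
        """Normalization period: the slower neuron's intrinsic period."""
        return max(self.period_1, self.period_2)

    @property
    def delay_sum(self) -> float:
        return self.delay_12 + self.delay_21

    def with_normalized_delay(self, delay_norm: float, delta_delay: float = 0.0
                              ) -> "CircuitSpec":
        """Copy with mean delay ``delay_norm * period_slow`` in both directions."""
        d = delay_norm * self.period_slow
        return replace(self, delay_12=d + delta_delay / 2.0,
                       delay_21=d - delta_delay / 2.0)


@dataclass
class LockingMode:
    """One 1:1 periodic solution with its intervals, lags and stability."""

    phi_1: float
    phi_2: float
    k: int
    ts_1: float
    tr_1: float
    ts_2: float
    tr_2: float
    tl_1: float
    tl_2: float
    period_net: float
    stable: bool = False
    mode_class: str = "other"
    flags: tuple[str, ...] = ()

    @property
    def lags(self) -> tuple[float, float]:
        return (self.tl_1, self.tl_2)

    @property
    def network_phase(self) -> float:
        """Locked phase of neuron 2's spike within the network cycle."""
        return (self.tl_1 / self.period_net) % 1.0


# ---------------------------------------------------------------------------
# intervals and residuals


def _intervals(spec: CircuitSpec, phi1, phi2):
    P1, P2 = spec.period_1, spec.period_2
    ts1 = P1 * np.asarray(phi1, dtype=float)
    ts2 = P2 * np.asarray(phi2, dtype=float)
    tr1 = P1 * (1.0 - np.asarray(phi1) + evaluate_prc(spec.prc_1, phi1))
    tr2 = P2 * (1.0 - np.asarray(phi2) + evaluate_prc(spec.prc_2, phi2))
    return ts1, tr1, ts2, tr2


def _residuals(spec: CircuitSpec, phi1, phi2, k: int):
    ts1, tr1, ts2, tr2 = _intervals(spec, phi1, phi2)
    dsum = spec.delay_sum
    res_a = dsum + tr1 - ts2 - (k - 1) * (ts2 + tr2)
    res_b = dsum + tr2 - ts1 - (k - 1) * (ts1 + tr1)
    return res_a, res_b


def interval_curves(spec: CircuitSpec, k: int = 1, n_grid: int = 1001) -> dict:
    """Sampled interval-return curves whose intersections are the lockings.

    For neuron 1 the abscissa is ``2*delay + tr_1`` and the ordinate
    ``ts_1 + (k-1) P_N,1``; for neuron 2 abscissa and ordinate are reversed,
    so a crossing satisfies both periodicity constraints simultaneously.
    Returns a dict with the phase grid and (x, y) arrays per neuron.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    phi = np.linspace(0.0, 1.0 - 1e-9, n_grid)
    ts1, tr1, _, _ = _intervals(spec, phi, phi)
    _, _, ts2, tr2 = _intervals(spec, phi, phi)
    dsum = spec.delay_sum
    return {
        "phi": phi,
        "neuron1_x": dsum + tr1,
        "neuron1_y": ts1 + (k - 1) * (ts1 + tr1),
        "neuron2_x": ts2 + (k - 1) * (ts2 + tr2),
        "neuron2_y": dsum + tr2,
    }


# ---------------------------------------------------------------------------
# root finding


def _refine_root(spec, k, lo1, hi1, lo2, hi2, tol):
    """Nested-bisection refinement of a candidate cell.

    Solve res_a(phi1, phi2) = 0 for phi2 at fixed phi1 (bisection within the
    cell, widened by one cell so the root may drift), then drive
    res_b(phi1, phi2(phi1)) to zero over phi1.
    """
    w = hi2 - lo2
    lo2 = max(0.0, lo2 - w)
    hi2 = min(1.0 - 1e-9, hi2 + w)

    def phi2_of(phi1):
        f = lambda p2: _residuals(spec, phi1, p2, k)[0]
        a, b = f(lo2), f(hi2)
        if a == 0.0:
            return lo2
        if b == 0.0:
            return hi2
        if np.sign(a) == np.sign(b):
            return None
        return brentq(f, lo2, hi2, xtol=1e-14)

    def g(phi1):
        p2 = phi2_of(phi1)
        if p2 is None:
            return None
        return _residuals(spec, phi1, p2, k)[1], p2

    ga, gb = g(lo1), g(hi1)
    # a root can sit exactly on a cell corner: accept endpoints directly
    if ga is not None and abs(ga[0]) <= tol:
        return float(lo1), float(ga[1])
    if gb is not None and abs(gb[0]) <= tol:
        return float(hi1), float(gb[1])
    if ga is None or gb is None:
        return None
    if np.sign(ga[0]) == np.sign(gb[0]):
        return None
    a, b, fa = lo1, hi1, ga[0]
    for _ in range(80):
        m = 0.5 * (a + b)
        gm = g(m)
        if gm is None:
            return None
        if gm[0] == 0.0 or (b - a) < 1e-15:
            break
        if np.sign(gm[0]) == np.sign(fa):
            a, fa = m, gm[0]
        else:
            b = m
    m = 0.5 * (a + b)
    gm = g(m)
    if gm is None:
        return None
    res_b, p2 = gm
    res_a = 0.0
    if abs(res_b) > tol:
        return None
    return float(m), float(p2)


def _refine_root_2d(spec, k, c1, c2, tol):
    """Quasi-Newton solve of both residuals from a cell center."""

    def fun(x):
        a, b = _residuals(spec, float(np.clip(x[0], 0.0, 1 - 1e-9)),
                          float(np.clip(x[1], 0.0, 1 - 1e-9)), k)
        return [float(a), float(b)]

    sol = _root2d(fun, [c1, c2], method="hybr", tol=1e-13)
    p1, p2 = (float(np.clip(v, 0.0, 1 - 1e-9)) for v in sol.x)
    ra, rb = _residuals(spec, p1, p2, k)
    if abs(float(ra)) > tol or abs(float(rb)) > tol:
        return None
    return p1, p2


def _mode_from_phases(spec: CircuitSpec, phi1: float, phi2: float, k: int
                      ) -> LockingMode:
    ts1, tr1, ts2, tr2 = (float(x) for x in _intervals(spec, phi1, phi2))
    pn = ts1 + tr1
    tl1 = (ts1 - spec.delay_21) % pn if pn > 0 else 0.0
    tl2 = pn - tl1
    return LockingMode(
        phi_1=float(phi1), phi_2=float(phi2), k=k,
        ts_1=ts1, tr_1=tr1, ts_2=ts2, tr_2=tr2,
        tl_1=tl1, tl_2=tl2, period_net=pn,
    )


def find_lockings(
    spec: CircuitSpec,
    k_max: int = 3,
    *,
    n_grid: int = 800,
    class_tol: float = CLASS_TOL,
    junction_tol: float = JUNCTION_TOL,
) -> list[LockingMode]:
    """Locate all 1:1 phase-locked modes for feedback indices 1..k_max.

    Both periodicity residuals are evaluated on an ``n_grid`` x ``n_grid``
    phase grid; cells where both residuals change sign are refined by
    nested bisection to a relative residual below ``RESIDUAL_RTOL``.
    Degenerate (non-transversal) intersections — e.g. the continuum of the
    uncoupled zero-resetting pair — are detected by a vanishing Jacobian
    determinant, logged, and skipped.  Modes are deduplicated across k and
    annotated with stability and a class label (synchrony, antiphase,
    leader_follower, other).

    An empty list is a legitimate outcome: no stable 1:1 locking exists at
    some delays.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    tol = RESIDUAL_RTOL * spec.period_slow
    phi = np.linspace(0.0, 1.0 - 1e-9, n_grid + 1)
    p1g, p2g = np.meshgrid(phi, phi, indexing="ij")
    modes: list[LockingMode] = []
    for k in range(1, k_max + 1):
        res_a, res_b = _residuals(spec, p1g, p2g, k)
        sa, sb = np.sign(res_a), np.sign(res_b)
        # cells whose four corners show both signs for both residuals
        def mixed(s):
            mx = np.maximum(np.maximum(s[:-1, :-1], s[1:, :-1]),
                            np.maximum(s[:-1, 1:], s[1:, 1:]))
            mn = np.minimum(np.minimum(s[:-1, :-1], s[1:, :-1]),
                            np.minimum(s[:-1, 1:], s[1:, 1:]))
            return (mx > 0) & (mn < 0) | (mx == 0) | (mn == 0)
        cells = np.argwhere(mixed(sa) & mixed(sb))
        for i, j in cells:
            got = _refine_root(spec, k, phi[i], phi[i + 1], phi[j], phi[j + 1], tol)
            if got is None:
                # the inner root can outrun the widened bracket when the
                # constraint curve is steep; fall back to a 2-D solve
                got = _refine_root_2d(spec, k,
                                      0.5 * (phi[i] + phi[i + 1]),
                                      0.5 * (phi[j] + phi[j + 1]), tol)
            if got is None:
                continue
            f1, f2 = got
            ra, rb = _residuals(spec, f1, f2, k)
            if abs(float(ra)) > tol or abs(float(rb)) > tol:
                continue
            if _is_degenerate(spec, f1, f2, k):
                logger.info("degenerate (non-transversal) locking at "
                            "phi=(%.4f, %.4f), k=%d: skipped", f1, f2, k)
                continue
            if any(abs(m.phi_1 - f1) < DEDUP_TOL and abs(m.phi_2 - f2) < DEDUP_TOL
                   for m in modes):
                continue
            mode = _mode_from_phases(spec, f1, f2, k)
            if mode.tr_1 < -tol or mode.tr_2 < -tol or mode.period_net <= 0:
                continue
            _classify_mode(mode, spec, class_tol)
            stable, flags = _stability(mode, spec, class_tol, junction_tol)
            mode.stable = stable
            mode.flags = tuple(flags)
            modes.append(mode)
    modes.sort(key=lambda m: (m.k, m.phi_1))
    return modes


def _is_degenerate(spec, phi1, phi2, k, h=1e-6, cond_tol=1e-6) -> bool:
    # central differences: forward differences carry O(h * f'') truncation
    # error, which swamps the determinant near curves of non-transversal
    # solutions (e.g. an antiphase mode exactly at its stability boundary)
    def clipped(p):
        return float(np.clip(p, 0.0, 1.0 - 1e-9))

    def col(dp1, dp2):
        a1, b1 = _residuals(spec, clipped(phi1 + dp1), clipped(phi2 + dp2), k)
        a0, b0 = _residuals(spec, clipped(phi1 - dp1), clipped(phi2 - dp2), k)
        return (float(a1 - a0) / (2 * h), float(b1 - b0) / (2 * h))

    j11, j21 = col(h, 0.0)
    j12, j22 = col(0.0, h)
    det = j11 * j22 - j12 * j21
    norm = max(abs(j11), abs(j12), abs(j21), abs(j22), 1e-30)
    return abs(det) < cond_tol * norm ** 2


def _classify_mode(mode: LockingMode, spec: CircuitSpec, class_tol: float) -> None:
    pn = mode.period_net
    if pn <= 0:
        mode.mode_class = "other"
        return
    min_lag = min(mode.tl_1, mode.tl_2)
    if min_lag / pn < class_tol:
        mode.mode_class = "synchrony"
    elif abs(mode.tl_1 - mode.tl_2) / pn < class_tol:
        mode.mode_class = "antiphase"
    elif abs(min_lag - (spec.delay_12 + spec.delay_21) / 2.0) / pn < 0.1:
        mode.mode_class = "leader_follower"
    else:
        mode.mode_class = "other"


# ---------------------------------------------------------------------------
# stability


def _stability(mode: LockingMode, spec: CircuitSpec,
               class_tol: float, junction_tol: float) -> tuple[bool, list[str]]:
    s1 = prc_slope(spec.prc_1, mode.phi_1)
    s2 = prc_slope(spec.prc_2, mode.phi_2)
    k = mode.k
    num = abs((s1 - 1.0) * (s2 - 1.0))
    den = abs((1.0 + (k - 1) * s1) * (1.0 + (k - 1) * s2))
    # strict margin: marginal (|multiplier| = 1) modes are not attracting
    stable = num < den * (1.0 - 1e-6)
    flags: list[str] = []

    on_limit_1 = bool(spec.prc_1.on_causal_limit(mode.phi_1))
    on_limit_2 = bool(spec.prc_2.on_causal_limit(mode.phi_2))
    if on_limit_1 or on_limit_2:
        flags.append("neutral-at-limit")

    if mode.mode_class == "synchrony":
        ssum = s1 + s2
        if on_limit_1 and on_limit_2:
            # exactly on the causal limit the synchrony criterion is
            # marginal (|1 - 2| = 1); treated as open -> stable, flagged
            stable = True
        else:
            stable = stable and abs(1.0 - ssum) < 1.0
        for prc, phi in ((spec.prc_1, mode.phi_1), (spec.prc_2, mode.phi_2)):
            if (prc.coupling_sign == "inhibitory"
                    and prc.endpoint_gap > GAP_TOL
                    and (min(phi, 1.0 - phi) < junction_tol)):
                stable = False
                flags.append("discontinuity-unstable")
                break
    return stable, flags


def assess_stability(
    mode: LockingMode,
    spec: CircuitSpec,
    *,
    class_tol: float = CLASS_TOL,
    junction_tol: float = JUNCTION_TOL,
) -> bool:
    """Stability verdict for a locking mode.

    Applies the graphical slope-comparison rule at the two locking points;
    synchronous modes additionally require ``|1 - (f_1' + f_2')| < 1``, with
    the causal-limit neutral case reported stable (flagged on the mode) and
    the inhibitory endpoint-discontinuity rule overriding to unstable when
    the locking phase sits within ``junction_tol`` of the discontinuity.
    """
    _classify_mode(mode, spec, class_tol)
    stable, flags = _stability(mode, spec, class_tol, junction_tol)
    mode.stable = stable
    mode.flags = tuple(flags)
    return stable


# ---------------------------------------------------------------------------
# sweeps and heterogeneity


def delay_sweep(
    spec: CircuitSpec,
    delays_norm=None,
    k_max: int = 3,
    *,
    include_unstable: bool = False,
    n_grid: int = 600,
) -> pd.DataFrame:
    """Tabulate locking modes over a grid of normalized conduction delays.

    ``delays_norm`` are mean delays normalized by the slower neuron's
    intrinsic period (default 0 to 1 in steps of 0.02, the increment of the
    graphical method).  A fixed delay difference in ``spec`` is preserved.
    Output columns: delay_norm, k, phi1, phi2, tl1_norm, tl2_norm,
    period_norm, stable, mode_class, flags — lags and period normalized by
    the slow period, with tl2 reported as negative for signed-lag diagrams.
    """
    if delays_norm is None:
        delays_norm = np.arange(0.0, 1.0 + 1e-9, 0.02)
    delta = spec.delay_12 - spec.delay_21
    rows = []
    for dn in np.asarray(delays_norm, dtype=float):
        sub = spec.with_normalized_delay(dn, delta)
        for m in find_lockings(sub, k_max=k_max, n_grid=n_grid):
            if not (m.stable or include_unstable):
                continue
            rows.append({
                "delay_norm": dn,
                "k": m.k,
                "phi1": m.phi_1,
                "phi2": m.phi_2,
                "tl1_norm": m.tl_1 / spec.period_slow,
                "tl2_norm": -m.tl_2 / spec.period_slow,
                "period_norm": m.period_net / spec.period_slow,
                "stable": m.stable,
                "mode_class": m.mode_class,
                "flags": ";".join(m.flags),
            })
    return pd.DataFrame(rows, columns=[
        "delay_norm", "k", "phi1", "phi2", "tl1_norm", "tl2_norm",
        "period_norm", "stable", "mode_class", "flags"])


def heterogeneity_lag(spec: CircuitSpec) -> float:
    """Near-synchronous time lag (ms) under small heterogeneity.

    Linearizing both PRCs about the homogeneous synchronous locking point
    (input phase ``delay / P_i`` for each neuron) gives, for the lag of
    neuron 2 behind neuron 1::

        eps = d_delta / 2
              + [P_2 (1 + f_2(d/P_2)) - P_1 (1 + f_1(d/P_1))]
                / [f_1'(d/P_1) + f_2'(d/P_2)]

    with ``d`` the mean of the two delays and ``d_delta = delay_12 -
    delay_21``.  For identical neurons with equal delays the numerator
    vanishes and ``eps = 0``; with both locking points on the causal limit
    the numerator vanishes for *any* periods and the slopes are one, so
    ``eps = d_delta / 2``.  Valid while the perturbed locking points stay
    in a linear neighborhood (small ``eps`` and ``d_delta``).

    Raises
    ------
    ValueError
        If the homogeneous synchronous locking point does not exist
        (``d/P_i`` outside [0, 1)) or is unstable.
    """
    d = 0.5 * spec.delay_sum
    d_delta = spec.delay_12 - spec.delay_21
    p1, p2 = spec.period_1, spec.period_2
    x1, x2 = d / p1, d / p2
    if not (0 <= x1 < 1 and 0 <= x2 < 1):
        raise ValueError("no synchronous locking point: delay/period >= 1")
    s1, s2 = prc_slope(spec.prc_1, x1), prc_slope(spec.prc_2, x2)
    on_limit = bool(spec.prc_1.on_causal_limit(x1)) and bool(
        spec.prc_2.on_causal_limit(x2))
    if not on_limit and abs(1.0 - (s1 + s2)) >= 1.0:
        raise ValueError("synchronous locking point is unstable at this delay")
    num = p2 * (1.0 + evaluate_prc(spec.prc_2, x2)) - p1 * (
        1.0 + evaluate_prc(spec.prc_1, x1))
    den = s1 + s2
    if num == 0.0:
        return d_delta / 2.0
    if den == 0.0:
        raise ValueError("vanishing slope sum: linearization breaks down")
    return d_delta / 2.0 + num / den
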