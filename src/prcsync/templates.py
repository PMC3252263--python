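"""Canonical PRC archetypes and synthetic measurement/circuit generation.

Four template shapes cover what dynamic-clamp measurements of entorhinal
cortical cells typically show:

``exc_I``
    Excitatory Type I: advances only, single interior extremum, near zero
    at both endpoints.  Strong coupling clamps the late half of the curve
    onto the causal limit ``f = phi - 1``.
``exc_II``
    Excitatory weakly Type II: a small region of delays at early phases
    (phi < ~0.2), advances everywhere else, causal-limit branch late.
``inh_I``
    Inhibitory Type I: delays only, monotonically increasing with phase,
    not returning to zero as phi -> 1.
``inh_II``
    Inhibitory weakly Type II: small advances at early phases, delays at
    all later phases, with a second region of negative slope at very late
    phases; also nonzero as phi -> 1.

Excitatory templates get a noise envelope that shrinks at late phases
(inputs near the causal limit evoke spikes reliably); inhibitory noise is
roughly phase-independent.  Template coefficients are this package's own
parameterization of those shape constraints; amplitudes are free because
absolute resetting depends on the (unpublished) synaptic conductance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .prc import PRCMeasurementSet, PRCModel, classify_prc, evaluate_prc
from .locking import CircuitSpec

__all__ = [
    "TEMPLATE_NAMES",
    "PRCTemplate",
    "describe_template",
    "make_template",
    "generate_measurements",
    "make_circuit",
]

TEMPLATE_NAMES = ("exc_I", "exc_II", "inh_I", "inh_II")

#: default resetting amplitudes (max |f|), one per template
DEFAULT_SCALE = {"exc_I": 0.4, "exc_II": 0.16, "inh_I": 0.45, "inh_II": 0.15}

#: excitatory noise s.d. polynomial sigma(phi) = 0.05 * (1 - 0.9 phi):
#: substantial early variability, strongly quieted near the causal limit
#: where an input fires the cell almost deterministically
_SIGMA_EXC = np.array([0.05, -0.045])
#: inhibitory noise s.d. is approximately phase-independent
_SIGMA_INH = np.array([0.02])

# exc_II base shape phi*(phi - r)*(phi - m): small delays on (0, r),
# advances on (r, 1); with the default amplitude the curve rides just above
# the causal limit near phi ~ 0.9 (slope < 1, mildly contracting) and
# clamps onto it for phi > ~0.92.
_EXC2_R, _EXC2_M = 0.2, 1.0
# inh_II mean-curve derivative has roots at these phases: slope negative
# before the first (early advances), positive between (rising delays),
# negative after the second (the late downturn that kills antiphase at
# longer delays); the third root shapes the descent steepness.
_INH2_SLOPE_ROOTS = (0.10, 0.85, 1.4)


def _poly_max_abs(coeffs: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> float:
    g = np.linspace(lo, hi, 4001)
    return float(np.max(np.abs(npoly.polyval(g, coeffs))))


@dataclass(frozen=True)
class PRCTemplate:
    """Descriptor of one archetype: name, shape class and endpoint gap."""

    name: str
    mean_coeffs: np.ndarray
    sigma_profile: str           # "late_decreasing" or "flat"
    endpoint_gap: float          # f(1-) - f(0+) of the mean curve


def describe_template(
    name: str,
    scale: float | None = None,
    endpoint_gap: float | None = None,
) -> PRCTemplate:
    """Realized descriptor for a template parameterization."""
    model = make_template(name, scale, endpoint_gap)
    profile = "late_decreasing" if model.coupling_sign == "excitatory" else "flat"
    return PRCTemplate(name=name, mean_coeffs=model.mean_coeffs,
                       sigma_profile=profile, endpoint_gap=model.endpoint_gap)


def make_template(
    name: str,
    scale: float | None = None,
    endpoint_gap: float | None = None,
) -> PRCModel:
    """Build a PRCModel for one of the four canonical archetypes.

    Parameters
    ----------
    name : {"exc_I", "exc_II", "inh_I", "inh_II"}
    scale : float, optional
        Maximum resetting magnitude of the mean curve (dimensionless,
        fraction of a period).  Defaults per template; ``scale == 0`` gives
        the degenerate zero curve.
    endpoint_gap : float, optional
        Inhibitory templates only: the discontinuity ``f(1-) - f(0+)``.
        Defaults to the template's natural endpoint value (``scale`` for
        inh_I, about ``0.66 * scale`` for inh_II).  Ignored for excitatory
        templates, whose curves return to the causal-limit branch instead.
    """
    if name not in TEMPLATE_NAMES:
        raise ValueError(f"unknown template {name!r}; choose from {TEMPLATE_NAMES}")
    if scale is None:
        scale = DEFAULT_SCALE[name]
    if scale < 0:
        raise ValueError("scale must be >= 0")

    if name == "exc_I":
        # -4 s phi (1 - phi): peak advance s at mid-phase; clamps onto the
        # causal limit for phi >= 1/(4 s).
        coeffs = np.array([0.0, -4.0 * scale, 4.0 * scale])
        sign, sig = "excitatory", _SIGMA_EXC
    elif name == "exc_II":
        base = npoly.polyfromroots([0.0, _EXC2_R, _EXC2_M])  # ascending
        amp = _poly_max_abs(base)
        coeffs = (scale / amp) * base if scale > 0 else np.zeros(4)
        sign, sig = "excitatory", _SIGMA_EXC
    elif name == "inh_I":
        gap = scale if endpoint_gap is None else float(endpoint_gap)
        if not 0 <= gap <= scale:
            raise ValueError("inh_I requires 0 <= endpoint_gap <= scale")
        # constant offset keeps the curve all-delay while the rising
        # quadratic carries the requested endpoint discontinuity
        coeffs = np.array([scale - gap, 0.3 * gap, 0.7 * gap])
        sign, sig = "inhibitory", _SIGMA_INH
    else:  # inh_II
        z1, z2, z3 = _INH2_SLOPE_ROOTS
        base = np.array([0.0, -z1 * z2 * z3,
                         (z1 * z2 + z1 * z3 + z2 * z3) / 2.0,
                         -(z1 + z2 + z3) / 3.0, 0.25])
        amp = _poly_max_abs(base)
        coeffs = (scale / amp) * base if scale > 0 else np.zeros(5)
        if endpoint_gap is not None and scale > 0:
            natural = float(npoly.polyval(1.0, coeffs))
            corr = float(endpoint_gap) - natural
            coeffs = coeffs.copy()
            coeffs[4] += corr  # phi^4 term moves f(1-) only weakly elsewhere
        sign, sig = "inhibitory", _SIGMA_INH

    eps = 1e-6
    end0 = float(max(npoly.polyval(eps, coeffs), eps - 1))
    end1 = float(max(npoly.polyval(1 - eps, coeffs), -eps))
    model = PRCModel(
        mean_coeffs=coeffs,
        sigma_upper_coeffs=npoly.polyadd(coeffs, sig),
        sigma_lower_coeffs=npoly.polysub(coeffs, sig),
        prc_type="I",
        coupling_sign=sign,
        endpoint_values=(end0, end1),
        name=name,
    )
    model.prc_type = classify_prc(model)
    return model


def generate_measurements(
    model: PRCModel,
    n_samples: int = 2000,
    seed: int | np.random.Generator | None = None,
    intrinsic_period: float = 100.0,
) -> PRCMeasurementSet:
    """Synthesize a PRC measurement set from a model.

    Phases are uniform on [0, 1) (the stimulation protocol randomizes the
    stimulus interval; only the resulting (phase, resetting) pairs matter
    downstream).  Resetting values are Gaussian around the mean curve with
    the model's phase-dependent s.d.; draws violating the causal limit are
    rejected and redrawn.
    """
    if n_samples < 300:
        raise ValueError("n_samples must be >= 300 so the fit can bin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phases = rng.uniform(0.0, 1.0, n_samples)
    mean = evaluate_prc(model, phases)
    sd = model.sigma(phases)
    vals = rng.normal(mean, sd)
    floor = phases - 1.0
    bad = vals < floor
    tries = 0
    while bad.any():
        vals[bad] = rng.normal(mean[bad], sd[bad])
        bad = vals < floor
        tries += 1
        if tries > 1000:
            raise RuntimeError("causality rejection did not terminate")
    return PRCMeasurementSet(phases, vals, model.coupling_sign, intrinsic_period)


def make_circuit(
    prc_a: PRCModel,
    prc_b: PRCModel,
    period_a: float = 100.0,
    heterogeneity: float = 0.0,
    delay: float = 0.0,
    delta_delay: float = 0.0,
) -> CircuitSpec:
    """Assemble a two-neuron circuit specification.

    ``period_b = period_a * (1 + heterogeneity)``; the conduction delays in
    the two directions are ``delay +/- delta_delay / 2`` (a -> b gets the
    larger one when ``delta_delay > 0``).  Delays are in ms.
    """
    if period_a <= 0:
        raise ValueError("period_a must be positive")
    if abs(heterogeneity) >= 0.5:
        raise ValueError("|heterogeneity| must be < 0.5")
    if delay < 0:
        raise ValueError("delay must be >= 0")
    d_ab = delay + delta_delay / 2.0
    d_ba = delay - delta_delay / 2.0
    if d_ab < 0 or d_ba < 0:
        raise ValueError("delta_delay would make a directional delay negative")
    if prc_a.coupling_sign != prc_b.coupling_sign:
        raise ValueError("both PRCs must share one coupling sign")
    return CircuitSpec(
        period_1=period_a,
        period_2=period_a * (1.0 + heterogeneity),
        prc_1=prc_a,
        prc_2=prc_b,
        delay_12=d_ab,
        delay_21=d_ba,
    )
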