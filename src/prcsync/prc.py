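"""Phase resetting curves: representation, fitting, classification, sampling.

A phase resetting curve (PRC) describes how a single pulsatile synaptic
input shifts the next spike of a periodically firing neuron.  If an input
arrives a stimulus interval ``ts`` after a spike, the cycle containing the
perturbation has length ``P_pert = ts + tr`` (``tr`` the recovery interval),
and the resetting at phase ``phi = ts / P`` is the normalized change in
cycle length::

    f(phi) = (P_pert - P) / P

with ``P`` the intrinsic (unperturbed) period.  Sign convention: positive
resetting is a *delay* (the next spike comes later), negative an *advance*.

An advance cannot exceed the remaining fraction of the cycle: an excitatory
input can at most make the neuron fire immediately, so ``f(phi) >= phi - 1``
(the *causal limit*).  Strong excitation late in the cycle sits exactly on
this limit, producing a linear branch ``f = phi - 1`` of slope one.  All
evaluation in this module clamps the fitted polynomial to that floor.

Phenomenological classes: Type I PRCs are single-signed (all advances or
all delays); Type II PRCs mix advances and delays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "PRCMeasurementSet",
    "PRCModel",
    "fit_prc",
    "classify_prc",
    "evaluate_prc",
    "prc_slope",
    "sample_noisy_resetting",
    "CausalityError",
    "FitError",
]

#: fraction of the curve amplitude below which a sign is not counted when
#: classifying (guards against fit jitter crossing zero near the endpoints)
CLASSIFY_AMPLITUDE_TOL = 0.02
#: margin excluded at each end of (0, 1) when classifying
CLASSIFY_EDGE = 0.01
#: excitatory fits drop isolated positive (delay) values later than this
#: phase before fitting; such late delays are measurement artifacts
SPURIOUS_LATE_PHASE = 0.9


class FitError(ValueError):
    """Raised when a PRC measurement set cannot be binned or fitted."""


class CausalityError(RuntimeError):
    """Raised when noisy resetting draws cannot satisfy the causal limit."""


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class PRCMeasurementSet:
    """Raw (phase, resetting) samples from a stimulation protocol.

    Parameters
    ----------
    phases : array-like
        Stimulus phases, each in ``[0, 1)``.
    resettings : array-like
        Normalized period changes; each must satisfy the causal limit
        ``resetting >= phase - 1``.
    coupling_sign : {"excitatory", "inhibitory"}
        Sign of the synaptic perturbation used.
    intrinsic_period : float
        Unperturbed firing period in ms.
    """

    phases: np.ndarray
    resettings: np.ndarray
    coupling_sign: str
    intrinsic_period: float = 100.0

    def __post_init__(self) -> None:
        self.phases = _as_array(self.phases)
        self.resettings = _as_array(self.resettings)
        if self.phases.shape != self.resettings.shape:
            raise ValueError("phases and resettings must have equal length")
        if self.coupling_sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown coupling_sign {self.coupling_sign!r}")
        if self.intrinsic_period <= 0:
            raise ValueError("intrinsic_period must be positive")
        if self.phases.size:
            if (self.phases < 0).any() or (self.phases >= 1).any():
                raise ValueError("phases must lie in [0, 1)")
            if (self.resettings < self.phases - 1 - 1e-12).any():
                raise ValueError(
                    "resettings violate the causal limit f >= phi - 1"
                )

    @property
    def records(self) -> list[tuple[float, float]]:
        return list(zip(self.phases.tolist(), self.resettings.tolist()))

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[float, float]],
        coupling_sign: str,
        intrinsic_period: float = 100.0,
    ) -> "PRCMeasurementSet":
        recs = list(records)
        phases = [r[0] for r in recs]
        resets = [r[1] for r in recs]
        return cls(phases, resets, coupling_sign, intrinsic_period)

    def __len__(self) -> int:
        return self.phases.size


@dataclass
class PRCModel:
    """Polynomial mean resetting curve plus a noise envelope.

    The mean curve is a polynomial of degree 2-4 in the phase; evaluation
    clamps it to the causal-limit floor ``phi - 1``.  ``sigma_upper_coeffs``
    and ``sigma_lower_coeffs`` are polynomial fits to the binned mean plus
    and minus one standard deviation; the phase-dependent noise s.d. is
    half their difference, floored at zero.

    All coefficient vectors are in ascending order (c0 + c1*phi + ...).
    """

    mean_coeffs: np.ndarray
    sigma_upper_coeffs: np.ndarray
    sigma_lower_coeffs: np.ndarray
    prc_type: str = "I"
    coupling_sign: str = "excitatory"
    endpoint_values: tuple[float, float] = (0.0, 0.0)
    name: str | None = None

    def __post_init__(self) -> None:
        self.mean_coeffs = np.atleast_1d(_as_array(self.mean_coeffs))
        self.sigma_upper_coeffs = np.atleast_1d(_as_array(self.sigma_upper_coeffs))
        self.sigma_lower_coeffs = np.atleast_1d(_as_array(self.sigma_lower_coeffs))
        if self.coupling_sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown coupling_sign {self.coupling_sign!r}")
        if self.prc_type not in ("I", "II"):
            raise ValueError("prc_type must be 'I' or 'II'")
        self.endpoint_values = (
            float(self.endpoint_values[0]),
            float(self.endpoint_values[1]),
        )

    # -- evaluation ------------------------------------------------------
    def __call__(self, phase):
        return evaluate_prc(self, phase)

    def slope(self, phase):
        return prc_slope(self, phase)

    def sigma(self, phase):
        """Phase-dependent noise s.d., (upper - lower)/2 floored at 0."""
        phase = _as_array(phase)
        up = npoly.polyval(phase, self.sigma_upper_coeffs)
        lo = npoly.polyval(phase, self.sigma_lower_coeffs)
        return np.maximum((up - lo) / 2.0, 0.0)

    def on_causal_limit(self, phase, tol: float = 1e-9) -> np.ndarray:
        """True where the mean polynomial is at or below the causal floor."""
        phase = _as_array(phase)
        raw = npoly.polyval(phase, self.mean_coeffs)
        return raw <= phase - 1 + tol

    @property
    def endpoint_gap(self) -> float:
        """f(1-) - f(0+): the discontinuity a strong inhibitory PRC shows."""
        return self.endpoint_values[1] - self.endpoint_values[0]

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "coupling_sign": self.coupling_sign,
            "prc_type": self.prc_type,
            "mean_coeffs": self.mean_coeffs.tolist(),
            "sigma_upper_coeffs": self.sigma_upper_coeffs.tolist(),
            "sigma_lower_coeffs": self.sigma_lower_coeffs.tolist(),
            "endpoint_values": list(self.endpoint_values),
        }
        if self.name:
            d["name"] = self.name
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PRCModel":
        return cls(
            mean_coeffs=d["mean_coeffs"],
            sigma_upper_coeffs=d["sigma_upper_coeffs"],
            sigma_lower_coeffs=d["sigma_lower_coeffs"],
            prc_type=d.get("prc_type", "I"),
            coupling_sign=d["coupling_sign"],
            endpoint_values=tuple(d.get("endpoint_values", (0.0, 0.0))),
            name=d.get("name"),
        )


# ---------------------------------------------------------------------------
# evaluation


def _check_phase(phase: np.ndarray) -> None:
    if np.any(phase < 0) or np.any(phase >= 1):
        raise ValueError("phase must lie in [0, 1)")


def evaluate_prc(model: PRCModel, phase):
    """Mean resetting at ``phase``, clamped to the causal limit.

    Returns ``max(polynomial(phase), phase - 1)``; scalar in, scalar out.
    """
    arr = _as_array(phase)
    _check_phase(arr)
    val = np.maximum(npoly.polyval(arr, model.mean_coeffs), arr - 1.0)
    return float(val) if np.isscalar(phase) or arr.ndim == 0 else val


def prc_slope(model: PRCModel, phase):
    """Derivative of the clamped mean curve.

    On the causal-limit branch (and exactly at the junction) the slope is 1:
    there an input evokes a spike immediately, so the advance tracks the
    remaining fraction of the cycle one-for-one, which is the strongly
    stabilizing regime.
    """
    arr = _as_array(phase)
    _check_phase(arr)
    dcoef = npoly.polyder(model.mean_coeffs)
    sl = npoly.polyval(arr, dcoef)
    sl = np.where(model.on_causal_limit(arr), 1.0, sl)
    return float(sl) if np.isscalar(phase) or arr.ndim == 0 else sl


def classify_prc(model: PRCModel) -> str:
    """Classify the mean curve as Type I or Type II by its sign pattern.

    Type I is single-signed over the cycle interior; Type II shows both
    advances and delays.  Signs are counted on a fine grid over
    ``(CLASSIFY_EDGE, 1 - CLASSIFY_EDGE)`` and only where the curve exceeds
    ``CLASSIFY_AMPLITUDE_TOL`` times its maximum magnitude, so that fit
    jitter around zero does not flip the label.  An identically zero curve
    is Type I by convention.
    """
    grid = np.linspace(CLASSIFY_EDGE, 1.0 - CLASSIFY_EDGE, 1999)
    vals = evaluate_prc(model, grid)
    amp = float(np.max(np.abs(vals)))
    if amp == 0.0:
        return "I"
    tol = CLASSIFY_AMPLITUDE_TOL * amp
    has_pos = bool(np.any(vals > tol))
    has_neg = bool(np.any(vals < -tol))
    return "II" if (has_pos and has_neg) else "I"


# ---------------------------------------------------------------------------
# binning and fitting


@dataclass
class _Bin:
    phase: float   # value-weighted mean phase of member samples
    mean: float
    sd: float
    n: int


def _bin_measurements(
    phases: np.ndarray, resets: np.ndarray, n_bins: int = 100, min_count: int = 3
) -> list[_Bin]:
    """Equal-width phase bins; deficient bins merged with their neighbors.

    Bins with fewer than ``min_count`` samples are pooled with the
    immediately neighboring bins on both sides (repeatedly, until every
    surviving bin is full).  A merged bin is centered at the mean phase of
    its member samples.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(phases, edges) - 1, 0, n_bins - 1)
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            groups.append((phases[m], resets[m]))
        else:
            groups.append((np.empty(0), np.empty(0)))

    def counts(gs):
        return [g[0].size for g in gs]

    while True:
        cs = counts(groups)
        if len(groups) == 1:
            if cs[0] < min_count:
                raise FitError(
                    "cannot fill phase bins: fewer than "
                    f"{min_count} samples in total after merging"
                )
            break
        deficient = [i for i, c in enumerate(cs) if c < min_count]
        if not deficient:
            break
        i = deficient[0]
        lo, hi = max(0, i - 1), min(len(groups) - 1, i + 1)
        ph = np.concatenate([groups[j][0] for j in range(lo, hi + 1)])
        rs = np.concatenate([groups[j][1] for j in range(lo, hi + 1)])
        groups[lo : hi + 1] = [(ph, rs)]

    out = []
    for ph, rs in groups:
        out.append(
            _Bin(
                phase=float(ph.mean()),
                mean=float(rs.mean()),
                sd=float(rs.std(ddof=0)),
                n=int(rs.size),
            )
        )
    return out


def _aic(n: int, rss: float, n_params: int) -> float:
    # Gaussian log-likelihood up to constants; tiny floor keeps noiseless
    # data finite and lets the 2k term break ties toward low degree.
    rss = max(rss, 1e-28 * max(n, 1))
    return n * np.log(rss / n) + 2.0 * (n_params + 1)


def fit_prc(
    samples: PRCMeasurementSet,
    max_degree: int = 4,
    *,
    n_bins: int = 100,
    min_per_bin: int = 3,
    spurious_late_phase: float = SPURIOUS_LATE_PHASE,
) -> PRCModel:
    """Fit a PRC model to a measurement set.

    The measurements are averaged in ``n_bins`` equal-width phase bins
    (deficient bins merged with neighbors), and polynomials of degree 2 up
    to ``max_degree`` are fitted to the binned means by least squares; the
    degree with the lowest AIC wins (ties go to the lower degree, which is
    what makes a single-extremum curve come out Type I).  Envelope
    polynomials of the same degree are fitted to mean +/- one binned
    standard deviation.

    For excitatory sets, isolated positive (delay) values at phases later
    than ``spurious_late_phase`` are excluded before binning: late advances
    larger than the time remaining to the next spike are unobservable,
    which biases late-phase data toward small spurious delays.

    Raises
    ------
    FitError
        If fewer than 300 samples are supplied or binning cannot satisfy
        the per-bin minimum even after merging.
    """
    if len(samples) < 300:
        raise FitError(f"need >= 300 samples to fit a PRC, got {len(samples)}")
    if not 2 <= max_degree <= 4:
        raise ValueError("max_degree must be 2, 3 or 4")

    phases = samples.phases
    resets = samples.resettings
    if samples.coupling_sign == "excitatory":
        keep = ~((phases > spurious_late_phase) & (resets > 0))
        phases, resets = phases[keep], resets[keep]
        if phases.size < 300:
            raise FitError("too few samples left after spurious-delay filter")

    bins = _bin_measurements(phases, resets, n_bins=n_bins, min_count=min_per_bin)
    bp = np.array([b.phase for b in bins])
    bm = np.array([b.mean for b in bins])
    bs = np.array([b.sd for b in bins])

    best = None
    for deg in range(2, max_degree + 1):
        if bp.size < deg + 1:
            continue
        coeffs = npoly.polyfit(bp, bm, deg)
        rss = float(np.sum((npoly.polyval(bp, coeffs) - bm) ** 2))
        aic = _aic(bp.size, rss, deg + 1)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, deg, coeffs)
    if best is None:
        raise FitError("not enough bins for even a quadratic fit")
    _, deg, coeffs = best

    up = npoly.polyfit(bp, bm + bs, deg)
    lo = npoly.polyfit(bp, bm - bs, deg)

    eps = 1e-6
    end0 = float(max(npoly.polyval(eps, coeffs), eps - 1))
    end1 = float(max(npoly.polyval(1 - eps, coeffs), -eps))
    model = PRCModel(
        mean_coeffs=coeffs,
        sigma_upper_coeffs=up,
        sigma_lower_coeffs=lo,
        prc_type="I",
        coupling_sign=samples.coupling_sign,
        endpoint_values=(end0, end1),
    )
    model.prc_type = classify_prc(model)
    return model


# ---------------------------------------------------------------------------
# noisy sampling


def sample_noisy_resetting(
    model: PRCModel,
    phase,
    rng: np.random.Generator,
    max_draws: int = 1000,
):
    """Draw Gaussian resetting at ``phase`` with the model's noise envelope.

    The draw has mean ``evaluate_prc(model, phase)`` and s.d.
    ``model.sigma(phase)``; draws violating the causal limit
    ``f >= phase - 1`` (which would put the evoked spike before the input)
    are rejected and redrawn.

    Raises
    ------
    CausalityError
        If ``max_draws`` consecutive draws violate causality, indicating an
        inconsistent envelope (mean far below the causal floor).
    """
    mean = evaluate_prc(model, phase)
    sd = float(model.sigma(phase))
    if sd == 0.0:
        return mean
    floor = float(phase) - 1.0
    for _ in range(max_draws):
        val = rng.normal(mean, sd)
        if val >= floor:
            return float(val)
    raise CausalityError(
        f"no causal resetting draw at phase {phase:.4f} in {max_draws} tries"
    )
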