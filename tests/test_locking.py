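"""Tests for 1:1 locking existence, stability, sweeps and the lag formula."""

import numpy as np
import pytest


from prcsync import (
    CircuitSpec,
    assess_stability,
    delay_sweep,
    evaluate_prc,
    find_lockings,
    heterogeneity_lag,
    interval_curves,
    make_circuit,
    make_template,
)
from prcsync.locking import _residuals
from prcsync.prc import PRCModel

from conftest import zero_prc


def slope_model(slope, sign="excitatory", gap=0.0):
    """Linear PRC f = gap*step-ish + slope*phi, for criterion arithmetic."""
    coeffs = np.array([0.0, slope])
    m = PRCModel(coeffs, coeffs, coeffs, "I", sign)
    return m


# ---------------------------------------------------------------------------
# residual geometry and interval curves


def test_interval_curve_intersections_match_brute_force_residuals(exc1_pair):
    """Curve crossings coincide with sign changes of the periodicity
    residuals scanned densely along the symmetric diagonal."""
    spec = exc1_pair.with_normalized_delay(0.3)
    phi = np.linspace(1e-4, 1 - 1e-4, 20000)
    res_a, res_b = _residuals(spec, phi, phi, 1)
    sym = np.where(np.diff(np.sign(res_a)) != 0)[0]
    modes = [m for m in find_lockings(spec, k_max=1) if
             abs(m.phi_1 - m.phi_2) < 1e-9]
    assert len(sym) == len(modes)
    for i, m in zip(sym, sorted(modes, key=lambda m: m.phi_1)):
        assert abs(phi[i] - m.phi_1) < 1e-3


def test_interval_curves_axes_are_reversed_between_neurons(exc1_pair):
    spec = exc1_pair.with_normalized_delay(0.2)
    c = interval_curves(spec, k=1)
    # neuron 1 plots (2*delay + tr) against ts; neuron 2 the reverse
    ts1 = spec.period_1 * c["phi"]
    assert np.allclose(c["neuron1_y"], ts1)
    assert np.allclose(c["neuron2_x"], spec.period_2 * c["phi"])


def test_uncoupled_zero_resetting_pair_is_degenerate():
    z = zero_prc()
    spec = CircuitSpec(1.0, 1.0, z, z, 0.0, 0.0)
    assert find_lockings(spec, k_max=1) == []


# ---------------------------------------------------------------------------
# mode structure for the excitatory Type I pair (graphical-method examples)


def test_three_k1_modes_at_very_short_delay(exc1_pair):
    spec = exc1_pair.with_normalized_delay(0.04)
    modes = [m for m in find_lockings(spec) if m.k == 1]
    assert len(modes) == 3
    stable = [m for m in modes if m.stable]
    unstable = [m for m in modes if not m.stable]
    assert len(stable) == 2 and len(unstable) == 1
    # the unstable one is the equal-lag antiphase
    assert unstable[0].mode_class == "antiphase"
    # stable pair: unequal lags, lag-swapped images of each other
    a, b = stable
    assert a.tl_1 == pytest.approx(b.tl_2, abs=1e-9)
    assert a.tl_2 == pytest.approx(b.tl_1, abs=1e-9)
    # follower spike is evoked after ~the conduction delay
    assert min(a.tl_1, a.tl_2) == pytest.approx(0.04, abs=1e-9)


def test_antiphase_stable_at_intermediate_delay(exc1_pair):
    spec = exc1_pair.with_normalized_delay(0.40)
    anti = [m for m in find_lockings(spec)
            if m.mode_class == "antiphase" and m.stable]
    assert len(anti) == 1
    m = anti[0]
    assert m.tl_1 == pytest.approx(m.period_net / 2, rel=1e-9)
    assert m.tl_2 == pytest.approx(m.period_net / 2, rel=1e-9)


def test_synchrony_appears_at_k2_for_long_delay(exc1_pair):
    spec = exc1_pair.with_normalized_delay(0.80)
    sync = [m for m in find_lockings(spec)
            if m.mode_class == "synchrony" and m.stable]
    assert len(sync) == 1
    assert sync[0].k == 2
    assert min(sync[0].tl_1, sync[0].tl_2) == pytest.approx(0.0, abs=1e-9)


def test_conservation_and_symmetry_invariants(exc1_pair):
    for dn in (0.04, 0.2, 0.4, 0.6, 0.8):
        spec = exc1_pair.with_normalized_delay(dn)
        modes = find_lockings(spec)
        for m in modes:
            pn1 = m.ts_1 + m.tr_1
            pn2 = m.ts_2 + m.tr_2
            assert abs(pn1 - pn2) < 1e-9 * m.period_net
            assert abs(m.tl_1 + m.tl_2 - m.period_net) < 1e-9 * m.period_net
        # identical neurons, equal delays: lag-swapped partners exist
        # (lags compared modulo the network period: synchrony's (0, P_N)
        # is its own mirror image)
        def key(a, b, pn):
            a, b = round(a % pn, 7) % round(pn, 7), round(b % pn, 7) % round(pn, 7)
            return (a, b)
        pairs = [key(m.tl_1, m.tl_2, m.period_net) for m in modes]
        for a, b in pairs:
            assert any(abs(x - b) < 1e-6 and abs(y - a) < 1e-6
                       for x, y in pairs)


# ---------------------------------------------------------------------------
# stability criterion arithmetic


def test_synchrony_slope_sum_criterion():
    # |1 - (f1' + f2')| < 1 -> stable for slope sum 0.5, unstable for 2.5
    for s, expect in ((0.25, True), (1.25, False)):
        m1, m2 = slope_model(s), slope_model(s)
        spec = CircuitSpec(1.0, 1.0, m1, m2, 0.2, 0.2)
        modes = [x for x in find_lockings(spec) if x.mode_class == "synchrony"]
        assert modes, f"no synchronous mode for slope {s}"
        assert modes[0].stable is expect


def test_discontinuity_rule_at_zero_delay(inh2_pair):
    """An inhibitory endpoint gap makes zero-delay synchrony unstable even
    though the PRC slope there would be stabilizing by itself."""
    t = make_template("inh_I")
    assert t.endpoint_gap > 0
    spec = make_circuit(t, t, period_a=1.0, delay=0.0)
    sync = [m for m in find_lockings(spec) if m.mode_class == "synchrony"]
    assert sync and not sync[0].stable
    assert "discontinuity-unstable" in sync[0].flags
    # a short conduction delay restores slope-based stability
    spec = make_circuit(t, t, period_a=1.0, delay=0.05)
    sync = [m for m in find_lockings(spec) if m.mode_class == "synchrony"]
    assert sync and sync[0].stable


def test_assess_stability_matches_find_lockings(exc2_pair):
    spec = exc2_pair.with_normalized_delay(0.55)
    for m in find_lockings(spec):
        recorded = m.stable
        assert assess_stability(m, spec) is recorded


# ---------------------------------------------------------------------------
# delay sweep


def test_sweep_shows_leader_follower_antiphase_synchrony_progression(exc1_pair):
    tab = delay_sweep(exc1_pair, np.arange(0.0, 1.0001, 0.02), n_grid=400)
    def classes(dn):
        return set(tab[np.isclose(tab.delay_norm, dn)].mode_class)
    assert "leader_follower" in classes(0.06)
    assert "synchrony" not in classes(0.06)
    assert classes(0.30) == {"antiphase"}
    assert "synchrony" in classes(0.70)
    assert "leader_follower" not in classes(0.70)


def test_sweep_signed_lags_and_columns(exc1_pair):
    tab = delay_sweep(exc1_pair, [0.4], n_grid=400)
    assert list(tab.columns) == [
        "delay_norm", "k", "phi1", "phi2", "tl1_norm", "tl2_norm",
        "period_norm", "stable", "mode_class", "flags"]
    assert (tab.tl1_norm >= 0).all() and (tab.tl2_norm <= 0).all()


def test_inhibitory_type_II_pair_has_bistable_delay_range(inh2_pair):
    tab = delay_sweep(inh2_pair, [0.15, 0.2, 0.25], n_grid=400)
    for dn in (0.15, 0.2, 0.25):
        cls = set(tab[np.isclose(tab.delay_norm, dn)].mode_class)
        assert {"synchrony", "antiphase"} <= cls


def test_mixed_inhibitory_pair_never_synchronizes_at_matched_periods():
    a, b = make_template("inh_I"), make_template("inh_II")
    spec = make_circuit(a, b, period_a=1.0)
    tab = delay_sweep(spec, np.arange(0.0, 0.90001, 0.05), n_grid=400)
    assert not (tab.mode_class == "synchrony").any()


# ---------------------------------------------------------------------------
# heterogeneity lag formula


def test_lag_vanishes_for_identical_neurons_with_equal_delays():
    t = make_template("inh_I")
    spec = make_circuit(t, t, period_a=100.0, delay=10.0)
    assert heterogeneity_lag(spec) == 0.0


def test_lag_is_half_the_delay_difference_on_the_causal_limit():
    t = make_template("exc_I")  # on the causal limit at phi = 0.8
    spec = make_circuit(t, t, period_a=100.0, delay=80.0, delta_delay=2.0)
    assert heterogeneity_lag(spec) == pytest.approx(1.0, abs=1e-12)


def test_causal_limit_lag_robust_to_period_heterogeneity():
    """On the limit the numerator vanishes for any intrinsic periods."""
    t = make_template("exc_I")
    for het in (0.0, 0.02, 0.05):
        spec = make_circuit(t, t, period_a=100.0, heterogeneity=het,
                            delay=80.0, delta_delay=2.0)
        assert heterogeneity_lag(spec) == pytest.approx(1.0, abs=1e-9)


def test_lag_formula_errors_when_synchrony_unstable():
    t = make_template("exc_I")  # negative slope at early phases
    spec = make_circuit(t, t, period_a=100.0, delay=10.0)
    with pytest.raises(ValueError):
        heterogeneity_lag(spec)


def test_lag_formula_matches_zero_noise_map():
    """Predicted near-synchronous lag agrees with the map's asymptotic lag."""
    from prcsync import run_map
    t = make_template("inh_II")
    spec = make_circuit(t, t, period_a=1.0, heterogeneity=0.02, delay=0.25)
    eps = heterogeneity_lag(spec)
    _, lags = run_map(spec, n_cycles=1500, noise=False, seed=0,
                      phi_init=(0.0, 0.02))
    tail = np.minimum(lags.tl_1[-100:], lags.mean_network_period
                      - lags.tl_1[-100:])
    assert abs(abs(eps) - tail.mean()) < 0.02 * spec.period_slow
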