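"""Reaction scheme, quasi-steady state and stimulus-response analysis."""

import numpy as np
import pytest
from dataclasses import replace

from canaliflow import hippo as H


def random_feasible_params(rng):
    """Random free-parameter draw around the reference, kept in the
    regime where a steady state exists up to stimulus 4."""
    while True:
        p = H.HippoParams.reference()
        factors = {n: 10 ** rng.uniform(-0.4, 0.4) for n in p.free_names}
        p = p.with_free([getattr(p, n) * factors[n] for n in p.free_names])
        try:
            H.quasi_steady_state(p, 4.0)
            return p
        except H.NoSteadyStateError:
            continue


def random_state(rng, params):
    S = rng.uniform(0, params.S_tot)
    C = rng.uniform(0, params.SF_tot)
    return H.HippoState(S=S, S_i=params.S_tot - S,
                        Y_c=rng.uniform(0, 2), Y_i=rng.uniform(0, 2),
                        C=C, SF=params.SF_tot - C, Y_n=rng.uniform(0, 2))


def test_rhs_conserves_sensor_and_sf_totals(ref_params):
    rng = np.random.default_rng(0)
    for _ in range(20):
        s = random_state(rng, ref_params)
        d = H.rhs(s, ref_params, rng.uniform(0, 4))
        assert d[0] + d[1] == pytest.approx(0.0, abs=1e-14)   # S + S_i
        assert d[4] + d[5] == pytest.approx(0.0, abs=1e-14)   # C + SF


def test_zero_stimulus_only_reactivates_sensor(ref_params):
    s = random_state(np.random.default_rng(1), ref_params)
    d = H.rhs(s, ref_params, 0.0)
    assert d[0] == pytest.approx(ref_params.k_sens_on * s.S_i)
    assert d[0] >= 0


def test_total_yap_conserved_without_synthesis_and_degradation():
    p = H.HippoParams.reference()
    # k_syn = k_deg = 0 is outside the positivity domain; use tiny rates
    p = replace(p, k_syn=1e-12, k_deg=1e-12)
    s0 = H.HippoState(S=0.5, S_i=0.5, Y_c=0.3, Y_i=0.4, C=0.2, SF=0.8,
                      Y_n=0.6)
    total0 = p.V_cyt * (s0.Y_c + s0.Y_i + s0.C) + p.V_nuc * s0.Y_n
    _, states = H.integrate(p, 2.0, np.linspace(0, 50, 6), initial=s0)
    for s in states:
        total = p.V_cyt * (s.Y_c + s.Y_i + s.C) + p.V_nuc * s.Y_n
        assert abs(total - total0) / total0 < 1e-8


def test_qss_residual_vanishes(ref_params):
    for u in (0.5, 1.0, 1.75, 3.0):
        s = H.quasi_steady_state(ref_params, u)
        assert np.max(np.abs(H.rhs(s, ref_params, u))) < 1e-10


def test_qss_matches_long_time_integration_over_random_draws():
    rng = np.random.default_rng(42)
    for _ in range(50):
        p = random_feasible_params(rng)
        u = rng.uniform(0.5, 3.5)
        qss = H.quasi_steady_state(p, u)
        _, states = H.integrate(p, u, np.array([0.0, 2.0e3]),
                                initial=H.quasi_steady_state(p, 1.0))
        end = states[-1]
        for name in ("S", "Y_c", "Y_i", "C", "Y_n"):
            a, b = getattr(end, name), getattr(qss, name)
            assert abs(a - b) <= 1e-6 * max(abs(b), 1e-12)


def test_conservation_drift_along_trajectory(ref_params):
    _, states = H.integrate(ref_params, 2.5, np.linspace(0, 100, 11),
                            initial=H.quasi_steady_state(ref_params, 1.0))
    for s in states:
        assert abs(s.S + s.S_i - ref_params.S_tot) < 1e-8 * ref_params.S_tot
        assert abs(s.SF + s.C - ref_params.SF_tot) < 1e-8 * ref_params.SF_tot


def test_numeric_multistart_root_agrees_with_closed_form(ref_params):
    for u in (1.0, 2.0, 3.0):
        a = H.quasi_steady_state(ref_params, u)
        b = H.quasi_steady_state(ref_params, u, method="numeric", seed=1)
        assert b.Y_n == pytest.approx(a.Y_n, rel=1e-6)
        assert b.S == pytest.approx(a.S, rel=1e-6)


def test_steady_state_shuttling_balance(ref_params):
    """Nuclear:cytoplasmic active-YAP ratio = (k_in/k_out)(V_cyt/V_nuc)."""
    p = ref_params
    s = H.quasi_steady_state(p, 2.0)
    expected = (p.k_in / p.k_out) * (p.V_cyt / p.V_nuc)
    assert s.Y_n / s.Y_c == pytest.approx(expected, rel=1e-12)


def test_constant_trajectory_from_steady_initial(ref_params):
    s0 = H.quasi_steady_state(ref_params, 1.0)
    _, states = H.integrate(ref_params, 1.0, np.linspace(0, 10, 5),
                            initial=s0)
    for s in states:
        assert s.Y_n == pytest.approx(s0.Y_n, rel=1e-7)


def test_step_stimulus_monotone_approach_to_new_steady_state(ref_params):
    s0 = H.quasi_steady_state(ref_params, 1.0)
    t, states = H.integrate(ref_params, 2.0, np.linspace(0, 40, 200),
                            initial=s0)
    yn = np.array([s.Y_n for s in states])
    target = H.quasi_steady_state(ref_params, 2.0).Y_n
    assert np.all(np.diff(yn) >= -1e-9 * target)
    assert yn[-1] == pytest.approx(target, rel=1e-5)


def test_observables_baseline_normalization_and_linearity(ref_params):
    base = H.quasi_steady_state(ref_params, 1.0)
    nuc, tot = H.observables(base, ref_params, baseline=base)
    assert (nuc, tot) == (pytest.approx(1.0), pytest.approx(1.0))
    doubled = H.HippoState(**{k: 2 * getattr(base, k)
                              for k in H.HippoState._FIELDS})
    n2, t2 = H.observables(doubled, ref_params)
    n1, t1 = H.observables(base, ref_params)
    assert n2 == pytest.approx(2 * n1) and t2 == pytest.approx(2 * t1)


def test_normalized_observables_invariant_to_concentration_rescaling(
        ref_params):
    """Expressing all concentrations in a rescaled unit (state and
    baseline multiplied by the same factor) leaves normalized
    observables unchanged."""
    base = H.quasi_steady_state(ref_params, 1.0)
    state = H.quasi_steady_state(ref_params, 2.2)
    ref = H.observables(state, ref_params, baseline=base)
    c = 3.7
    scale = lambda s: H.HippoState(**{k: c * getattr(s, k)
                                      for k in H.HippoState._FIELDS})
    rescaled = H.observables(scale(state), ref_params, baseline=scale(base))
    assert rescaled[0] == pytest.approx(ref[0], rel=1e-12)
    assert rescaled[1] == pytest.approx(ref[1], rel=1e-12)


def test_curve_passes_through_unity_at_baseline(ref_params):
    grid = np.linspace(0.25, 4.0, 151)     # contains 1.0
    curve = H.stimulus_response(ref_params, grid)
    i = np.argmin(np.abs(curve.stimulus - 1.0))
    assert curve.nuclear[i] == pytest.approx(1.0, abs=1e-9)
    assert curve.total[i] == pytest.approx(1.0, abs=1e-9)
    assert curve.monotone


def test_decoupled_sensor_gives_flat_curve_and_no_threshold():
    p = replace(H.HippoParams.reference(), k_sens_off=1e-12)
    curve = H.stimulus_response(p)
    assert np.allclose(curve.nuclear, 1.0, atol=1e-9)
    thr = H.activation_threshold(curve)
    assert thr.value is None and "flat" in thr.reason


def test_switch_regime_is_ultrasensitive(ref_params):
    curve = H.stimulus_response(ref_params)
    assert curve.hill > 2.0


def test_tangent_threshold_matches_symbolic_hill_oracle():
    """Tangent-at-inflection threshold on an analytic Hill curve vs the
    symbolic construction s* - (f(s*) - b)/f'(s*)."""
    import sympy as sp

    n, K, b, A = 6, 2.0, 1.0, 3.0
    s = sp.symbols("s", positive=True)
    f = b + A * s ** n / (K ** n + s ** n)
    s_star = sp.solve(sp.diff(f, s, 2), s)
    s_star = [r for r in s_star if r.is_real and r > 0][0]
    oracle = float(s_star - (f.subs(s, s_star) - b) / sp.diff(f, s).subs(
        s, s_star))

    grid = np.linspace(0.05, 8.0, 2001)
    y = b + A * grid ** n / (K ** n + grid ** n)
    curve = H.StimulusResponseCurve(stimulus=grid, nuclear=y, total=y,
                                    ok=np.ones_like(grid, bool))
    thr = H.activation_threshold(curve)
    assert thr.value == pytest.approx(oracle, rel=0.01)


def test_effective_hill_recovers_exponent_of_pure_hill_curve():
    grid = np.linspace(0.05, 50.0, 8001)   # far into saturation
    for n in (2, 4):
        y = 1.0 + 2.0 * grid ** n / (3.0 ** n + grid ** n)
        assert H.effective_hill(grid, y) == pytest.approx(n, rel=0.05)


def test_reference_threshold_near_printed_value(ref_params):
    thr = H.activation_threshold(H.stimulus_response(ref_params))
    assert thr.value == pytest.approx(1.75, rel=0.02)
    assert thr.alternatives["rise10"] is not None


def test_threshold_robust_to_twofold_rate_perturbations(ref_params):
    base, records = H.threshold_robustness(ref_params)
    worst = max(r["rel_change"] for r in records)
    assert worst < 0.25


def test_parameter_registry_counts():
    p = H.HippoParams.reference()
    assert len(p.fixed_to_one) == 5 and len(p.free) == 9
    assert all(getattr(p, n) == 1.0 for n in p.fixed_to_one)
    with pytest.raises(ValueError):
        replace(p, K_inact=2.0)          # declared fixed-to-one
    with pytest.raises(ValueError):
        replace(p, k_syn=-1.0)


def test_no_steady_state_is_flagged_not_silent():
    p = H.HippoParams.reference()
    weak = p.with_free([getattr(p, n) * (0.25 if n == "V_inact" else 1.0)
                        for n in p.free_names])
    with pytest.raises(H.NoSteadyStateError):
        H.quasi_steady_state(weak, 8.0)
    curve = H.stimulus_response(weak)
    assert (~curve.ok).any()             # partial curve with flags
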