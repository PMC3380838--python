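"""Steady-state solvers against closed forms and the integration oracle."""
import numpy as np
import pytest

from multiphos.models import ModelConfig, ParameterSet
from multiphos.sampling import SamplingPolicy, sample
from multiphos.steady import (SolverOptions, integrate_to_steady_state,
                              random_initial_state, solve, solve_lr_ns,
                              solve_lr_s, solve_ma, sweep_states)

FAST = SolverOptions(newton_grid=4, newton_random=8, lr_grid_points=400)


def rel_dist(x, y):
    return np.max(np.abs(x - y)) / max(np.max(np.abs(y)), 1e-300)


def perturb_in_class(config, state, rng, rel=1e-3):
    """Perturb a positive state without leaving its stoichiometric
    compatibility class (conservation totals are preserved exactly)."""
    from multiphos.crn import conservation_laws
    from multiphos.models import build_network

    laws = np.array(conservation_laws(build_network(config)), dtype=float)
    delta = rng.standard_normal(state.size)
    # project onto the kernel of the conservation-law matrix
    q, _ = np.linalg.qr(laws.T)
    delta -= q @ (q.T @ delta)
    scale = rel * np.min(state[state > 0]) / max(np.max(np.abs(delta)), 1e-300)
    return state + scale * delta


# --- LR-NS closed form -----------------------------------------------------


def test_lr_ns_equal_fluxes_give_uniform_phosphoform_distribution():
    cfg = ModelConfig(2, "LR", scaffold=False)
    p = ParameterSet(n=2, b=np.array([1.0, 1.0]), c=np.array([1.0, 1.0]),
                     A_tot=3.0, K_tot=1.0, P_tot=1.0)
    ss = solve_lr_ns(cfg, p)
    assert ss.n_states == 1 and ss.stable[0]
    assert np.allclose(ss.states[0], [1.0, 1.0, 1.0])


def test_lr_ns_flux_ratio_two():
    cfg = ModelConfig(1, "LR", scaffold=False)
    p = ParameterSet(n=1, b=np.array([2.0]), c=np.array([1.0]),
                     A_tot=3.0, K_tot=1.0, P_tot=1.0)
    ss = solve_lr_ns(cfg, p)
    assert np.allclose(ss.states[0], [1.0, 2.0])


def test_lr_ns_matches_integration_for_random_parameters(rng):
    cfg = ModelConfig(4, "LR", scaffold=False)
    pol = SamplingPolicy()
    for _ in range(3):
        p = sample(cfg, pol, rng)
        ss = solve_lr_ns(cfg, p)
        x0 = random_initial_state(cfg, p, rng)
        xT, conv = integrate_to_steady_state(cfg, p, x0, t_max=1e9)
        assert conv
        assert rel_dist(xT, ss.states[0]) < 1e-5


# --- LR-S ------------------------------------------------------------------


def test_lr_s_uniform_binding_rates_always_monostable(rng):
    """Phosphostate-independent scaffold binding cannot produce
    multistability (the provably monostable uniform variant)."""
    cfg = ModelConfig(2, "LR", scaffold=True, scaffold_rates_uniform=True)
    pol = SamplingPolicy()
    for _ in range(200):
        p = sample(cfg, pol, rng)
        ss = solve_lr_s(cfg, p, options=FAST)
        assert not ss.solver_failure
        assert ss.n_states == 1 and ss.n_stable == 1


def test_lr_s_vanishing_binding_leaves_substrate_free_and_dephosphorylated():
    cfg = ModelConfig(2, "LR", scaffold=True)  # phos on-scaffold only
    n = 2
    p = ParameterSet(n=n, b=np.ones(n), c=np.ones(n),
                     alpha=np.full(n + 1, 1e-12), beta=np.ones(n + 1),
                     A_tot=5.0, B_tot=2.0, K_tot=1.0, P_tot=1.0)
    ss = solve_lr_s(cfg, p)
    assert ss.n_states == 1
    state = dict(zip(ss.species, ss.states[0]))
    assert state["S0"] == pytest.approx(5.0, rel=1e-5)
    assert state["B"] == pytest.approx(2.0, rel=1e-5)


def test_lr_s_matches_integration(rng):
    cfg = ModelConfig(2, "LR", scaffold=True)
    pol = SamplingPolicy()
    for _ in range(5):
        p = sample(cfg, pol, rng)
        ss = solve_lr_s(cfg, p, options=FAST)
        x0 = random_initial_state(cfg, p, rng)
        xT, conv = integrate_to_steady_state(cfg, p, x0, t_max=1e9)
        assert conv
        dists = [rel_dist(xT, s) for s in ss.states[ss.stable]]
        assert min(dists) < 1e-4


# --- MA --------------------------------------------------------------------


def test_ma_ns_single_site_is_monostable(rng):
    """One phosphosite cannot produce bistability (no scaffold)."""
    cfg = ModelConfig(1, "MA", scaffold=False)
    pol = SamplingPolicy()
    for _ in range(20):
        p = sample(cfg, pol, rng)
        ss = solve_ma(cfg, p, ktot=1.0, options=FAST)
        assert not ss.solver_failure
        assert ss.n_stable == 1


def test_ma_large_km_approaches_lr_limit(rng):
    """With every K_M >= 1e3 * A_tot the mass-action readout matches the
    lumped linear model with b_i = kcat_i/K_M,i at each dose point."""
    from multiphos.screen import default_ktot_grid

    n = 2
    cfg_ma = ModelConfig(n, "MA", scaffold=False)
    cfg_lr = ModelConfig(n, "LR", scaffold=False)
    A_tot = 2.0
    km = 1e3 * A_tot * np.exp(rng.uniform(0, 1, n))
    kcat = np.exp(rng.uniform(-1, 1, n))
    kmp = 1e3 * A_tot * np.exp(rng.uniform(0, 1, n))
    kp = np.exp(rng.uniform(-1, 1, n))
    a = 2 * kcat / km
    ap = 2 * kp / kmp
    p_ma = ParameterSet(n=n, a=a, d=kcat.copy(), kcat=kcat, ap=ap, dp=kp.copy(), kp=kp,
                        A_tot=A_tot, P_tot=1.0)
    p_lr = ParameterSet(n=n, b=kcat / km, c=kp / kmp, A_tot=A_tot, P_tot=1.0)
    grid = default_ktot_grid(10, 1e-2, 1e2)
    for ktot in grid:
        ma = solve_ma(cfg_ma, p_ma, ktot=ktot, options=FAST)
        lr = solve_lr_ns(cfg_lr, p_lr, ktot=ktot)
        r_ma = ma.readout_values(cfg_ma)[ma.stable]
        r_lr = lr.readout_values(cfg_lr)[lr.stable]
        assert r_ma.size == 1 and r_lr.size == 1
        assert abs(r_ma[0] - r_lr[0]) <= 0.05 * A_tot


def test_ma_states_match_integration_within_basins(rng):
    """Every stable state is an attractor: integration from a small
    perturbation returns to it."""
    cfg = ModelConfig(2, "MA", scaffold=True)
    pol = SamplingPolicy(km_bin=(1, 10))
    tested = 0
    for _ in range(6):
        p = sample(cfg, pol, rng)
        ss = solve_ma(cfg, p, ktot=1.0, options=FAST)
        if ss.solver_failure:
            continue
        for state in ss.states[ss.stable]:
            x0 = perturb_in_class(cfg, state, rng)
            xT, conv = integrate_to_steady_state(cfg, p, x0, ktot=1.0, t_max=1e9)
            assert conv
            assert min(rel_dist(xT, s) for s in ss.states[ss.stable]) < 1e-4
            tested += 1
    assert tested >= 4


def test_known_bistable_set_has_three_states():
    """A screening-style draw known to be bistable: two stable states
    bracketing one unstable state, confirmed by integration from both
    attractor basins."""
    from multiphos.screen import classify

    rng = np.random.default_rng(1)
    cfg = ModelConfig(2, "MA", scaffold=True)
    pol = SamplingPolicy(km_bin=(0.1, 1))
    found = None
    for _ in range(60):
        p = sample(cfg, pol, rng)
        call = classify(cfg, p, options=FAST)
        if call.bistable:
            ss = solve_ma(cfg, p, ktot=call.witness_ktot)
            if ss.n_stable == 2:
                found = (p, call.witness_ktot, ss)
                break
    assert found is not None, "no bistable draw in the pilot stream"
    p, ktot_w, ss = found
    assert ss.n_states == 3 and ss.n_stable == 2
    for state in ss.states[ss.stable]:
        x0 = perturb_in_class(cfg, state, np.random.default_rng(2))
        xT, _ = integrate_to_steady_state(cfg, p, x0, ktot=ktot_w, t_max=1e9)
        assert rel_dist(xT, state) < 1e-4


def test_steady_state_set_invariants(rng):
    """Residuals, distinctness, and the structural zero-eigenvalue count."""
    cfg = ModelConfig(2, "MA", scaffold=True)
    pol = SamplingPolicy(km_bin=(1, 10))
    p = sample(cfg, pol, rng)
    ss = solve_ma(cfg, p, ktot=1.0)
    assert ss.residual_norm <= 1e-8
    for i in range(ss.n_states):
        for j in range(i + 1, ss.n_states):
            assert rel_dist(ss.states[i], ss.states[j]) > 1e-6
        ev = np.sort(np.abs(ss.eigvals[i]))
        assert np.all(ev[:4] <= 1e-7 * ev[-1])   # 4 conservation laws
    assert ss.n_stable >= 1


def test_integration_oracle_fixed_point_and_conservation(rng):
    cfg = ModelConfig(2, "MA", scaffold=True)
    pol = SamplingPolicy(km_bin=(1, 10))
    p = sample(cfg, pol, rng)
    ss = solve_ma(cfg, p, ktot=1.0, options=FAST)
    stable_state = ss.states[ss.stable][0]
    xT, conv = integrate_to_steady_state(cfg, p, stable_state, ktot=1.0, t_max=1e6)
    assert conv
    assert rel_dist(xT, stable_state) < 1e-8

    from multiphos.crn import conservation_laws
    from multiphos.models import build_network

    net = build_network(cfg)
    laws = conservation_laws(net)
    x0 = random_initial_state(cfg, p, rng)
    x0[ss.species.index("K")] = 1.0
    xT, _ = integrate_to_steady_state(cfg, p, x0, ktot=1.0, t_max=1e8)
    for law in laws:
        q0, qT = law @ x0, law @ xT
        assert abs(qT - q0) <= 1e-6 * max(abs(q0), 1.0)


def test_sweep_states_matches_single_point_solutions(rng):
    cfg = ModelConfig(2, "MA", scaffold=False)
    pol = SamplingPolicy(km_bin=(1, 10))
    p = sample(cfg, pol, rng)
    grid = [0.1, 1.0, 10.0]
    swept = sweep_states(cfg, p, grid, FAST)
    for ktot, st in zip(grid, swept):
        single = solve_ma(cfg, p, ktot=ktot, options=FAST)
        assert st.n_states == single.n_states
        for s in single.states:
            assert min(rel_dist(s, t) for t in st.states) < 1e-6
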