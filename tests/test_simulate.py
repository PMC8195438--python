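"""Coupled-cell SDE simulator: determinism, convergence, fates, pulses."""

import numpy as np
import pytest

import vulvascape as vs
from vulvascape.landscape import Fate
from vulvascape.simulate import SimulationSettings


def zero_signal_condition():
    return vs.ExperimentalCondition(id="dark", egf_dose=0.0, notch_receptor_factor=0.0)


def test_em_step_fixed_point_without_noise(demo_theta):
    theta = demo_theta.copy()
    theta[20] = 0.0  # sigma_dif
    y0 = theta[10] + np.sqrt(-theta[9])
    states = np.array([[0.0, y0]] * 3)
    rng = np.random.default_rng(0)
    cond = zero_signal_condition()
    s = states
    for k in range(500):
        s = vs.em_step(s, k * 1e-3, theta, cond, 1e-3, rng)
    assert np.allclose(s, states, atol=1e-12)


def test_em_step_determinism(demo_theta):
    cond = vs.ExperimentalCondition(id="wt")
    states = np.array([[0.0, 2.2]] * 3)
    a = vs.em_step(states, 0.5, demo_theta, cond, 1e-3, np.random.default_rng(7))
    b = vs.em_step(states, 0.5, demo_theta, cond, 1e-3, np.random.default_rng(7))
    assert np.array_equal(a, b)


def test_em_step_first_order_convergence(demo_theta):
    """Richardson check: deterministic endpoint error halves with dt."""
    theta = demo_theta.copy()
    theta[20] = 0.0
    cond = vs.ExperimentalCondition(id="wt")
    y0 = theta[10] + np.sqrt(-theta[9])
    rng = np.random.default_rng(0)

    def endpoint(dt, t_end=0.5):
        s = np.array([[0.05, y0]] * 3)
        for k in range(int(round(t_end / dt))):
            s = vs.em_step(s, k * dt, theta, cond, dt, rng)
        return s

    fine = endpoint(1.25e-4)
    e1 = np.max(np.abs(endpoint(1e-3) - fine))
    e2 = np.max(np.abs(endpoint(5e-4) - fine))
    assert e1 > e2 > 0
    assert 1.4 < e1 / e2 < 3.0


def test_python_step_matches_compiled_kernel(demo_theta):
    """The reference em_step and the compiled path agree without noise."""
    from vulvascape import _kernel
    from vulvascape.simulate import _pack_condition, _zero_signal_attractors

    theta = demo_theta.copy()
    theta[20] = 0.0
    cond = vs.ExperimentalCondition(id="wt")
    packed = _pack_condition(cond)
    ax, ay, afate, geom = _zero_signal_attractors(theta)
    # python path to the kernel's horizon
    y0 = theta[10] + np.sqrt(-theta[9])
    s = np.array([[0.0, y0]] * 3)
    rng = np.random.default_rng(0)
    for k in range(200):
        s = vs.em_step(s, k * 1e-3, theta, cond, 1e-3, rng)
    # fates assigned from the python endpoint match the kernel's own calls
    lp = vs.LandscapeParams(a=theta[7], b=theta[8], c=theta[9], M=theta[10],
                            tau=theta[0], smoothing_width=1e-3)
    fates_py = [vs.assign_fate(tuple(row), lp) for row in s]
    codes_full = _kernel.simulate_condition(theta, packed, 1, 1e-3, 0.2, 0, 1e-3,
                                            20000, 1e-3, ax, ay, afate, geom, -1)
    code_of = {Fate.UNASSIGNED: 0, Fate.PRIMARY: 1, Fate.SECONDARY: 2, Fate.TERTIARY: 3}
    assert [code_of[f] for f in fates_py] == list(codes_full[0])


def test_estimate_outcome_properties(demo_theta, conditions_by_id):
    out = vs.estimate_outcome(conditions_by_id["WT"], demo_theta, n_reps=50, seed=3)
    assert np.allclose(out.proportions.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(out.proportions >= 0) and np.all(out.proportions <= 1)
    out2 = vs.estimate_outcome(conditions_by_id["WT"], demo_theta, n_reps=50, seed=3)
    assert np.array_equal(out.proportions, out2.proportions)
    with pytest.raises(ValueError):
        vs.estimate_outcome(conditions_by_id["WT"], demo_theta, n_reps=0)


def test_zero_noise_outcomes_are_deterministic(demo_theta, conditions_by_id):
    theta = demo_theta.copy()
    theta[20] = 0.0
    out = vs.estimate_outcome(conditions_by_id["WT"], theta, n_reps=20, seed=1)
    assert set(np.unique(out.proportions)) <= {0.0, 1.0}


def test_dark_condition_all_tertiary(demo_theta):
    out = vs.estimate_outcome(zero_signal_condition(), demo_theta, n_reps=40, seed=2)
    assert np.all(out.proportions[:, 2] == 1.0)


def test_notch_null_pattern(reference_theta, conditions_by_id):
    fates = vs.simulate_lineage(conditions_by_id["Notch null"], reference_theta, seed=4)
    assert fates["P6.p"] is Fate.PRIMARY
    assert fates["P5.p"] is Fate.TERTIARY
    assert fates["P4.p"] is Fate.TERTIARY


def test_early_ablation_all_tertiary(reference_theta, conditions_by_id):
    out = vs.estimate_outcome(conditions_by_id["ablation L2 lethargus"],
                              reference_theta, n_reps=60, seed=5)
    assert np.all(out.proportions[:, 2] >= 0.95)


def test_wt_pattern_with_reference_particle(reference_theta, conditions_by_id):
    out = vs.estimate_outcome(conditions_by_id["WT"], reference_theta,
                              n_reps=150, seed=6)
    assert out.proportion("P4.p", Fate.TERTIARY) >= 0.9
    assert out.proportion("P5.p", Fate.SECONDARY) >= 0.9
    assert out.proportion("P6.p", Fate.PRIMARY) >= 0.9


def test_mirrored_parameterization_swaps_vulval_fates(demo_theta, conditions_by_id):
    """b -> -b (with the Notch-production direction flipped accordingly)
    exchanges primary and secondary proportions."""
    theta = demo_theta.copy()
    mirrored = theta.copy()
    mirrored[[3, 4, 8]] *= -1  # m21, m22, q2
    n = 400
    out = vs.estimate_outcome(conditions_by_id["WT"], theta, n_reps=n, seed=8)
    outm = vs.estimate_outcome(conditions_by_id["WT"], mirrored, n_reps=n, seed=8,
                               n1_sign=+1)
    for i in range(3):
        p1, p2 = out.proportions[i, 0], out.proportions[i, 1]
        m1, m2 = outm.proportions[i, 0], outm.proportions[i, 1]
        tol = 3 * np.sqrt(0.5 / n) + 1e-9  # difference of two binomial estimates
        assert abs(p1 - m2) < tol
        assert abs(p2 - m1) < tol
        assert abs(out.proportions[i, 2] - outm.proportions[i, 2]) < tol


def test_three_cell_reduction_matches_five_cell_simulation(demo_theta,
                                                           conditions_by_id):
    """An independent five-cell (P4-P8) simulation with symmetric geometry
    reproduces the three-cell reduction's fate proportions within
    Monte-Carlo error, validating the mirror boundary rule."""
    theta = demo_theta
    tau, M = theta[0], theta[10]
    m = theta[1:7].reshape(3, 2)
    q = theta[7:10]
    s, ell, gamma, he, me = theta[11:16]
    n0, n1, alpha, ld, sigma = theta[16:21]
    n_reps, dt, n_steps = 400, 1e-3, 1000
    w = 1e-3
    rng = np.random.default_rng(123)
    y0 = M + np.sqrt(-q[2])
    x = np.zeros((n_reps, 5))
    y = np.full((n_reps, 5), y0)
    atten = gamma ** np.array([2.0, 1.0, 0.0, 1.0, 2.0])  # P4..P8 around P6
    sqdt = np.sqrt(dt)
    for k in range(n_steps):
        t = k * dt
        sig_t = 0.5 * (1 + np.tanh(he * t + me))
        L = 0.5 * (1 + np.tanh(n0 - n1 * x))
        Lpad = np.pad(L, ((0, 0), (1, 1)))  # P3.p and P9.p contribute 0
        tn = (1 - ld * L) * (Lpad[:, :-2] + alpha * L + Lpad[:, 2:])
        te = sig_t * atten[None, :]
        se, sn = s * te, ell * tn
        a = m[0, 0] * se + m[0, 1] * sn + q[0]
        b = m[1, 0] * se + m[1, 1] * sn + q[1]
        c = m[2, 0] * se + m[2, 1] * sn + q[2]
        h = 0.5 * (1 - np.tanh((y - np.sqrt(w)) / (2 * w)))
        f1 = h * (-4 * x**3 - 2 * a * x - b) - (1 - h) * x
        f2 = y * (-((y - M) ** 2) - c)
        x = x + tau * f1 * dt + sigma * sqdt * rng.standard_normal(x.shape)
        y = y + tau * f2 * dt + sigma * sqdt * rng.standard_normal(y.shape)
    lp = vs.LandscapeParams(a=q[0], b=q[1], c=q[2], M=M, tau=tau,
                            smoothing_width=w)
    fates = np.empty((n_reps, 5), dtype=object)
    for r in range(n_reps):
        for i in range(5):
            fates[r, i] = vs.assign_fate((x[r, i], y[r, i]), lp)
    out3 = vs.estimate_outcome(conditions_by_id["WT"], theta, n_reps=n_reps,
                               seed=55)
    tol = 3 * np.sqrt(0.5 / n_reps)
    code = {Fate.PRIMARY: 0, Fate.SECONDARY: 1, Fate.TERTIARY: 2}

    def frac(cell_idx, fate):
        return np.mean([f is fate for f in fates[:, cell_idx]])

    for i3, i5 in ((0, 0), (1, 1), (2, 2)):  # P4.p, P5.p, P6.p
        for fate, col in code.items():
            assert abs(frac(i5, fate) - out3.proportions[i3, col]) < tol, (i3, fate)
    # the mirrored pair agrees with itself
    for fate in code:
        assert abs(frac(1, fate) - frac(3, fate)) < tol


def test_trajectory_export_is_tidy_and_consistent(demo_theta, conditions_by_id):
    df = vs.simulate_trajectory(conditions_by_id["WT"], demo_theta, seed=4,
                                stride=100)
    assert set(df.columns) == {"rep", "cell", "t", "x", "y", "theta_E",
                               "theta_N", "a", "b", "c"}
    assert set(df.cell) == set(vs.CELLS)
    # starts at the zero-signal tertiary attractor
    start = df[df.t == 0]
    y0 = demo_theta[10] + np.sqrt(-demo_theta[9])
    assert np.allclose(start.x, 0) and np.allclose(start.y, y0)
    # EGF ordering along the whole course
    by_t = df.pivot(index="t", columns="cell", values="theta_E")
    assert (by_t["P6.p"] >= by_t["P5.p"]).all()
    assert (by_t["P5.p"] >= by_t["P4.p"]).all()


def test_pulse_protocol_quiescent_cell_stays_tertiary(demo_theta):
    theta = demo_theta.copy()
    theta[20] = 0.0
    out = vs.simulate_pulse_protocol(theta, [], n_reps=10, seed=0)
    assert out.proportions[0, 2] == 1.0


def test_pulse_protocol_rejects_overlap(demo_theta):
    with pytest.raises(ValueError):
        vs.simulate_pulse_protocol(
            demo_theta, [("egf", 1.0, 0.0, 0.5), ("egf", 1.0, 0.4, 0.8)])


def test_pulse_irreversibility_appending_dark_tail(reference_theta):
    """Once cells have exited the tertiary basin, turning all signals off
    never returns them: the tertiary proportion cannot increase."""
    pulses = [("egf", 1.0, 0.0, 0.4)]
    short = vs.simulate_pulse_protocol(reference_theta, pulses, n_reps=200, seed=9,
                                       settings=SimulationSettings(t_end=0.5))
    long = vs.simulate_pulse_protocol(reference_theta, pulses, n_reps=200, seed=9,
                                      settings=SimulationSettings(t_end=1.5))
    assert long.proportions[0, 2] <= short.proportions[0, 2] + 0.03
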