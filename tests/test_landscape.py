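"""Landscape geometry: normal forms, critical points, stability, fates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vulvascape as vs
from vulvascape.landscape import Fate, PointKind, Stratum, VulvalState

from conftest import numeric_critical_points

finite = st.floats(-5, 5, allow_nan=False)


@pytest.mark.parametrize(
    "func,args,expected",
    [
        (vs.fold_rhs, (0, -1), 1.0),
        (vs.fold_rhs, (1, -1), 0.0),
        (vs.fold_rhs, (2, 0), -4.0),
        (vs.cusp_rhs, (0, 0, 0), 0.0),
        (vs.cusp_rhs, (1, -1, 0), -2.0),
        (vs.cusp_rhs, (1 / math.sqrt(2), -1, 0), 0.0),
        (vs.cusp_discriminant, (-1, 0), -8.0),
        (vs.cusp_discriminant, (0, 1), 27.0),
        (vs.cusp_discriminant, (-3, 2), -108.0),
    ],
)
def test_normal_form_values(func, args, expected):
    assert func(*args) == pytest.approx(expected, abs=1e-12)


def test_non_finite_inputs_rejected():
    with pytest.raises(ValueError):
        vs.fold_rhs(np.nan, 0.0)
    with pytest.raises(ValueError):
        vs.cusp_rhs(np.inf, 0.0, 0.0)
    with pytest.raises(ValueError):
        vs.combined_rhs((np.nan, 0.0), vs.LandscapeParams(0, 0, 0, 1))


def test_combined_rhs_fixed_points_and_branches():
    # the upper fold point is a fixed point for any cusp parameters
    lp = vs.LandscapeParams(a=0.3, b=-0.2, c=-1.0, M=2.0)
    v = vs.combined_rhs((0.0, lp.M + math.sqrt(1.0)), lp)
    assert v == pytest.approx((0.0, 0.0), abs=1e-14)
    # on the invariant line both components vanish at the cusp origin
    lp2 = vs.LandscapeParams(a=-1.0, b=0.0, c=-1.0, M=2.0)
    assert vs.combined_rhs((0.0, 0.0), lp2) == pytest.approx((0.0, 0.0), abs=1e-14)
    # above the switching line the x-dynamics are the contraction -x
    lp3 = vs.LandscapeParams(a=0.0, b=0.0, c=-1.0, M=2.0, tau=1.0)
    assert vs.combined_rhs((1.0, 2.0), lp3) == pytest.approx((-1.0, 2.0), abs=1e-14)


def test_tau_scales_velocity():
    lp1 = vs.LandscapeParams(a=-1, b=0.2, c=-0.5, M=1.5, tau=1.0)
    lp3 = vs.LandscapeParams(a=-1, b=0.2, c=-0.5, M=1.5, tau=3.0)
    v1 = np.array(vs.combined_rhs((0.4, -0.3), lp1))
    v3 = np.array(vs.combined_rhs((0.4, -0.3), lp3))
    assert np.allclose(v3, 3 * v1)


def test_find_critical_points_tristable():
    lp = vs.LandscapeParams(a=-1, b=0, c=-1, M=2)
    pts = {(round(p.position[0], 9), round(p.position[1], 9)): p
           for p in vs.find_critical_points(lp)}
    assert len(pts) == 5
    r = round(1 / math.sqrt(2), 9)
    assert pts[(0.0, 3.0)].kind is PointKind.ATTRACTOR
    assert pts[(0.0, 3.0)].fate is Fate.TERTIARY
    assert pts[(0.0, 1.0)].kind is PointKind.SADDLE
    assert pts[(-r, 0.0)].fate is Fate.PRIMARY
    assert pts[(0.0, 0.0)].kind is PointKind.SADDLE
    assert pts[(r, 0.0)].fate is Fate.SECONDARY


def test_find_critical_points_no_tertiary_for_positive_c():
    lp = vs.LandscapeParams(a=-1, b=0, c=1, M=2)
    pts = vs.find_critical_points(lp)
    assert len(pts) == 3
    assert all(p.position[1] == 0 for p in pts)


def test_find_critical_points_single_vulval_attractor():
    lp = vs.LandscapeParams(a=0, b=1, c=-1, M=2)
    pts = vs.find_critical_points(lp)
    on_axis = [p for p in pts if p.position[1] == 0]
    assert len(on_axis) == 1
    assert on_axis[0].kind is PointKind.ATTRACTOR
    assert on_axis[0].fate is Fate.PRIMARY
    assert on_axis[0].position[0] < 0
    assert len(pts) == 3  # plus the fold pair


def test_degenerate_points_flagged_not_dropped():
    on_fold = vs.find_critical_points(vs.LandscapeParams(a=-1, b=0, c=0, M=2))
    assert any(p.kind is PointKind.DEGENERATE for p in on_fold)
    on_cusp = vs.find_critical_points(vs.LandscapeParams(a=0, b=0, c=-1, M=2))
    assert any(p.kind is PointKind.DEGENERATE for p in on_cusp)


def geometry_oracle_check(rng, n_sets=100):
    """Closed-form critical points vs brute-force root finding."""
    checked = 0
    while checked < n_sets:
        a = rng.uniform(-2, 2)
        b = rng.uniform(-1.5, 1.5)
        c = rng.uniform(-2, 2)
        M = rng.uniform(0.5, 2.5)
        delta = vs.cusp_discriminant(a, b)
        # stay away from bifurcation strata and from fold points near y=0
        if abs(delta) < 0.2 or abs(c) < 0.05:
            continue
        if c < 0 and M - math.sqrt(-c) < 0.05:
            continue
        lp = vs.LandscapeParams(a=a, b=b, c=c, M=M)
        closed = vs.find_critical_points(lp)
        numeric = numeric_critical_points(lp)
        assert len(numeric) == len(closed), (a, b, c, M)
        for cx, cy, eigs in numeric:
            match = min(closed, key=lambda p: np.hypot(p.position[0] - cx, p.position[1] - cy))
            assert np.hypot(match.position[0] - cx, match.position[1] - cy) <= 1e-8
            num_kind = PointKind.ATTRACTOR if np.all(eigs < 0) else PointKind.SADDLE
            assert match.kind is num_kind, (a, b, c, M, match)
        checked += 1


def test_critical_points_match_numeric_oracle():
    geometry_oracle_check(np.random.default_rng(42), n_sets=30)


@given(x=finite, y=finite, a=finite, b=finite)
@settings(max_examples=200, deadline=None)
def test_mirror_equivariance_of_field(x, y, a, b):
    lp = vs.LandscapeParams(a=a, b=b, c=-1.0, M=2.0)
    lpm = vs.LandscapeParams(a=a, b=-b, c=-1.0, M=2.0)
    f1, f2 = vs.combined_rhs((x, y), lp)
    g1, g2 = vs.combined_rhs((-x, y), lpm)
    assert g1 == pytest.approx(-f1, abs=1e-12)
    assert g2 == pytest.approx(f2, abs=1e-12)


@pytest.mark.parametrize(
    "a,b,c,expected_n",
    [
        (-1, 0.1, -1, 5),   # c<0, delta<0
        (0, 1, -1, 3),      # c<0, delta>0
        (-1, 0.1, 1, 3),    # c>0, delta<0
        (0, 1, 1, 1),       # c>0, delta>0
    ],
)
def test_critical_point_counting(a, b, c, expected_n):
    pts = vs.find_critical_points(vs.LandscapeParams(a=a, b=b, c=c, M=2))
    assert len(pts) == expected_n


def test_crossing_fold_line_changes_count_by_two():
    for a, b in [(-1, 0.1), (0.5, 0.3), (0, 1)]:
        n_neg = len(vs.find_critical_points(vs.LandscapeParams(a, b, -0.5, 2)))
        n_pos = len(vs.find_critical_points(vs.LandscapeParams(a, b, 0.5, 2)))
        assert n_neg - n_pos == 2


def test_vulval_attractor_always_exists():
    """The cusp always keeps at least one of the two vulval attractors."""
    rng = np.random.default_rng(7)
    for _ in range(300):
        a, b = rng.uniform(-3, 3), rng.uniform(-3, 3)
        pts = vs.find_critical_points(vs.LandscapeParams(a, b, 0.5, 2))
        assert any(
            p.kind is not PointKind.SADDLE and p.position[1] == 0 for p in pts
        )


def test_smoothed_critical_points_converge_to_sharp_limit():
    """Numerically located equilibria of the smoothed field approach the
    sharp-step closed forms as the width shrinks."""
    from scipy.optimize import brentq

    lp0 = vs.LandscapeParams(a=-1, b=0.3, c=-1, M=2)
    sharp = sorted(
        p.position[0] for p in vs.find_critical_points(lp0) if p.position[1] == 0
    )
    errors = []
    for w in (0.3, 0.1, 0.03, 0.01, 0.001):
        lp = vs.LandscapeParams(a=-1, b=0.3, c=-1, M=2, smoothing_width=w)

        def f1(x):
            return vs.combined_rhs((x, 0.0), lp)[0]

        located = []
        for x_star in sharp:
            located.append(brentq(f1, x_star - 0.3, x_star + 0.3, xtol=1e-14))
        errors.append(max(abs(l - s) for l, s in zip(located, sharp)))
    assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))
    assert errors[-1] < 1e-8


def test_classify_landscape_regions():
    r = vs.classify_landscape((-1, 0, -1))
    assert r.has_tertiary and r.vulval_state is VulvalState.BISTABLE
    r = vs.classify_landscape((0, 1, -1))
    assert r.has_tertiary and r.vulval_state is VulvalState.ONLY_PRIMARY
    assert vs.classify_landscape((-1, 0, 0)).stratum is Stratum.ON_FOLD_LINE
    assert vs.classify_landscape((0, 0, -1)).stratum is Stratum.ON_CUSP_LINE
    assert vs.classify_landscape((1, -0.5, 1)).vulval_state is VulvalState.ONLY_SECONDARY


def test_classification_consistent_with_point_counts():
    rng = np.random.default_rng(3)
    for _ in range(100):
        a, b, c = rng.uniform(-2, 2, 3)
        if abs(vs.cusp_discriminant(a, b)) < 1e-3 or abs(c) < 1e-3:
            continue
        region = vs.classify_landscape((a, b, c))
        pts = vs.find_critical_points(vs.LandscapeParams(a, b, c, M=2))
        n_tert = sum(1 for p in pts if p.fate is Fate.TERTIARY)
        assert (n_tert > 0) == region.has_tertiary
        n_vulval = sum(1 for p in pts if p.fate in (Fate.PRIMARY, Fate.SECONDARY))
        assert n_vulval == (2 if region.vulval_state is VulvalState.BISTABLE else 1)


def test_assign_fate_basics():
    lp = vs.LandscapeParams(a=-1, b=0, c=-1, M=2, tau=1.0)
    tert = (0.0, 3.0)
    assert vs.assign_fate(tert, lp) is Fate.TERTIARY
    assert vs.assign_fate((-2.0, 0.0), lp) is Fate.PRIMARY
    assert vs.assign_fate((2.0, 0.0), lp) is Fate.SECONDARY
    # exact saddle with no step budget: no motion, never arbitrary
    assert vs.assign_fate((0.0, 0.0), lp, max_steps=0) is Fate.UNASSIGNED


def test_assign_fate_fine_step_oracle():
    """Basin call agrees with a fine-step reference integration."""
    from scipy.integrate import solve_ivp

    lp = vs.LandscapeParams(a=-1, b=0.4, c=-1, M=2, tau=1.0)
    attr = [p for p in vs.find_critical_points(lp) if p.kind is PointKind.ATTRACTOR]
    rng = np.random.default_rng(11)
    for _ in range(10):
        x0 = (rng.uniform(-2, 2), rng.uniform(-0.5, 3.5))
        sol = solve_ivp(lambda t, v: vs.combined_rhs(v, lp), (0, 200), x0,
                        rtol=1e-10, atol=1e-12)
        end = sol.y[:, -1]
        nearest = min(attr, key=lambda p: np.hypot(p.position[0] - end[0],
                                                   p.position[1] - end[1]))
        dist = np.hypot(nearest.position[0] - end[0], nearest.position[1] - end[1])
        if dist > 1e-6:  # reference did not settle (near-saddle start)
            continue
        assert vs.assign_fate(x0, lp) is nearest.fate
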