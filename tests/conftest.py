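"""Shared fixtures: a demonstration parameter vector and a numeric geometry oracle.

The *demo* vector is hand-constructed to satisfy the signal-map constraints
(used where only a valid landscape is needed); the *reference* vector is the
package's bundled desk-scale fit (used where the pattern quality matters).
"""

import numpy as np
import pytest
from scipy.optimize import fsolve

import vulvascape as vs


@pytest.fixture(scope="session")
def demo_theta() -> np.ndarray:
    # tau; m11 m12 m21 m22 m31 m32; q1 q2 q3; M; s l gamma H_E M_E n0 n1
    # alpha l_d sigma_dif lambda
    theta = np.array([
        10.0, 0.1, 0.1, 0.6, -0.8, 0.9, 0.3, -1.0, 0.0, -0.5, 1.5,
        2.0, 2.0, 0.3, 8.0, -4.0, -2.0, 4.0, 0.5, 0.2, 0.1, 10.0,
    ])
    from vulvascape.manifest import satisfies_constraints

    assert satisfies_constraints(theta)
    return theta


@pytest.fixture(scope="session")
def reference_theta() -> np.ndarray:
    return vs.reference_particle()


@pytest.fixture(scope="session")
def conditions_by_id() -> dict:
    return {c.id: c for c in vs.builtin_reference_conditions()}


def numeric_critical_points(lp: vs.LandscapeParams, n_starts: int = 15):
    """Brute-force 2-D root finding on the sharp-step field.

    Runs fsolve on each branch (contraction for y > 0, cusp for y <= 0) from
    a grid of starting points, keeps converged roots consistent with their
    branch, and deduplicates.  Independent of the closed-form construction.
    """

    def upper(v):  # y > 0: x' = -x, y' = y f_fold(y - M, c)
        x, y = v
        return [-x, y * (-((y - lp.M) ** 2) - lp.c)]

    def lower(v):  # y <= 0 (and the invariant line): cusp branch
        x, y = v
        return [-4 * x**3 - 2 * lp.a * x - lp.b, y * (-((y - lp.M) ** 2) - lp.c)]

    found = []
    grid = np.linspace(-3, 3, n_starts)
    for x0 in grid:
        for y0 in grid:
            for branch, cond in ((upper, lambda y: y > 1e-6), (lower, lambda y: abs(y) <= 1e-6)):
                sol, info, ier, _ = fsolve(branch, [x0, y0], full_output=True)
                if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-10:
                    continue
                if not cond(sol[1]):
                    continue
                if any(np.hypot(sol[0] - fx, sol[1] - fy) < 1e-6 for fx, fy, _ in found):
                    continue
                jac = _numeric_jacobian(branch, sol)
                found.append((sol[0], sol[1], np.linalg.eigvals(jac).real))
    return found


def _numeric_jacobian(f, v, h=1e-7):
    v = np.asarray(v, dtype=float)
    jac = np.zeros((2, 2))
    for j in range(2):
        dp = v.copy()
        dm = v.copy()
        dp[j] += h
        dm[j] -= h
        jac[:, j] = (np.asarray(f(dp)) - np.asarray(f(dm))) / (2 * h)
    return jac
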