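"""Numba-compiled inner loops for the coupled-cell SDE and fate relaxation.

Everything here operates on flat float64 arrays so that the ABC SMC inner
loop never touches Python objects.  Parameter-vector layout (see
``vulvascape.manifest``)::

    0  tau
    1..6  m11 m12 m21 m22 m31 m32
    7..9  q1 q2 q3
    10 M
    11 s   12 l   13 gamma   14 H_E   15 M_E
    16 n0  17 n1 (norm)      18 alpha 19 l_d
    20 sigma_dif  21 lambda (post-ablation decay, EGF and Notch)

Condition layout::

    0 egf_mult (dose x n_AC x lin-3 halving)
    1 notch_receptor_factor
    2 notch_ectopic
    3 ablation time (inf = no ablation)
    4..6 mosaic flags for P4.p, P5.p, P6.p (1 = no EGF reception)

Relaxation geometry layout (computed in Python, see
``vulvascape.simulate._relax_geometry``)::

    0 fold flag (1: top saddle exists with the tertiary attractor above it)
    1 y_saddle            2 tertiary attractor index
    3 cusp root count     4 x_saddle (middle root; valid when count == 3)
    5 left attractor idx  6 right attractor idx (or the single root's idx)
    7 zone height: below it the step is saturated and the flow is 1-D in x

Fate codes: 0 unassigned, 1 primary, 2 secondary, 3 tertiary.

The relaxation exploits the merged field's structure for exact early
decisions: above the top saddle the y-flow is monotone to the tertiary
attractor; inside the saturated cusp zone the flow is one-dimensional and
monotone toward the attractor on the current side of the middle root.
States within a margin of either saddle are never assigned geometrically --
they keep integrating and fall to *unassigned* on budget exhaustion.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BLOWUP = 50.0


@njit(cache=True)
def _step_h(y, width):
    """Smoothed step H(-y): 1 on the cusp side (y<=0), 0 above.

    The logistic is centered sqrt(width) above the invariant line y=0: the
    offset vanishes with the width while the step value on y=0 tends to 1,
    so the cusp equilibria on the line converge to the sharp-step closed
    forms as width -> 0.
    """
    if width == 0.0:
        return 1.0 if y <= 0.0 else 0.0
    u = (y - np.sqrt(width)) / (2.0 * width)
    if u > 20.0:
        return 0.0
    if u < -20.0:
        return 1.0
    return 0.5 * (1.0 - np.tanh(u))


@njit(cache=True)
def _drift(x, y, a, b, c, M, tau, width):
    h = _step_h(y, width)
    fcusp = -4.0 * x * x * x - 2.0 * a * x - b
    f1 = h * fcusp - (1.0 - h) * x
    u = y - M
    f2 = y * (-u * u - c)
    return tau * f1, tau * f2


@njit(cache=True)
def _geometric_fate(x, y, geom, margin):
    """Exact basin call where the flow structure allows it; -1 otherwise."""
    if geom[0] != 0.0 and y > geom[1] + margin:
        return int(geom[2])  # monotone y-flow up to the tertiary attractor
    if y < geom[7]:
        n_roots = geom[3]
        if n_roots == 1.0:
            return int(geom[6])  # single cusp attractor: 1-D monotone flow
        if n_roots == 3.0:
            if x < geom[4] - margin:
                return int(geom[5])
            if x > geom[4] + margin:
                return int(geom[6])
    return -1


@njit(cache=True)
def relax_to_attractor(x, y, a, b, c, M, tau, width, dt, max_steps, radius,
                       ax, ay, geom):
    """Noise-free flow until an attractor's basin is decided.

    Returns the index into (ax, ay) of the attractor reached -- by entering
    its convergence radius or by an exact geometric basin call -- or -1 on
    budget exhaustion or blow-up.
    """
    r2 = radius * radius
    for step in range(max_steps + 1):
        k = _geometric_fate(x, y, geom, radius)
        if k >= 0:
            return k
        for j in range(ax.shape[0]):
            dxa = x - ax[j]
            dya = y - ay[j]
            if dxa * dxa + dya * dya <= r2:
                return j
        if step == max_steps:
            break
        if abs(x) > BLOWUP or abs(y) > BLOWUP:
            return -1
        f1, f2 = _drift(x, y, a, b, c, M, tau, width)
        x += f1 * dt
        y += f2 * dt
    return -1


@njit(cache=True)
def simulate_condition(params, cond, n_reps, dt, t_end, seed, width,
                       relax_steps, radius, ax, ay, afate, geom, n1_sign):
    """Euler-Maruyama ensemble for one condition; returns fate codes (n_reps,3).

    Each rep is seeded independently (seed + rep).  After t_end the signals
    are cut and each cell's fate is called under the zero-signal landscape
    (noise-free relaxation with exact geometric early exits); a trajectory
    deciding no basin within budget, or leaving the blow-up box, is 0
    (unassigned).
    """
    tau = params[0]
    m = params[1:7]
    q = params[7:10]
    big_m = params[10]
    s = params[11]
    ell = params[12]
    gamma = params[13]
    he = params[14]
    me = params[15]
    n0 = params[16]
    n1 = params[17] * (-n1_sign)  # default direction: production rises as x falls
    alpha = params[18]
    ld = params[19]
    sigma = params[20]
    lam = params[21]
    n_steps = int(np.ceil(t_end / dt))

    # per-step signal tables shared by all replicates
    egf = np.zeros((n_steps, 3))
    ndecay = np.ones(n_steps)
    t_abl = cond[3]
    for step in range(n_steps):
        t = step * dt
        decay = 1.0
        tc = t
        if t > t_abl:
            decay = np.exp(-lam * (t - t_abl))
            tc = t_abl  # AC removed: EGF production frozen, ligand decays
            ndecay[step] = decay
        sigma_t = 0.5 * (1.0 + np.tanh(he * tc + me))
        for i in range(3):
            base = sigma_t * gamma ** (2 - i) * cond[0]
            if cond[4 + i] != 0.0:
                base = 0.0
            egf[step, i] = base * decay

    fates = np.zeros((n_reps, 3), dtype=np.int8)
    xs = np.zeros(3)
    ys = np.zeros(3)
    ln = np.zeros(3)
    y0 = big_m + np.sqrt(max(-q[2], 0.0))
    sqdt = np.sqrt(dt)
    for rep in range(n_reps):
        np.random.seed(seed + rep)
        for i in range(3):
            xs[i] = 0.0
            ys[i] = y0
        blown = False
        for step in range(n_steps):
            # Notch production from the current state
            for i in range(3):
                ln[i] = 0.5 * (1.0 + np.tanh(n0 - n1 * xs[i]))
            for i in range(3):
                if i == 0:
                    left = 0.0
                    right = ln[1]
                elif i == 1:
                    left = ln[0]
                    right = ln[2]
                else:
                    left = ln[1]   # P7.p mirrors P5.p
                    right = ln[1]
                if cond[1] == 0.0:
                    tn = 0.0
                else:
                    base = (1.0 - ld * ln[i]) * (left + alpha * ln[i] + right)
                    tn = (base * cond[1] + cond[2]) * ndecay[step]
                se = s * egf[step, i]
                sn = ell * tn
                a = m[0] * se + m[1] * sn + q[0]
                b = m[2] * se + m[3] * sn + q[1]
                c = m[4] * se + m[5] * sn + q[2]
                f1, f2 = _drift(xs[i], ys[i], a, b, c, big_m, tau, width)
                xs[i] += f1 * dt + sigma * sqdt * np.random.normal()
                ys[i] += f2 * dt + sigma * sqdt * np.random.normal()
                if abs(xs[i]) > BLOWUP or abs(ys[i]) > BLOWUP:
                    blown = True
            if blown:
                break
        if blown:
            continue  # all three cells flagged unassigned
        for i in range(3):
            # noise-free relaxation tolerates a coarser step than the SDE
            k = relax_to_attractor(xs[i], ys[i], q[0], q[1], q[2], big_m, tau,
                                   width, 2.0 * dt, relax_steps, radius,
                                   ax, ay, geom)
            fates[rep, i] = 0 if k < 0 else afate[k]
    return fates


@njit(cache=True)
def simulate_pulses(params, pulses, n_reps, dt, t_end, seed, width,
                    relax_steps, radius, ax, ay, afate, geom):
    """Single isolated cell under a scripted signal schedule.

    ``pulses`` is a (k, 4) array of rows (channel, level, t_start, t_end)
    with channel 0 = EGF, 1 = Notch.  No autocrine or paracrine Notch
    coupling.  Returns fate codes (n_reps,).
    """
    tau = params[0]
    m = params[1:7]
    q = params[7:10]
    big_m = params[10]
    s = params[11]
    ell = params[12]
    sigma = params[20]
    n_steps = int(np.ceil(t_end / dt))
    fates = np.zeros(n_reps, dtype=np.int8)
    y0 = big_m + np.sqrt(max(-q[2], 0.0))
    sqdt = np.sqrt(dt)
    for rep in range(n_reps):
        np.random.seed(seed + rep)
        x = 0.0
        y = y0
        blown = False
        for step in range(n_steps):
            t = step * dt
            te = 0.0
            tn = 0.0
            for j in range(pulses.shape[0]):
                if pulses[j, 2] <= t < pulses[j, 3]:
                    if pulses[j, 0] == 0.0:
                        te += pulses[j, 1]
                    else:
                        tn += pulses[j, 1]
            se = s * te
            sn = ell * tn
            a = m[0] * se + m[1] * sn + q[0]
            b = m[2] * se + m[3] * sn + q[1]
            c = m[4] * se + m[5] * sn + q[2]
            f1, f2 = _drift(x, y, a, b, c, big_m, tau, width)
            x += f1 * dt + sigma * sqdt * np.random.normal()
            y += f2 * dt + sigma * sqdt * np.random.normal()
            if abs(x) > BLOWUP or abs(y) > BLOWUP:
                blown = True
                break
        if blown:
            continue
        k = relax_to_attractor(x, y, q[0], q[1], q[2], big_m, tau, width,
                               2.0 * dt, relax_steps, radius, ax, ay, geom)
        fates[rep] = 0 if k < 0 else afate[k]
    return fates
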