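"""Likelihood-free fitting by ABC SMC with an OLCM perturbation kernel.

The posterior ``pi(theta | X0) \\propto pi(theta) L(X0 | theta)`` is
approximated by a sequence of intermediate distributions
``pi_t = pi(theta | d(X(theta), X0) <= eps_t)`` with a decreasing threshold
schedule: each ``eps_t`` is the 0.3 quantile (order statistic
``ceil(0.3 n)``) of the previous generation's accepted distances.  Accepted
particles are resampled by weight, perturbed with a Gaussian kernel whose
covariance is the Optimal Local Covariance Matrix (OLCM): for each parent,
the weighted scatter of the previous particles that already satisfy the next
threshold, about that parent.  Weights follow the standard importance
correction ``pi(theta') / sum_j w_j K_j(theta')``.

The distance between an observed condition set and its simulation is the L1
mismatch of fate proportions plus a penalty for unassigned outcomes,
averaged over conditions; cells missing from the record are skipped in both
terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .manifest import ParameterManifest, parameter_manifest, satisfies_constraints
from .signaling import CELLS, ExperimentalCondition
from .simulate import OutcomeTable, SimulationSettings, estimate_outcome

__all__ = [
    "PriorSpec",
    "ParticlePopulation",
    "pattern_distance",
    "sample_prior",
    "olcm_covariance",
    "perturb_and_weight",
    "adapt_epsilon",
    "run_abc_smc",
    "make_condition_model",
    "fit_modifier",
]

OLCM_JITTER = 1e-8


@dataclass(frozen=True)
class PriorSpec:
    """Flat priors on finite supports with a joint constraint predicate."""

    lows: np.ndarray
    highs: np.ndarray
    names: list[str]
    constraint: Callable[[np.ndarray], bool] | None = None
    max_rejections: int = 100_000

    @classmethod
    def from_manifest(
        cls,
        manifest: ParameterManifest | None = None,
        constrained: bool = True,
    ) -> "PriorSpec":
        manifest = manifest or parameter_manifest()
        lo, hi = manifest.bounds
        return cls(lows=lo, highs=hi, names=manifest.names,
                   constraint=satisfies_constraints if constrained else None)

    @property
    def dim(self) -> int:
        return len(self.lows)

    def in_support(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta)
        if np.any(theta < self.lows) or np.any(theta > self.highs):
            return False
        return self.constraint is None or bool(self.constraint(theta))

    def log_pdf(self, theta: np.ndarray) -> float:
        # flat: constant inside the (constrained) support, -inf outside; the
        # normalizing constant cancels in the importance weights
        return 0.0 if self.in_support(theta) else -np.inf


@dataclass
class ParticlePopulation:
    """One ABC SMC generation."""

    particles: np.ndarray  # (N, dim)
    weights: np.ndarray  # (N,), normalized
    distances: np.ndarray  # (N,)
    epsilon: float
    generation: int
    n_proposals: int = 0
    names: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.distances > self.epsilon):
            raise ValueError("all particle distances must satisfy the threshold")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be normalized")

    @property
    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def weighted_mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def weighted_quantile(self, name_or_idx, qs: Sequence[float]) -> np.ndarray:
        idx = self.names.index(name_or_idx) if isinstance(name_or_idx, str) else name_or_idx
        x = self.particles[:, idx]
        order = np.argsort(x)
        cw = np.cumsum(self.weights[order])
        return np.interp(np.asarray(qs), cw, x[order])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.particles, columns=self.names or None)
        df["weight"] = self.weights
        df["distance"] = self.distances
        df["epsilon"] = self.epsilon
        df["generation"] = self.generation
        return df

    @classmethod
    def from_frame(cls, df) -> "ParticlePopulation":
        """Rebuild a stored generation (inverse of :meth:`to_frame`)."""
        meta = {"weight", "distance", "epsilon", "generation"}
        names = [c for c in df.columns if c not in meta]
        return cls(
            particles=df[names].to_numpy(float),
            weights=df["weight"].to_numpy(float),
            distances=df["distance"].to_numpy(float),
            epsilon=float(df["epsilon"].iloc[0]),
            generation=int(df["generation"].iloc[0]),
            names=names,
        )


# ---------------------------------------------------------------------------
# distance

def pattern_distance(
    observed: Sequence[ExperimentalCondition],
    simulated: Mapping[str, OutcomeTable] | Sequence[OutcomeTable],
) -> float:
    """L1 fate-proportion mismatch plus unassigned penalty, averaged over
    conditions::

        d = (1/E) sum_e sum_f sum_c |p_{e,f,c} - p^sim_{e,f,c}|
          + (1/E) sum_e sum_c |p^sim_{e,4,c}|

    Cells absent from a condition's record (ablation rows lack P4.p) are
    skipped in both terms.
    """
    if not isinstance(simulated, Mapping):
        simulated = {t.condition_id: t for t in simulated}
    missing = [c.id for c in observed if c.id not in simulated]
    if missing:
        raise ValueError(f"simulated tables missing for conditions {missing}")
    E = len(observed)
    if E == 0:
        raise ValueError("empty condition set")
    total = 0.0
    for cond in observed:
        table = simulated[cond.id]
        for cell, probs in cond.observed.items():
            if probs is None:
                continue
            i = CELLS.index(cell)
            sim = table.proportions[i]
            total += float(np.abs(np.asarray(probs) - sim[:3]).sum()) + abs(float(sim[3]))
    return total / E


def make_condition_model(
    conditions: Sequence[ExperimentalCondition],
    n_reps: int = 24,
    settings: SimulationSettings | None = None,
    modifiers: Mapping[str, float] | None = None,
    nuisance_dose_index: int | None = None,
) -> Callable[[np.ndarray, int], float]:
    """Distance model ``(theta, seed) -> d`` over a fixed condition set.

    If ``nuisance_dose_index`` is given, that entry of ``theta`` resolves
    every ``egf_dose == "fit"`` condition (the overexpression level fitted
    as a nuisance parameter).  The returned callable is the ABC inner loop:
    it shares one attractor computation per parameter vector across all
    conditions but is numerically identical to composing
    :func:`vulvascape.simulate.estimate_outcome` with
    :func:`pattern_distance` (a test asserts the equivalence).
    """
    from . import _kernel
    from .simulate import _pack_condition, _zero_signal_attractors

    settings = settings or SimulationSettings()
    conditions = list(conditions)
    base_mods = dict(modifiers or {})
    # pre-pack what does not depend on theta
    static: list[tuple[np.ndarray | None, ExperimentalCondition]] = []
    for cond in conditions:
        needs_theta = nuisance_dose_index is not None and cond.egf_dose == "fit"
        if needs_theta:
            static.append((None, cond))
        else:
            static.append((_pack_condition(cond.resolve(base_mods)), cond))
    # observed proportions and availability masks, in CELLS order
    obs = np.zeros((len(conditions), 3, 3))
    avail = np.zeros((len(conditions), 3), dtype=bool)
    for e, cond in enumerate(conditions):
        for i, cell in enumerate(CELLS):
            probs = cond.observed.get(cell)
            if probs is not None:
                obs[e, i] = probs
                avail[e, i] = True
    E = len(conditions)
    if E == 0:
        raise ValueError("empty condition set")

    def model(theta: np.ndarray, seed: int) -> float:
        theta = np.asarray(theta, dtype=float)
        try:
            ax, ay, afate, geom = _zero_signal_attractors(theta, settings.smoothing_width)
        except ValueError:
            return np.inf
        ss = np.random.SeedSequence([int(seed), 0x51D])
        child = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(E)]
        total = 0.0
        for e, ((packed, cond), cseed) in enumerate(zip(static, child)):
            if packed is None:
                mods = dict(base_mods)
                mods["ju1100_dose"] = float(theta[nuisance_dose_index])
                packed = _pack_condition(cond.resolve(mods))
            codes = _kernel.simulate_condition(
                theta[:22], packed, n_reps, settings.dt, settings.t_end,
                cseed, settings.smoothing_width, settings.relax_steps,
                settings.radius, ax, ay, afate, geom, -1)
            for i in range(3):
                if not avail[e, i]:
                    continue
                col = codes[:, i]
                p_sim = np.array([np.mean(col == 1), np.mean(col == 2),
                                  np.mean(col == 3)])
                total += np.abs(obs[e, i] - p_sim).sum() + np.mean(col == 0)
        return total / E

    return model


# ---------------------------------------------------------------------------
# SMC machinery

def adapt_epsilon(distances_prev: Sequence[float], quantile: float = 0.3) -> float:
    """The ``ceil(q n)``-th smallest previous distance (order statistic)."""
    d = np.sort(np.asarray(distances_prev, dtype=float))
    if d.size == 0:
        raise ValueError("empty distance list")
    k = int(np.ceil(quantile * d.size))
    return float(d[max(k, 1) - 1])


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample the constrained flat prior."""
    for _ in range(priors.max_rejections):
        theta = rng.uniform(priors.lows, priors.highs)
        if priors.constraint is None or priors.constraint(theta):
            return theta
    raise RuntimeError(
        "prior constraint acceptance rate below floor; constraints likely inconsistent"
    )


def olcm_covariance(
    population: ParticlePopulation,
    epsilon_next: float,
    center: np.ndarray,
    jitter: float = OLCM_JITTER,
) -> np.ndarray:
    """OLCM kernel covariance for a parent particle.

    Weighted scatter, about ``center``, of the previous generation's
    particles whose distance already satisfies ``epsilon_next``; falls back
    to the global weighted covariance about the weighted mean when that
    sub-population is empty.  A diagonal jitter guarantees positive
    definiteness.
    """
    center = np.asarray(center, dtype=float)
    mask = population.distances <= epsilon_next
    if not np.any(mask):
        dev = population.particles - population.weighted_mean()
        w = population.weights
    else:
        dev = population.particles[mask] - center
        w = population.weights[mask]
        w = w / w.sum()
    cov = (w[:, None] * dev).T @ dev
    return cov + jitter * np.eye(cov.shape[0])


def _log_mvn(dx: np.ndarray, chol: np.ndarray) -> float:
    z = np.linalg.solve(chol, dx)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    k = dx.shape[0]
    return float(-0.5 * (z @ z) - 0.5 * logdet - 0.5 * k * np.log(2 * np.pi))


class _KernelMixture:
    """Precomputed Gaussian-mixture density over a particle population."""

    def __init__(self, particles: np.ndarray, weights: np.ndarray,
                 chols: Sequence[np.ndarray]):
        self.particles = particles
        self.chols = list(chols)
        d = particles.shape[1]
        eye = np.eye(d)
        self.inv_chols = np.stack([np.linalg.solve(c, eye) for c in chols])
        self.logdets = np.array([2.0 * np.sum(np.log(np.diag(c))) for c in chols])
        with np.errstate(divide="ignore"):
            self.logw = np.log(weights)
        self.const = -0.5 * d * np.log(2 * np.pi)

    def logpdf(self, theta: np.ndarray) -> float:
        dx = theta[None, :] - self.particles
        z = np.einsum("jab,jb->ja", self.inv_chols, dx)
        logs = self.logw - 0.5 * np.einsum("ja,ja->j", z, z) - 0.5 * self.logdets + self.const
        m = logs.max()
        return float(m + np.log(np.exp(logs - m).sum()))


def _kernel_mixture_logpdf(theta: np.ndarray, particles: np.ndarray,
                           weights: np.ndarray, chols: Sequence[np.ndarray]) -> float:
    return _KernelMixture(particles, weights, chols).logpdf(theta)


def perturb_and_weight(
    theta_parent: np.ndarray,
    population_prev: ParticlePopulation,
    kernel_chols: list[np.ndarray],
    parent_index: int,
    priors: PriorSpec,
    rng: np.random.Generator,
    mixture: "_KernelMixture | None" = None,
) -> tuple[np.ndarray, float]:
    """Gaussian-perturb a parent and compute the unnormalized weight.

    Proposals outside the prior support get weight 0 (caller resamples).
    """
    chol = kernel_chols[parent_index]
    theta = theta_parent + chol @ rng.standard_normal(priors.dim)
    lp = priors.log_pdf(theta)
    if not np.isfinite(lp):
        return theta, 0.0
    if mixture is None:
        mixture = _KernelMixture(population_prev.particles,
                                 population_prev.weights, kernel_chols)
    return theta, float(np.exp(lp - mixture.logpdf(theta)))


def _rng_for(seed: int, generation: int, proposal: int) -> tuple[np.random.Generator, int]:
    ss = np.random.SeedSequence([int(seed), int(generation), int(proposal)])
    sim_seed = int(ss.generate_state(1)[0] % 2**31)
    return np.random.default_rng(ss.spawn(1)[0]), sim_seed


def run_abc_smc(
    model: Callable[[np.ndarray, int], float],
    priors: PriorSpec,
    n_particles: int,
    n_generations: int = 14,
    seed: int = 0,
    workers: int = 1,
    epsilon_initial: float = np.inf,
    epsilon_target: float = 0.0,
    quantile: float = 0.3,
    max_proposal_factor: int = 60,
    max_total_evals: int | None = None,
    resume_from: ParticlePopulation | None = None,
    verbose: bool = False,
) -> list[ParticlePopulation]:
    """Sequential ABC sampler; returns one population per completed generation.

    Generation 1 rejection-samples the prior at ``epsilon_initial``; each
    later generation adopts the ``quantile`` order statistic of the previous
    distances as its threshold and perturbs weighted-resampled parents with
    the OLCM kernel.  Fully reproducible given ``seed`` (and invariant to
    ``workers``): every proposal's randomness derives from
    ``(seed, generation, proposal index)``.  Stagnation (fewer than
    ``n_particles`` acceptances within ``max_proposal_factor * n_particles``
    simulator evaluations, or a vanishing in-support proposal rate) stops
    the run cleanly with the populations so far.  ``max_total_evals``
    bounds the simulator evaluations across the whole run (a deterministic
    budget: runs with equal seeds stop at the same point).

    ``resume_from`` restarts after a stored generation: because every
    proposal's randomness is keyed by (seed, generation, index), resuming
    generation g+1 from a stored generation g reproduces the populations a
    single uninterrupted run would have produced.
    """
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    populations: list[ParticlePopulation] = []
    start_gen = 1
    if resume_from is not None:
        if resume_from.particles.shape[0] != n_particles:
            raise ValueError("resume population size differs from n_particles")
        populations.append(resume_from)
        start_gen = resume_from.generation + 1
    parallel = Parallel(n_jobs=workers, prefer="processes") if workers > 1 else None
    batch = max(2 * workers, 16)

    def evaluate(gen: int, proposals: list[tuple[int, np.ndarray, float]]):
        # proposals: (proposal_idx, theta, unnorm_weight)
        if parallel is None:
            return [model(th, _rng_for(seed, gen, i)[1]) for i, th, _ in proposals]
        return parallel(delayed(model)(th, _rng_for(seed, gen, i)[1]) for i, th, _ in proposals)

    eps = float(epsilon_initial)
    total_evals = 0
    for gen in range(start_gen, n_generations + 1):
        if max_total_evals is not None and total_evals >= max_total_evals:
            if verbose:
                print(f"[abc] evaluation budget reached before generation {gen}; stopping")
            break
        if gen > 1:
            prev = populations[-1]
            eps_next = adapt_epsilon(prev.distances, quantile)
            # strictly decreasing schedule even under ties
            eps = min(eps_next, np.nextafter(prev.epsilon, -np.inf))
            covs = [olcm_covariance(prev, eps, prev.particles[j])
                    for j in range(n_particles)]
            chols = [np.linalg.cholesky(c) for c in covs]
            mixture = _KernelMixture(prev.particles, prev.weights, chols)
        accepted: list[tuple[np.ndarray, float, float]] = []
        proposal_idx = 0
        n_evals = 0
        max_evals = max_proposal_factor * n_particles
        if max_total_evals is not None:
            max_evals = min(max_evals, max(max_total_evals - total_evals, 0))
        max_raw = 1000 * n_particles  # guard: out-of-support proposals are cheap
        stagnated = False
        while len(accepted) < n_particles:
            if n_evals >= max_evals or proposal_idx >= max_raw:
                stagnated = True
                break
            block: list[tuple[int, np.ndarray, float]] = []
            while len(block) < batch and n_evals + len(block) < max_evals \
                    and proposal_idx < max_raw:
                rng, _ = _rng_for(seed, gen, proposal_idx)
                if gen == 1:
                    try:
                        theta = sample_prior(priors, rng)
                    except RuntimeError:
                        stagnated = True
                        break
                    w = 1.0
                    block.append((proposal_idx, theta, w))
                else:
                    parent = rng.choice(n_particles, p=prev.weights)
                    theta, w = perturb_and_weight(prev.particles[parent], prev,
                                                  chols, int(parent), priors, rng,
                                                  mixture=mixture)
                    if w > 0.0:
                        block.append((proposal_idx, theta, w))
                proposal_idx += 1
            if stagnated and not block:
                break
            n_evals += len(block)
            total_evals += len(block)
            dists = evaluate(gen, block)
            for (_, theta, w), d in zip(block, dists):
                if d <= eps and len(accepted) < n_particles:
                    accepted.append((theta, w, float(d)))
        if len(accepted) < n_particles:
            if verbose:
                print(f"[abc] generation {gen}: stagnated after {proposal_idx} proposals; stopping")
            break
        thetas = np.array([a[0] for a in accepted])
        ws = np.array([a[1] for a in accepted])
        ws = ws / ws.sum()
        ds = np.array([a[2] for a in accepted])
        pop = ParticlePopulation(particles=thetas, weights=ws, distances=ds,
                                 epsilon=eps, generation=gen,
                                 n_proposals=proposal_idx, names=list(priors.names))
        if not np.isfinite(pop.ess):
            raise RuntimeError("effective sample size is not finite")
        populations.append(pop)
        if verbose:
            print(f"[abc] gen {gen}: eps={eps:.4g} proposals={proposal_idx} "
                  f"evals={n_evals} acc={n_particles/max(n_evals,1):.2%} ess={pop.ess:.1f}")
        if eps <= epsilon_target:
            break
    return populations


# ---------------------------------------------------------------------------
# one-dimensional mutant-modifier fits

def fit_modifier(
    theta: np.ndarray,
    modifier: str,
    conditions: Sequence[ExperimentalCondition],
    bounds: tuple[float, float],
    known_modifiers: Mapping[str, float] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    n_grid: int = 33,
) -> float:
    """Grid minimization of the pattern distance over one modifier constant.

    Holds ``theta`` fixed at a chosen posterior particle and scans the named
    modifier (``"notch_reduction"``, ``"ectopic_notch"`` or
    ``"egf_hypomorph"``) over ``bounds``, refining once around the best grid
    point.
    """
    known = dict(known_modifiers or {})

    def objective(value: float) -> float:
        mods = dict(known)
        mods[modifier] = float(value)
        model = make_condition_model(conditions, n_reps=n_reps, settings=settings,
                                     modifiers=mods)
        return model(np.asarray(theta, dtype=float), seed)

    lo, hi = bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = [objective(g) for g in grid]
    best = int(np.argmin(vals))
    span = (hi - lo) / (n_grid - 1)
    lo2 = max(lo, grid[best] - span)
    hi2 = min(hi, grid[best] + span)
    grid2 = np.linspace(lo2, hi2, 9)
    vals2 = [objective(g) for g in grid2]
    return float(grid2[int(np.argmin(vals2))])
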