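"""Adaptive dynamic sine-cosine fitness grey wolf optimizer (ADSCFGWO).

The optimizer hybridizes two population metaheuristics:

* **Grey wolf optimizer (GWO)** — agents move toward a weighted combination
  of the three fittest solutions (the alpha, beta and delta "wolves").
  Unlike classic GWO, the weighted-prey variant implemented here combines
  the leaders into a single prey estimate using *fitness-derived weights*,
  so a single distance term ``D`` drives all three pull terms.
* **Sine cosine algorithm (SCA)** — positions are perturbed along
  sine/cosine-scaled distances to the best solution, with an amplitude
  that decays linearly over the iteration budget.

On top of the hybrid update sits an *adaptive dynamic group* mechanism:
the population is split into an exploration group (size ``n1``) and an
exploitation group (size ``n2``).  The exploration share decays linearly
from 70% to 30% of the population over the run, and a stall detector
(best fitness unchanged for a window of iterations) pushes agents back
from exploitation into exploration to escape flat regions.  Elitism keeps
the incumbent best solution in the population whenever an iteration fails
to improve on it, so the best-so-far fitness is non-increasing.

All randomness flows through a single :class:`numpy.random.Generator`;
identical (seed, config, objective) triples produce bit-identical runs.
Fitness is always *minimized*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "OptimizerConfig",
    "Agent",
    "LeaderSet",
    "GroupState",
    "IterationRecord",
    "OptimizationResult",
    "compute_a",
    "sca_r1_schedule",
    "leader_weights",
    "weighted_prey_distance",
    "gwo_candidate",
    "sca_candidate",
    "select_leaders",
    "exploration_schedule",
    "dynamic_search",
    "step",
    "optimize",
    "optimize_baseline",
]

Objective = Callable[[np.ndarray], float]


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------


@dataclass
class OptimizerConfig:
    """Configuration of an ADSCFGWO run.

    Defaults follow the published configuration for the CNN-tuning
    experiments: 10 agents, 80 iterations, 11 independent repeats, and an
    ``a`` schedule decaying from 2 to 0.

    Parameters
    ----------
    dim:
        Search-space dimensionality ``d``.
    lower_bounds, upper_bounds:
        Per-dimension bounds of the search cube; positions are clamped
        back into the cube after every iteration.
    n_agents:
        Population size ``n`` (at least 3: three leaders are required).
    t_max:
        Iteration budget.
    n_runs:
        Number of independent repeats an experiment driver should run.
    seed:
        Base RNG seed; a run is fully determined by it.
    a_init:
        Upper end of the linearly decaying ``a`` schedule.
    exploration_frac_hi, exploration_frac_lo:
        Start/end fractions of the population assigned to exploration.
    stall_window:
        Number of consecutive iterations with an unchanged best fitness
        that triggers growth of the exploration group.
    stall_step:
        Agents moved from exploitation to exploration per trigger.
    stall_tolerance:
        Relative tolerance used to decide "unchanged" best fitness.
    sca_r2_range:
        ``"standard"`` draws the SCA angle r2 from [0, 2π] and the target
        scale r3 from [0, 2] (the ranges of the parent algorithm);
        ``"literal"`` restricts both to [0, 1].
    weighting_mode:
        ``"inverse"`` (default) weights the leaders by 1/(ε+f) so the best
        leader dominates under minimization; ``"literal"`` normalizes the
        raw fitness values directly.
    """

    dim: int
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    n_agents: int = 10
    t_max: int = 80
    n_runs: int = 11
    seed: int = 0
    a_init: float = 2.0
    exploration_frac_hi: float = 0.70
    exploration_frac_lo: float = 0.30
    stall_window: int = 3
    stall_step: int = 1
    stall_tolerance: float = 1e-12
    sca_r2_range: Literal["standard", "literal"] = "standard"
    weighting_mode: Literal["literal", "inverse"] = "inverse"

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if self.lower_bounds.shape != (self.dim,) or self.upper_bounds.shape != (self.dim,):
            raise ValueError("bounds must be vectors of length dim")
        if not np.all(self.lower_bounds < self.upper_bounds):
            raise ValueError("lower_bounds must be elementwise below upper_bounds")
        if self.n_agents < 3:
            raise ValueError("n_agents must be at least 3 (three leaders required)")
        if self.t_max < 1:
            raise ValueError("t_max must be positive")
        if not (0.0 < self.exploration_frac_lo <= self.exploration_frac_hi < 1.0):
            raise ValueError("need 0 < exploration_frac_lo <= exploration_frac_hi < 1")
        if self.sca_r2_range not in ("standard", "literal"):
            raise ValueError("sca_r2_range must be 'standard' or 'literal'")
        if self.weighting_mode not in ("literal", "inverse"):
            raise ValueError("weighting_mode must be 'literal' or 'inverse'")

    @property
    def n1_cap(self) -> int:
        return _round_half_up(self.exploration_frac_hi * self.n_agents)

    @property
    def n1_floor(self) -> int:
        return _round_half_up(self.exploration_frac_lo * self.n_agents)


@dataclass
class Agent:
    """A candidate solution with its fitness and current group."""

    position: np.ndarray
    fitness: float
    group: Literal["exploration", "exploitation"] = "exploration"
    index: int = 0


@dataclass
class LeaderSet:
    """The three fittest solutions with raw fitnesses and normalized weights."""

    s_alpha: np.ndarray
    s_beta: np.ndarray
    s_delta: np.ndarray
    f_alpha: float
    f_beta: float
    f_delta: float
    w_alpha: float
    w_beta: float
    w_delta: float
    degenerate_weights: bool = False

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_alpha, self.w_beta, self.w_delta])


@dataclass
class GroupState:
    """Exploration/exploitation group sizes and stall bookkeeping.

    ``boost`` accumulates the stall-triggered additions on top of the
    baseline linear schedule, so a stall can only push ``n1`` above the
    schedule and never below the floor.
    """

    n1: int
    n2: int
    stall_count: int = 0
    boost: int = 0


@dataclass
class IterationRecord:
    t: int
    best_fitness: float
    best_position: np.ndarray
    n1: int
    n2: int
    a: float
    r1_sca: float


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[IterationRecord]
    evaluations: int
    seed: int

    def history_frame(self):
        """Per-iteration log as a pandas DataFrame (t, best_fitness, n1, n2, a, r1_sca)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t": [r.t for r in self.history],
                "best_fitness": [r.best_fitness for r in self.history],
                "n1": [r.n1 for r in self.history],
                "n2": [r.n2 for r in self.history],
                "a": [r.a for r in self.history],
                "r1_sca": [r.r1_sca for r in self.history],
            }
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# scalar schedules and weights
# ---------------------------------------------------------------------------


def compute_a(t: int, t_max: int, a_init: float = 2.0) -> float:
    """Linearly decaying GWO control parameter ``a = a_init * (1 - t/t_max)``.

    ``a`` starts at ``a_init`` (2 by convention) and reaches 0 at the final
    iteration, shifting the A coefficients from exploration (|A| > 1) to
    exploitation (|A| < 1).
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration index t={t} outside [0, {t_max}]")
    return a_init * (1.0 - t / t_max)


def sca_r1_schedule(t: int, t_max: int, a_init: float = 2.0) -> float:
    """Amplitude of the sine-cosine perturbation at iteration ``t``.

    Follows the parent algorithm's linear decay ``r1 = a_init*(1 - t/t_max)``,
    shrinking the sine/cosine move toward zero as the run progresses.
    """
    return compute_a(t, t_max, a_init)


def leader_weights(
    f_alpha: float,
    f_beta: float,
    f_delta: float,
    mode: Literal["literal", "inverse"] = "inverse",
    eps: float = 1e-12,
) -> tuple[float, float, float, bool]:
    """Normalized fitness weights of the three leaders.

    ``literal`` divides each raw fitness by their sum (requires non-negative
    values); ``inverse`` normalizes ``1/(eps + f)`` so the *best* (lowest
    fitness) leader carries the largest weight under minimization.  Negative
    fitnesses under ``inverse`` are first shifted to be non-negative.

    Returns ``(w_alpha, w_beta, w_delta, degenerate)`` where ``degenerate``
    flags an all-zero denominator resolved to the uniform (1/3, 1/3, 1/3).
    """
    f = np.array([f_alpha, f_beta, f_delta], dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("leader fitnesses must be finite")
    if mode == "literal":
        if np.any(f < 0):
            raise ValueError("literal weighting requires non-negative fitness values")
        g = f
    else:
        if np.any(f < 0):
            f = f - f.min()
        g = 1.0 / (eps + f)
    total = g.sum()
    if total <= 0.0:
        return (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0, True)
    w = g / total
    return (float(w[0]), float(w[1]), float(w[2]), False)


# ---------------------------------------------------------------------------
# position updates
# ---------------------------------------------------------------------------


def weighted_prey_distance(x: np.ndarray, leaders: LeaderSet, c1: np.ndarray | float) -> np.ndarray:
    """Distance ``D = |C1 * (wα·Sα + wβ·Sβ + wδ·Sδ) - X|`` to the weighted prey.

    The three leaders are collapsed into a single prey estimate by their
    normalized fitness weights before the classic GWO encircling distance
    is taken.
    """
    x = np.asarray(x, dtype=float)
    centroid = (
        leaders.w_alpha * np.asarray(leaders.s_alpha, dtype=float)
        + leaders.w_beta * np.asarray(leaders.s_beta, dtype=float)
        + leaders.w_delta * np.asarray(leaders.s_delta, dtype=float)
    )
    if centroid.shape != x.shape:
        raise ValueError("position/leader dimension mismatch")
    return np.abs(np.asarray(c1) * centroid - x)


def gwo_candidate(
    x: np.ndarray,
    leaders: LeaderSet,
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fitness-weighted grey-wolf move ``(T1 + T2 + T3) / 3``.

    ``Ti = S_i - A_i * D`` with a single shared distance ``D`` computed from
    the weighted prey (C1 = 2*r2, one r2 vector per call) and independent
    coefficient vectors ``A_i = 2a*r1_i - a``.  The result is *not* clamped;
    bound handling belongs to the iteration step.

    Draw order (one ``rng.random(dim)`` each): r2, then r1 for alpha, beta,
    delta — relevant when forcing draws in tests.
    """
    x = np.asarray(x, dtype=float)
    dim = x.shape[0]
    c1 = 2.0 * rng.random(dim)
    d = weighted_prey_distance(x, leaders, c1)
    out = np.zeros_like(x)
    for s in (leaders.s_alpha, leaders.s_beta, leaders.s_delta):
        a_vec = 2.0 * a * rng.random(dim) - a
        out += np.asarray(s, dtype=float) - a_vec * d
    return out / 3.0


def sca_candidate(
    x: np.ndarray,
    s_alpha: np.ndarray,
    r1_sca: float,
    phase: Literal["sin", "cos"],
    rng: np.random.Generator,
    r_range: Literal["standard", "literal"] = "standard",
) -> np.ndarray:
    """Sine/cosine perturbation ``x + r1 * trig(r2) * |r3*Sα - x|``.

    ``standard`` draws the angle r2 from [0, 2π] and the scale r3 from
    [0, 2]; ``literal`` restricts both to [0, 1].  Draw order per call:
    r2 vector, then r3 vector.
    """
    x = np.asarray(x, dtype=float)
    s_alpha = np.asarray(s_alpha, dtype=float)
    if s_alpha.shape != x.shape:
        raise ValueError("position/leader dimension mismatch")
    dim = x.shape[0]
    if r_range == "standard":
        r2 = 2.0 * np.pi * rng.random(dim)
        r3 = 2.0 * rng.random(dim)
    else:
        r2 = rng.random(dim)
        r3 = rng.random(dim)
    trig = np.sin(r2) if phase == "sin" else np.cos(r2)
    return x + r1_sca * trig * np.abs(r3 * s_alpha - x)


# ---------------------------------------------------------------------------
# leaders and groups
# ---------------------------------------------------------------------------


def select_leaders(
    population: Sequence[Agent],
    mode: Literal["literal", "inverse"] = "inverse",
) -> LeaderSet:
    """Pick the three lowest-fitness agents as alpha, beta, delta.

    Ties are broken by the stable agent index; weights come from
    :func:`leader_weights`.
    """
    if len(population) < 3:
        raise ValueError("need at least 3 evaluated agents to select leaders")
    ranked = sorted(population, key=lambda ag: (ag.fitness, ag.index))
    alpha, beta, delta = ranked[0], ranked[1], ranked[2]
    wa, wb, wd, degen = leader_weights(alpha.fitness, beta.fitness, delta.fitness, mode)
    return LeaderSet(
        s_alpha=alpha.position.copy(),
        s_beta=beta.position.copy(),
        s_delta=delta.position.copy(),
        f_alpha=alpha.fitness,
        f_beta=beta.fitness,
        f_delta=delta.fitness,
        w_alpha=wa,
        w_beta=wb,
        w_delta=wd,
        degenerate_weights=degen,
    )


def exploration_schedule(
    t: int,
    t_max: int,
    n: int,
    frac_hi: float = 0.70,
    frac_lo: float = 0.30,
) -> int:
    """Baseline exploration group size: linear decay from 70% to 30% of ``n``."""
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration index t={t} outside [0, {t_max}]")
    frac = frac_hi - (frac_hi - frac_lo) * t / t_max
    return _round_half_up(n * frac)


def _stalled(tail: Sequence[float], window: int, rel_tol: float) -> bool:
    if len(tail) < window:
        return False
    ref = tail[-1]
    scale = max(1.0, abs(ref))
    return all(abs(v - ref) <= rel_tol * scale for v in tail[-window:])


def dynamic_search(
    best_history: Sequence[float],
    groups: GroupState,
    config: OptimizerConfig,
) -> GroupState:
    """Grow the exploration group when the best fitness has stalled.

    If the last ``stall_window`` best-so-far values are equal within the
    relative ``stall_tolerance``, ``stall_step`` agents move from
    exploitation to exploration (capped at round(frac_hi * n)) and the
    stall counter resets.  Otherwise the groups are returned unchanged
    apart from the updated trailing-equal count.
    """
    n = config.n_agents
    cap = config.n1_cap
    if _stalled(best_history, config.stall_window, config.stall_tolerance):
        n1 = min(groups.n1 + config.stall_step, cap)
        return GroupState(n1=n1, n2=n - n1, stall_count=0, boost=groups.boost + config.stall_step)
    # trailing count of best values equal to the current best
    count = 0
    if best_history:
        ref = best_history[-1]
        scale = max(1.0, abs(ref))
        for v in reversed(best_history):
            if abs(v - ref) <= config.stall_tolerance * scale:
                count += 1
            else:
                break
    return replace(groups, stall_count=count)


# ---------------------------------------------------------------------------
# the iteration step and full runs
# ---------------------------------------------------------------------------


@dataclass
class _RunState:
    population: list[Agent]
    groups: GroupState
    leaders: LeaderSet
    t: int
    best_position: np.ndarray
    best_fitness: float
    best_history: list[float] = field(default_factory=list)
    evaluations: int = 0


def _safe_eval(fitness: Objective, x: np.ndarray) -> float:
    val = float(fitness(x))
    if not np.isfinite(val):
        warnings.warn("non-finite fitness value; treating as +inf", RuntimeWarning, stacklevel=3)
        return math.inf
    return val


def step(
    state: _RunState,
    fitness: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> _RunState:
    """Advance the population by one ADSCFGWO iteration (in place).

    Per iteration: update the ``a`` and SCA-amplitude schedules; run the
    stall detector once; assign the ``n1`` worst agents to exploration and
    the ``n2`` best to exploitation; move every agent by the weighted GWO
    update, perturbing the candidate with a sine (exploration, r4 < 0.5) or
    cosine (exploitation, r4 >= 0.5) SCA move; clamp to bounds; re-evaluate;
    apply elitism; refresh the leaders; append an iteration record.
    """
    t = state.t + 1
    if t > config.t_max:
        raise ValueError("iteration budget exhausted")
    a = compute_a(t, config.t_max, config.a_init)
    r1 = sca_r1_schedule(t, config.t_max, config.a_init)

    groups = dynamic_search(state.best_history, state.groups, config)
    base = exploration_schedule(
        t, config.t_max, config.n_agents, config.exploration_frac_hi, config.exploration_frac_lo
    )
    n1 = min(max(base + groups.boost, config.n1_floor), config.n1_cap)
    groups = GroupState(
        n1=n1, n2=config.n_agents - n1, stall_count=groups.stall_count, boost=groups.boost
    )

    # n2 fittest agents exploit; the n1 worst explore
    ranked = sorted(state.population, key=lambda ag: (ag.fitness, ag.index))
    for ag in ranked[: groups.n2]:
        ag.group = "exploitation"
    for ag in ranked[groups.n2 :]:
        ag.group = "exploration"

    lo, hi = config.lower_bounds, config.upper_bounds
    for ag in state.population:
        cand = gwo_candidate(ag.position, state.leaders, a, rng)
        r4 = rng.random()
        if ag.group == "exploration" and r4 < 0.5:
            cand = sca_candidate(
                cand, state.leaders.s_alpha, r1, "sin", rng, config.sca_r2_range
            )
        elif ag.group == "exploitation" and r4 >= 0.5:
            cand = sca_candidate(
                cand, state.leaders.s_alpha, r1, "cos", rng, config.sca_r2_range
            )
        ag.position = np.clip(cand, lo, hi)
        ag.fitness = _safe_eval(fitness, ag.position)
        state.evaluations += 1

    new_best = min(ag.fitness for ag in state.population)
    if new_best < state.best_fitness:
        best_agent = min(state.population, key=lambda ag: (ag.fitness, ag.index))
        state.best_fitness = best_agent.fitness
        state.best_position = best_agent.position.copy()
    else:
        # elitism: no improvement, so the incumbent best replaces the worst agent
        worst = max(state.population, key=lambda ag: (ag.fitness, -ag.index))
        worst.position = state.best_position.copy()
        worst.fitness = state.best_fitness

    state.leaders = select_leaders(state.population, config.weighting_mode)
    state.groups = groups
    state.t = t
    state.best_history.append(state.best_fitness)
    return state


def _init_state(fitness: Objective, config: OptimizerConfig, rng: np.random.Generator) -> _RunState:
    lo, hi = config.lower_bounds, config.upper_bounds
    positions = lo + (hi - lo) * rng.random((config.n_agents, config.dim))
    population = [
        Agent(position=positions[i].copy(), fitness=_safe_eval(fitness, positions[i]), index=i)
        for i in range(config.n_agents)
    ]
    leaders = select_leaders(population, config.weighting_mode)
    n1 = exploration_schedule(
        0, config.t_max, config.n_agents, config.exploration_frac_hi, config.exploration_frac_lo
    )
    best = min(population, key=lambda ag: (ag.fitness, ag.index))
    return _RunState(
        population=population,
        groups=GroupState(n1=n1, n2=config.n_agents - n1),
        leaders=leaders,
        t=0,
        best_position=best.position.copy(),
        best_fitness=best.fitness,
        best_history=[best.fitness],
        evaluations=config.n_agents,
    )


def optimize(fitness: Objective, config: OptimizerConfig) -> OptimizationResult:
    """Run ADSCFGWO for ``config.t_max`` iterations and return the best solution."""
    rng = np.random.default_rng(config.seed)
    state = _init_state(fitness, config, rng)
    history: list[IterationRecord] = []
    for _ in range(config.t_max):
        state = step(state, fitness, config, rng)
        history.append(
            IterationRecord(
                t=state.t,
                best_fitness=state.best_fitness,
                best_position=state.best_position.copy(),
                n1=state.groups.n1,
                n2=state.groups.n2,
                a=compute_a(state.t, config.t_max, config.a_init),
                r1_sca=sca_r1_schedule(state.t, config.t_max, config.a_init),
            )
        )
    return OptimizationResult(
        best_position=state.best_position,
        best_fitness=state.best_fitness,
        history=history,
        evaluations=state.evaluations,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# parent-algorithm baselines
# ---------------------------------------------------------------------------


def _gwo_step_classic(
    positions: np.ndarray,
    fits: np.ndarray,
    a: float,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    order = np.lexsort((np.arange(len(fits)), fits))
    s = positions[order[:3]]
    n, dim = positions.shape
    new = np.empty_like(positions)
    for i in range(n):
        acc = np.zeros(dim)
        for k in range(3):
            r1, r2 = rng.random(dim), rng.random(dim)
            a_vec = 2.0 * a * r1 - a
            c_vec = 2.0 * r2
            d = np.abs(c_vec * s[k] - positions[i])
            acc += s[k] - a_vec * d
        new[i] = np.clip(acc / 3.0, lo, hi)
    return new


def _sca_step_classic(
    positions: np.ndarray,
    best: np.ndarray,
    r1: float,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n, dim = positions.shape
    new = np.empty_like(positions)
    for i in range(n):
        r2 = 2.0 * np.pi * rng.random(dim)
        r3 = 2.0 * rng.random(dim)
        r4 = rng.random(dim)
        dist = np.abs(r3 * best - positions[i])
        move = np.where(r4 < 0.5, np.sin(r2), np.cos(r2)) * r1 * dist
        new[i] = np.clip(positions[i] + move, lo, hi)
    return new


def optimize_baseline(
    fitness: Objective,
    config: OptimizerConfig,
    algorithm: Literal["gwo", "sca"],
) -> OptimizationResult:
    """Classic GWO or SCA run under the same config, for comparison experiments.

    ``gwo`` is the plain three-leader update (no fitness weights, no
    groups); ``sca`` is the plain sine-cosine update toward the best
    solution.  Both track the best-so-far solution so histories are
    monotone under minimization.
    """
    if algorithm not in ("gwo", "sca"):
        raise ValueError(f"unknown baseline algorithm {algorithm!r}")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower_bounds, config.upper_bounds
    positions = lo + (hi - lo) * rng.random((config.n_agents, config.dim))
    fits = np.array([_safe_eval(fitness, p) for p in positions])
    evaluations = config.n_agents
    best_i = int(np.argmin(fits))
    best_pos, best_fit = positions[best_i].copy(), float(fits[best_i])
    history: list[IterationRecord] = []
    for t in range(1, config.t_max + 1):
        a = compute_a(t, config.t_max, config.a_init)
        if algorithm == "gwo":
            positions = _gwo_step_classic(positions, fits, a, lo, hi, rng)
        else:
            positions = _sca_step_classic(positions, best_pos, a, lo, hi, rng)
        fits = np.array([_safe_eval(fitness, p) for p in positions])
        evaluations += config.n_agents
        i = int(np.argmin(fits))
        if fits[i] < best_fit:
            best_fit = float(fits[i])
            best_pos = positions[i].copy()
        history.append(
            IterationRecord(
                t=t,
                best_fitness=best_fit,
                best_position=best_pos.copy(),
                n1=0,
                n2=config.n_agents,
                a=a,
                r1_sca=a,
            )
        )
    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=history,
        evaluations=evaluations,
        seed=config.seed,
    )
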