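"""Grey-wolf optimization with three enhancements, plus PSO and random search.

The grey-wolf optimizer (GWO) maintains a population of candidate solutions
("wolves") ranked by fitness; the three best — alpha, beta, delta — jointly
steer every position update.  This module implements the standard update
equations together with three enhancements:

* **dynamic weight** — the coefficient scale ``a`` decays linearly from 2 to 0
  over the run, shifting search from exploration (|A| > 1) to exploitation;
* **elite opposition-based learning** — complementary candidates are generated
  for the top fraction of the pack by interpolating between the best and the
  worst member, widening coverage of the search space;
* **elite retention** — the top fraction of each generation is guaranteed to
  survive into the next, making the population's best member monotone.

Every component can be switched off independently, which is what the ablation
harness in :mod:`igwohealth.experiments` exercises.  A canonical global-best
particle-swarm optimizer and a uniform random search are provided as baselines
under the same contract.

All randomness flows through named child streams of one seed, so disabling one
component does not shift the draws any other component sees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .search_space import (
    CandidateVector,
    HyperparameterSpace,
    RFConfig,
    decode,
    repair,
    sample_uniform,
)

__all__ = [
    "OptimizerConfig",
    "WolfPack",
    "TraceRecord",
    "OptimizationTrace",
    "dynamic_weight",
    "coefficient_vectors",
    "update_position",
    "elite_opposition",
    "elite_retention",
    "check_termination",
    "optimize",
    "optimize_pso",
    "random_search",
    "select_features",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration and bookkeeping types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizerConfig:
    """Run settings for the swarm optimizers.

    Defaults follow the study protocol: a pack of 30 wolves, at most 100
    iterations, opposition applied to the top 10% and retention to the top
    20%, convergence declared when the best fitness changes by less than
    ``1e-5`` between iterations.
    """

    population_size: int = 30
    max_iterations: int = 100
    elite_opposition_fraction: float = 0.10
    elite_retention_fraction: float = 0.20
    convergence_tol: float = 1e-5
    seed: int = 0
    dynamic_weight: bool = True
    elite_opposition: bool = True
    elite_retention: bool = True
    #: reflect opposites through the box (lower+upper-x) instead of
    #: interpolating toward the worst member
    classical_opposition: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 3:
            raise ValueError("population must hold at least the leader triple (N >= 3)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for name in ("elite_opposition_fraction", "elite_retention_fraction"):
            f = getattr(self, name)
            if not 0 < f <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class WolfPack:
    """Population with leader triple and a best-so-far archive.

    The archive is bookkeeping, independent of the population: its fitness
    never decreases even when retention is disabled and good members are lost
    from the pack itself.
    """

    members: list[CandidateVector]
    best_vector: np.ndarray | None = None
    best_fitness: float = -math.inf

    def ranked_indices(self) -> np.ndarray:
        """Member indices sorted by descending fitness, ties to lower index."""
        fits = np.array([m.fitness for m in self.members], dtype=float)
        return np.argsort(-fits, kind="stable")

    @property
    def leaders(self) -> tuple[CandidateVector, CandidateVector, CandidateVector]:
        order = self.ranked_indices()
        return tuple(self.members[i] for i in order[:3])  # type: ignore[return-value]

    def update_archive(self) -> None:
        order = self.ranked_indices()
        top = self.members[order[0]]
        if top.fitness is not None and top.fitness > self.best_fitness:
            self.best_fitness = float(top.fitness)
            self.best_vector = top.coords.copy()


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    weight_a: float
    best_fitness: float
    mean_fitness: float
    diversity: float


@dataclass
class OptimizationTrace:
    """Per-iteration record of the run; serializable to JSON lines."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, rec: TraceRecord) -> None:
        self.records.append(rec)

    @property
    def best_series(self) -> np.ndarray:
        return np.array([r.best_fitness for r in self.records])

    def __len__(self) -> int:
        return len(self.records)

    def to_jsonl(self) -> str:
        import json

        return "\n".join(json.dumps(vars(r)) for r in self.records)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------


def dynamic_weight(t: int, T: int) -> float:
    """Linear decay ``a = 2 - 2 t / T`` from 2 (exploration) to 0."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration {t} outside [0, {T}]")
    return 2.0 - 2.0 * t / T


def coefficient_vectors(
    a: float, rng: np.random.Generator, d: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the stochastic coefficients ``A = 2 a r1 - a`` and ``C = 2 r2``.

    Componentwise, ``A`` lies in [-a, a] and ``C`` in [0, 2].
    """
    r1 = rng.uniform(size=d)
    r2 = rng.uniform(size=d)
    return 2.0 * a * r1 - a, 2.0 * r2


def update_position(
    x: CandidateVector,
    leaders: tuple[CandidateVector, CandidateVector, CandidateVector],
    a: float,
    rng: np.random.Generator,
) -> CandidateVector:
    """Move a wolf toward the alpha/beta/delta leaders.

    For each leader ``X_k`` an independent coefficient pair is drawn and the
    encircling equations give ``D_k = |C_k * X_k - x|`` and
    ``X_k' = X_k - A_k * D_k``; the new position is the average of the three
    pulls, clamped back into the unit cube.
    """
    d = x.coords.shape[0]
    pulls = np.empty((3, d))
    for k, leader in enumerate(leaders):
        A, C = coefficient_vectors(a, rng, d)
        D = np.abs(C * leader.coords - x.coords)
        pulls[k] = leader.coords - A * D
    return repair(CandidateVector(pulls.mean(axis=0)))


def elite_opposition(
    pack: WolfPack,
    fraction: float,
    rng: np.random.Generator,
    classical: bool = False,
) -> list[CandidateVector]:
    """Generate one opposite candidate per elite member.

    For each of the top ``ceil(fraction * N)`` wolves, draws ``F ~ U[0,1]``
    and forms ``X_new = X_best + F * (X_worst - X_best)`` — an interpolation
    between that elite and the current worst member.  With ``classical=True``
    the textbook reflection ``1 - x`` (through the unit box) is used instead.
    """
    order = pack.ranked_indices()
    n_elite = math.ceil(fraction * len(pack.members))
    if n_elite == 0:
        logger.info("opposition fraction rounds to zero elites; skipping")
        return []
    worst = pack.members[order[-1]].coords
    opposites = []
    for idx in order[:n_elite]:
        best = pack.members[idx].coords
        if classical:
            new = 1.0 - best
        else:
            F = rng.uniform()
            new = best + F * (worst - best)
        opposites.append(repair(CandidateVector(new)))
    return opposites


def elite_retention(
    previous: WolfPack,
    candidate_members: list[CandidateVector],
    fraction: float,
) -> WolfPack:
    """Merge a generation: the previous elite keeps guaranteed slots.

    The top ``ceil(fraction * N)`` of the previous pack survive; the rest of
    the ``N`` slots go to the best candidates.  Leaders are implied by member
    fitness; the archive carries over and is refreshed.
    """
    n = len(previous.members)
    n_keep = math.ceil(fraction * n)
    prev_order = previous.ranked_indices()
    kept = [previous.members[i].copy() for i in prev_order[:n_keep]]
    cand_sorted = sorted(
        range(len(candidate_members)),
        key=lambda i: (-float(candidate_members[i].fitness), i),
    )
    fillers = [candidate_members[i] for i in cand_sorted[: n - n_keep]]
    merged = WolfPack(
        members=kept + fillers,
        best_vector=previous.best_vector,
        best_fitness=previous.best_fitness,
    )
    merged.update_archive()
    return merged


def check_termination(trace: OptimizationTrace, tol: float, T: int) -> bool:
    """Stop at the iteration cap, or when the best fitness stalls below tol."""
    if len(trace) == 0:
        raise ValueError("termination check requires a nonempty trace")
    t = trace.records[-1].iteration
    if t >= T:
        return True
    if len(trace) >= 2:
        return abs(trace.records[-1].best_fitness - trace.records[-2].best_fitness) < tol
    return False


# --------------------------------------------------------------------------
# internal helpers
# --------------------------------------------------------------------------


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """One named child generator per component, all derived from one seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _diversity(members: list[CandidateVector]) -> float:
    """Mean pairwise euclidean distance of the pack."""
    X = np.array([m.coords for m in members])
    n = len(X)
    if n < 2:
        return 0.0
    diff = X[:, None, :] - X[None, :, :]
    dists = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, k=1)
    return float(dists[iu].mean())


def _evaluate(members: list[CandidateVector], fitness_fn, where: str) -> None:
    for i, m in enumerate(members):
        if m.fitness is None:
            try:
                m.fitness = float(fitness_fn(m))
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(
                    f"fitness evaluation failed at {where}, member {i}"
                ) from exc


# --------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------


def optimize(
    fitness_fn,
    space: HyperparameterSpace,
    config: OptimizerConfig,
) -> tuple[RFConfig, float, OptimizationTrace]:
    """Run the improved grey-wolf optimizer and return the decoded optimum.

    ``fitness_fn`` maps a :class:`CandidateVector` to a real number to be
    maximized.  The loop per iteration: compute the weight ``a``, move every
    wolf toward the leader triple, evaluate, inject opposition candidates
    (each replaces the current worst member only if strictly better), apply
    elite retention against the previous generation, refresh the archive,
    record the trace, and test termination.

    With all three enhancement flags off this reduces to standard GWO except
    that the weight is held constant at ``a = 1`` (the linear schedule's
    mean), isolating the schedule itself in ablations.
    """
    rngs = _streams(config.seed, ("init", "updates", "opposition"))
    N, T = config.population_size, config.max_iterations

    pack = WolfPack(members=sample_uniform(space, N, rngs["init"]))
    _evaluate(pack.members, fitness_fn, "initialization")
    pack.update_archive()

    trace = OptimizationTrace()
    for t in range(1, T + 1):
        a = dynamic_weight(t, T) if config.dynamic_weight else 1.0
        leaders = pack.leaders
        moved = [
            update_position(m, leaders, a, rngs["updates"]) for m in pack.members
        ]
        _evaluate(moved, fitness_fn, f"iteration {t} position update")

        new_pack = WolfPack(
            members=moved,
            best_vector=pack.best_vector,
            best_fitness=pack.best_fitness,
        )

        if config.elite_opposition:
            opposites = elite_opposition(
                new_pack,
                config.elite_opposition_fraction,
                rngs["opposition"],
                classical=config.classical_opposition,
            )
            _evaluate(opposites, fitness_fn, f"iteration {t} opposition")
            # greedy acceptance: each opposite replaces the current worst
            # member iff strictly better
            for opp in opposites:
                order = new_pack.ranked_indices()
                worst_idx = order[-1]
                if opp.fitness > new_pack.members[worst_idx].fitness:
                    new_pack.members[worst_idx] = opp

        if config.elite_retention:
            new_pack = elite_retention(
                pack, new_pack.members, config.elite_retention_fraction
            )
        new_pack.update_archive()
        pack = new_pack

        fits = np.array([m.fitness for m in pack.members], dtype=float)
        trace.append(
            TraceRecord(
                iteration=t,
                weight_a=a,
                best_fitness=pack.best_fitness,
                mean_fitness=float(fits.mean()),
                diversity=_diversity(pack.members),
            )
        )
        if check_termination(trace, config.convergence_tol, T):
            break

    best = CandidateVector(pack.best_vector)
    return decode(space, best), pack.best_fitness, trace


def optimize_pso(
    fitness_fn,
    space: HyperparameterSpace,
    config: OptimizerConfig,
    inertia: float = 0.7,
    c1: float = 1.5,
    c2: float = 1.5,
) -> tuple[RFConfig, float, OptimizationTrace]:
    """Canonical global-best particle swarm optimizer, same contract as
    :func:`optimize`.

    Velocity update ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``,
    position ``x <- repair(x + v)``; inertia 0.7 per the comparison protocol,
    acceleration constants 1.5.
    """
    rngs = _streams(config.seed, ("init", "updates"))
    N, T = config.population_size, config.max_iterations
    d = space.n_dims

    X = np.array([m.coords for m in sample_uniform(space, N, rngs["init"])])
    V = np.zeros_like(X)
    members = [CandidateVector(x) for x in X]
    _evaluate(members, fitness_fn, "initialization")
    fits = np.array([m.fitness for m in members], dtype=float)

    pbest, pbest_fit = X.copy(), fits.copy()
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    trace = OptimizationTrace()
    for t in range(1, T + 1):
        r1 = rngs["updates"].uniform(size=(N, d))
        r2 = rngs["updates"].uniform(size=(N, d))
        V = inertia * V + c1 * r1 * (pbest - X) + c2 * r2 * (gbest - X)
        X = np.clip(X + V, 0.0, 1.0)
        members = [CandidateVector(x) for x in X]
        _evaluate(members, fitness_fn, f"iteration {t}")
        fits = np.array([m.fitness for m in members], dtype=float)

        improved = fits > pbest_fit
        pbest[improved] = X[improved]
        pbest_fit[improved] = fits[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

        trace.append(
            TraceRecord(
                iteration=t,
                weight_a=inertia,
                best_fitness=gbest_fit,
                mean_fitness=float(fits.mean()),
                diversity=_diversity(members),
            )
        )
        if check_termination(trace, config.convergence_tol, T):
            break

    return decode(space, CandidateVector(gbest)), gbest_fit, trace


def random_search(
    fitness_fn,
    space: HyperparameterSpace,
    budget: int,
    rng: np.random.Generator,
) -> tuple[RFConfig, float]:
    """Evaluate ``budget`` uniform candidates and return the best.

    Serves as the no-structure baseline: with the same seed stream the best
    fitness is non-decreasing in the budget (prefix property).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    members = sample_uniform(space, budget, rng)
    _evaluate(members, fitness_fn, "random search")
    best = max(range(budget), key=lambda i: (float(members[i].fitness), -i))
    return decode(space, members[best]), float(members[best].fitness)


# --------------------------------------------------------------------------
# binary feature-selection mode
# --------------------------------------------------------------------------


def _levy_steps(
    rng: np.random.Generator, shape: tuple[int, ...], alpha: float = 1.5
) -> np.ndarray:
    """Levy-stable steps via the Mantegna algorithm (stability index 1.5)."""
    num = math.gamma(1 + alpha) * math.sin(math.pi * alpha / 2)
    den = math.gamma((1 + alpha) / 2) * alpha * 2 ** ((alpha - 1) / 2)
    sigma_u = (num / den) ** (1 / alpha)
    u = rng.normal(0.0, sigma_u, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    return u / np.abs(v) ** (1 / alpha)


def _mask_of(coords: np.ndarray) -> np.ndarray:
    return (coords >= 0.5).astype(int)


def select_features(
    fitness_fn,
    n_features: int,
    config: OptimizerConfig,
) -> np.ndarray:
    """Binary-masked grey-wolf feature selection.

    Wolves keep continuous positions in the unit cube; a position is read as
    a feature mask by thresholding each coordinate at 0.5.  Initial positions
    are perturbed by Levy-flight steps (Mantegna algorithm, stability index
    1.5, step scale 0.1 of the cube) and each wolf's step size is jittered by
    a Cauchy mutation whose scale decays as ``1 - t/T``.  ``fitness_fn``
    receives an integer 0/1 mask and returns a real to maximize.  A candidate
    whose mask is all-zero is repaired by activating one uniformly random
    feature.  Returns the best mask found.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_features == 1:
        return np.array([1])

    rngs = _streams(config.seed, ("init", "updates", "mutation"))
    N, T = config.population_size, config.max_iterations

    X = rngs["init"].uniform(size=(N, n_features))
    X = np.clip(X + 0.1 * _levy_steps(rngs["init"], X.shape), 0.0, 1.0)

    def ensure_nonzero(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if _mask_of(coords).sum() == 0:
            coords = coords.copy()
            coords[rng.integers(n_features)] = 1.0
        return coords

    members = []
    cache: dict[tuple, float] = {}

    def eval_mask(coords: np.ndarray) -> float:
        key = tuple(_mask_of(coords))
        if key not in cache:
            cache[key] = float(fitness_fn(np.array(key)))
        return cache[key]

    for i in range(N):
        X[i] = ensure_nonzero(X[i], rngs["init"])
        members.append(CandidateVector(X[i], eval_mask(X[i])))

    pack = WolfPack(members=members)
    pack.update_archive()
    best_mask = _mask_of(pack.best_vector)

    for t in range(1, T + 1):
        a = dynamic_weight(t, T) if config.dynamic_weight else 1.0
        leaders = pack.leaders
        scale = 1.0 - t / T
        moved = []
        for m in pack.members:
            new = update_position(m, leaders, a, rngs["updates"])
            # Cauchy mutation of the step size, decaying over the run
            step = scale * rngs["mutation"].standard_cauchy(size=n_features) * 0.05
            coords = np.clip(new.coords + step, 0.0, 1.0)
            coords = ensure_nonzero(coords, rngs["mutation"])
            moved.append(CandidateVector(coords, eval_mask(coords)))
        new_pack = WolfPack(
            members=moved, best_vector=pack.best_vector, best_fitness=pack.best_fitness
        )
        if config.elite_retention:
            new_pack = elite_retention(
                pack, new_pack.members, config.elite_retention_fraction
            )
        new_pack.update_archive()
        pack = new_pack
        if pack.best_fitness > -math.inf:
            best_mask = _mask_of(pack.best_vector)

    if best_mask.sum() == 0:  # pragma: no cover - guarded upstream
        best_mask[int(rngs["mutation"].integers(n_features))] = 1
    return best_mask
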