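"""Multiobjective differential evolution (MODE) with a bounded external archive.

The optimizer follows the standard DE loop (mutation, binomial crossover,
selection) with three modifications:

* the mutation base vector is drawn from an external archive of
  nondominated solutions rather than the population (DE/best/1 flavor),
* selection is Pareto-based and routes nondominated trials through the
  archive, and
* F and Cr are self-adaptive: F ~ N(0.5, 0.3^2) truncated to (0, 2] by
  resampling; Cr ~ N(Cr_m, 0.1^2) truncated to [0, 1] by resampling, with
  Cr_m reset each iteration to the median of the Cr values that produced
  successful trials.

The archive has fixed capacity; when full, a crowding-distance density
estimate (NSGA-II convention) decides which member of the most crowded
region is evicted.  ``run_de_single`` reuses the same loop for the
single-objective baselines, with greedy selection and an elite set
maintained by worst-out tournament.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Archive",
    "AdaptiveState",
    "IterationLogger",
    "dominates",
    "nondominated_subset",
    "nondominated_mask",
    "crowding_distance",
    "archive_insert",
    "init_population",
    "sample_F",
    "sample_Cr",
    "record_success",
    "end_iteration",
    "mutate_with_archive",
    "binomial_crossover",
    "repair_bounds",
    "mo_select",
    "run_mode",
    "run_de_single",
]


@dataclass
class Individual:
    """A candidate solution: a position in [0,1]^M and its objective vector."""

    position: np.ndarray
    objectives: np.ndarray

    def copy(self) -> "Individual":
        return Individual(self.position.copy(), self.objectives.copy())


@dataclass
class Archive:
    """Bounded set of mutually nondominated individuals.

    ``last_event`` records what the most recent insertion did
    ("rejected" | "added" | "purged" | "evicted" | "duplicate"), and
    ``last_evicted`` the member removed by a capacity eviction — test
    instrumentation, not part of the optimizer contract.
    """

    capacity: int
    members: list[Individual] = field(default_factory=list)
    last_event: str = ""
    last_evicted: Individual | None = None

    def __len__(self) -> int:
        return len(self.members)

    def objective_matrix(self) -> np.ndarray:
        return np.array([m.objectives for m in self.members])


@dataclass
class AdaptiveState:
    """Self-adaptive crossover-rate state: current mean and the success pool."""

    cr_mean: float = 0.5
    success_pool: list[float] = field(default_factory=list)


def dominates(a, b) -> bool:
    """Pareto dominance (minimization): a <= b componentwise and a != b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal length")
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_mask(points: np.ndarray) -> np.ndarray:
    """Boolean mask of members not dominated by any other member.

    Pairwise O(n^2) comparison, vectorized; duplicates of a nondominated
    vector are all kept (no strict dominance between equals).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    le = np.all(pts[:, None, :] <= pts[None, :, :], axis=2)
    lt = np.any(pts[:, None, :] < pts[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    return ~dom.any(axis=0)


def nondominated_subset(points) -> list:
    """The nondominated members of a set of objective vectors."""
    pts = list(points)
    if not pts:
        raise ValueError("nondominated_subset of an empty set")
    mask = nondominated_mask(np.array([np.asarray(p, dtype=float) for p in pts]))
    return [p for p, keep in zip(pts, mask) if keep]


def crowding_distance(front) -> np.ndarray:
    """NSGA-II crowding distance for a mutually nondominated front.

    Per objective: members are sorted, the two extremes get +inf, interior
    members accumulate (next - previous) / (max - min); zero-range
    objectives contribute nothing.  Fronts of size <= 2 are all-infinite.
    """
    pts = np.asarray([np.asarray(p, dtype=float) for p in front])
    if pts.ndim == 1:
        pts = pts[:, None]
    n, k = pts.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(k):
        order = np.argsort(pts[:, j], kind="stable")
        vals = pts[order, j]
        rng = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng > 0:
            dist[order[1:-1]] += (vals[2:] - vals[:-2]) / rng
    return dist


def archive_insert(arc: Archive, s: Individual) -> bool:
    """Offer a solution to the archive; returns True iff it was accepted.

    Acceptance criteria: (1) archive empty; (2) not full and s nondominated
    by all members; (3) s dominates at least one member — those members are
    purged; (4) full and mutually nondominated with all — s is added and
    the member with the smallest crowding distance over the enlarged set is
    evicted (earliest-inserted on ties, for determinism).  A candidate
    dominated by any member is rejected, as is an exact positional
    duplicate of a member (plateau objectives would otherwise flood the
    archive with clones).
    """
    arc.last_evicted = None
    if not arc.members:
        arc.members.append(s)
        arc.last_event = "added"
        return True
    objs = arc.objective_matrix()
    sv = s.objectives
    if any(np.all(o <= sv) and np.any(o < sv) for o in objs):
        arc.last_event = "rejected"
        return False
    dominated = [i for i, o in enumerate(objs) if np.all(sv <= o) and np.any(sv < o)]
    if dominated:
        for i in reversed(dominated):
            del arc.members[i]
        arc.members.append(s)
        arc.last_event = "purged"
        return True
    if any(np.array_equal(m.position, s.position) for m in arc.members):
        arc.last_event = "duplicate"
        return False
    if len(arc.members) < arc.capacity:
        arc.members.append(s)
        arc.last_event = "added"
        return True
    # criterion 4: full, mutually nondominated — evict from the most crowded region
    arc.members.append(s)
    dist = crowding_distance([m.objectives for m in arc.members])
    worst = int(np.argmin(dist))  # argmin takes the earliest index on ties
    arc.last_evicted = arc.members.pop(worst)
    arc.last_event = "evicted"
    return arc.last_evicted is not s


def sample_F(rng: np.random.Generator) -> float:
    """Mutation scale factor ~ N(0.5, 0.3^2), truncated to (0, 2] by resampling."""
    while True:
        f = rng.normal(0.5, 0.3)
        if 0.0 < f <= 2.0:
            return float(f)


def sample_Cr(state: AdaptiveState, rng: np.random.Generator) -> float:
    """Crossover rate ~ N(cr_mean, 0.1^2), truncated to [0, 1] by resampling.

    Clipping instead of resampling puts a point mass at the boundary: once
    the success median reaches 0, half of all draws are exactly Cr=0,
    trials degenerate to single-coordinate edits, and the adaptation can
    no longer escape.  Resampling keeps the distribution continuous on
    [0, 1] while honoring the same restriction.
    """
    while True:
        v = rng.normal(state.cr_mean, 0.1)
        if 0.0 <= v <= 1.0:
            return float(v)


def record_success(state: AdaptiveState, cr: float) -> None:
    """A trial replaced its target: its Cr enters the success pool."""
    state.success_pool.append(float(cr))


def end_iteration(state: AdaptiveState) -> None:
    """Reset cr_mean to the median of the pool (unchanged if empty); empty the pool."""
    if state.success_pool:
        state.cr_mean = float(np.median(state.success_pool))
    state.success_pool.clear()


def mutate_with_archive(pop: Sequence[Individual], arc: Archive, i: int,
                        F: float, rng: np.random.Generator) -> np.ndarray:
    """Donor V = X_arc + F (X_r2 - X_r3), base drawn uniformly from the archive."""
    if not arc.members:
        raise ValueError("archive is empty; cannot draw a mutation base")
    base = arc.members[rng.integers(len(arc.members))].position
    candidates = [j for j in range(len(pop)) if j != i]
    r2, r3 = rng.choice(candidates, size=2, replace=False)
    return base + F * (pop[r2].position - pop[r3].position)


def binomial_crossover(target: np.ndarray, donor: np.ndarray, Cr: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Componentwise exchange: donor value iff r <= Cr or j == j_r."""
    m = len(target)
    if len(donor) != m:
        raise ValueError("target and donor must have equal length")
    take = rng.uniform(size=m) <= Cr
    take[rng.integers(m)] = True  # at least one donor component
    return np.where(take, donor, target)


def repair_bounds(v: np.ndarray) -> np.ndarray:
    """Clip every component to [0, 1]."""
    return np.clip(v, 0.0, 1.0)


def mo_select(target: Individual, trial: Individual,
              arc: Archive) -> tuple[Individual, bool]:
    """Pareto selection between target and trial, mediated by the archive.

    If the trial dominates the target it survives and is offered to the
    archive.  If the target dominates the trial, the target survives.  When
    the two are mutually nondominated the trial is offered to the archive
    and replaces the target exactly when the archive accepted it — this is
    what makes a "successful replacement" well-defined for Cr adaptation.
    """
    if dominates(trial.objectives, target.objectives):
        archive_insert(arc, trial)
        return trial, True
    if dominates(target.objectives, trial.objectives):
        return target, False
    accepted = archive_insert(arc, trial)
    if accepted:
        return trial, True
    return target, False


def init_population(NP: int, M: int, seed) -> list[Individual]:
    """NP individuals uniform on [0,1]^M, objectives not yet evaluated."""
    if NP < 4:
        raise ValueError("NP must be >= 4")
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [Individual(rng.uniform(size=M), np.array([])) for _ in range(NP)]


class IterationLogger:
    """Collects per-iteration archive statistics; writable as TSV.

    Columns: iteration, archive size, per-objective min and mean, mean
    subset size (when a decoder is supplied), current cr_mean.
    """

    def __init__(self, subset_size_fn: Callable[[np.ndarray], int] | None = None,
                 keep_fronts: bool = False):
        self.subset_size_fn = subset_size_fn
        self.keep_fronts = keep_fronts
        self.fronts: list[np.ndarray] = []
        self.rows: list[dict] = []

    def log(self, iteration: int, arc: Archive, state: AdaptiveState) -> None:
        objs = arc.objective_matrix()
        if self.keep_fronts:
            self.fronts.append(objs.copy())
        row = {"iteration": iteration, "archive_size": len(arc), "cr_mean": state.cr_mean}
        for j in range(objs.shape[1]):
            row[f"f{j + 1}_min"] = float(objs[:, j].min())
            row[f"f{j + 1}_mean"] = float(objs[:, j].mean())
        if self.subset_size_fn is not None:
            row["mean_subset_size"] = float(
                np.mean([self.subset_size_fn(m.position) for m in arc.members])
            )
        self.rows.append(row)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.rows).to_csv(path, sep="\t", index=False)


def run_mode(objective_fn: Callable[[np.ndarray], np.ndarray], M: int, cfg,
             logger: IterationLogger | None = None,
             rng: np.random.Generator | None = None) -> Archive:
    """Run MODE and return the final archive.

    ``cfg`` needs NP, Na, Ite and seed (a RunConfig works); an explicit
    ``rng`` overrides the seed for sub-stream control by the pipeline.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pop = init_population(cfg.NP, M, rng)
    for ind in pop:
        ind.objectives = np.asarray(objective_fn(ind.position), dtype=float)
    arc = Archive(capacity=cfg.Na)
    for ind in pop:
        archive_insert(arc, ind.copy())
    state = AdaptiveState()
    for it in range(cfg.Ite):
        for i in range(cfg.NP):
            F = sample_F(rng)
            cr = sample_Cr(state, rng)
            donor = mutate_with_archive(pop, arc, i, F, rng)
            trial_pos = repair_bounds(binomial_crossover(pop[i].position, donor, cr, rng))
            trial = Individual(trial_pos, np.asarray(objective_fn(trial_pos), dtype=float))
            survivor, replaced = mo_select(pop[i], trial, arc)
            pop[i] = survivor
            if replaced:
                record_success(state, cr)
        end_iteration(state)
        if logger is not None:
            logger.log(it, arc, state)
    return arc


def run_de_single(fitness_fn: Callable[[np.ndarray], float], M: int, cfg,
                  logger: IterationLogger | None = None,
                  rng: np.random.Generator | None = None
                  ) -> tuple[Individual, list[Individual]]:
    """Single-objective DE with an elite set in place of the Pareto archive.

    The mutation base is drawn uniformly from the elite set; selection is
    greedy (f(U) <= f(X)); every accepted trial enters the elite set, which
    evicts its worst-fitness member when over capacity Na.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pop = init_population(cfg.NP, M, rng)
    for ind in pop:
        ind.objectives = np.array([float(fitness_fn(ind.position))])
    elite: list[Individual] = []

    def elite_insert(ind: Individual) -> None:
        if any(np.array_equal(e.position, ind.position) for e in elite):
            return
        elite.append(ind.copy())
        if len(elite) > cfg.Na:
            worst = int(np.argmax([e.objectives[0] for e in elite]))
            del elite[worst]

    for ind in pop:
        elite_insert(ind)
    state = AdaptiveState()
    for it in range(cfg.Ite):
        for i in range(cfg.NP):
            F = sample_F(rng)
            cr = sample_Cr(state, rng)
            base = elite[rng.integers(len(elite))].position
            candidates = [j for j in range(cfg.NP) if j != i]
            r2, r3 = rng.choice(candidates, size=2, replace=False)
            donor = base + F * (pop[r2].position - pop[r3].position)
            trial_pos = repair_bounds(binomial_crossover(pop[i].position, donor, cr, rng))
            fit = float(fitness_fn(trial_pos))
            if fit <= pop[i].objectives[0]:
                pop[i] = Individual(trial_pos, np.array([fit]))
                elite_insert(pop[i])
                record_success(state, cr)
        end_iteration(state)
        if logger is not None:
            arc_view = Archive(capacity=cfg.Na, members=elite)
            logger.log(it, arc_view, state)
    best = min(pop, key=lambda ind: ind.objectives[0])
    elite_best = min(elite, key=lambda e: e.objectives[0])
    if elite_best.objectives[0] < best.objectives[0]:
        best = elite_best
    return best, elite
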