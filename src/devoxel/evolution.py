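"""Age-Fitness-Pareto Optimization (AFPO) over voxel robot genomes.

Each generation the population is doubled by creating one mutated copy of
every individual, every individual's age is incremented (children share
their parent's lineage age), one fresh random individual of age zero is
injected, new genomes are evaluated in the physics simulator, and Pareto
dominance on the two objectives (fitness maximized, age minimized) reduces
the pool back to the population size. The age objective plus the random
injection maintain diversity: young lineages can only be displaced by
genuinely dominating ones.

Every individual of every generation is logged (with its developmental
window statistics) so that champion lineages can be traced afterwards.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .development import DevoConfig
from .genome import (
    EVO_DEVO,
    Genome,
    GridSpec,
    MutationParams,
    mutate,
    random_genome,
)
from .physics import PhysicsConfig, PhysicsInstabilityError, fitness, simulate

__all__ = [
    "Individual",
    "EvoConfig",
    "HistoryLog",
    "SimulationEvaluator",
    "dominates",
    "select",
    "afpo_generation",
    "run_trial",
    "expected_mutation_impact",
]


@dataclass
class Individual:
    """A genome under selection, with its lineage age and evaluated fitness."""

    genome: Genome
    uid: int
    age: int = 0
    fitness: float | None = None
    parent_uid: int | None = None
    unstable: bool = False


@dataclass
class EvoConfig:
    """One evolutionary trial's settings.

    The reference scale is a population of 30 for 10,000 generations; tests
    and demonstrations run far smaller. ``fixed_rate`` inside ``mutation``
    switches off mutation-rate self-adaptation (the generality experiment);
    self-adaptation is the default.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    devo: DevoConfig = field(default_factory=DevoConfig)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    mutation: MutationParams = field(default_factory=MutationParams)
    treatment: str = EVO_DEVO
    pop_size: int = 30
    generations: int = 10_000
    record_interval: float = 0.01

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


class SimulationEvaluator:
    """Callable genome -> fitness backed by the physics simulator.

    Results are cached by genome content so re-selected survivors are never
    re-simulated. Unstable simulations score fitness 0 (evolution must be
    able to traverse degenerate genomes); the count is kept for diagnostics.
    """

    def __init__(self, cfg: EvoConfig):
        self.cfg = cfg
        self.cache: dict[bytes, float] = {}
        self.n_evaluations = 0
        self.n_unstable = 0

    def __call__(self, genome: Genome) -> float:
        key = genome.key()
        if key in self.cache:
            return self.cache[key]
        self.n_evaluations += 1
        try:
            traj = simulate(
                genome,
                self.cfg.grid,
                self.cfg.devo,
                self.cfg.physics,
                self.cfg.record_interval,
            )
            fit = fitness(traj, self.cfg.grid)
        except PhysicsInstabilityError:
            self.n_unstable += 1
            fit = 0.0
        self.cache[key] = fit
        return fit


class HistoryLog:
    """Append-only log of every individual of every generation of a trial.

    Rows carry (generation, uid, parent_uid, age, fitness, w_morph, w_ctrl);
    genomes of all logged individuals are archived in memory so lineages can
    be re-simulated.
    """

    SCHEMA = "devoxel-history-v1"
    COLUMNS = ["generation", "uid", "parent_uid", "age", "fitness", "w_morph", "w_ctrl"]

    def __init__(self) -> None:
        self.rows: list[tuple] = []
        self.genomes: dict[int, Genome] = {}

    def record(self, generation: int, pop: list[Individual]) -> None:
        for ind in pop:
            self.rows.append(
                (
                    generation,
                    ind.uid,
                    -1 if ind.parent_uid is None else ind.parent_uid,
                    ind.age,
                    ind.fitness,
                    analysis.window_morph(ind.genome),
                    analysis.window_ctrl(ind.genome),
                )
            )
            self.genomes.setdefault(ind.uid, ind.genome)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.SCHEMA}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def frame_from_csv(cls, path) -> pd.DataFrame:
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            if header != cls.SCHEMA:
                raise ValueError(f"unrecognized history schema {header!r}")
            return pd.read_csv(fh)

    def validate_links(self) -> None:
        seen_by_gen: dict[int, set] = {}
        known: set[int] = set()
        frame = self.to_dataframe()
        for gen in sorted(frame["generation"].unique()):
            sub = frame[frame["generation"] == gen]
            for parent in sub["parent_uid"]:
                if parent != -1 and parent not in known:
                    raise ValueError(f"parent uid {parent} unseen before generation {gen}")
            known.update(sub["uid"])


def dominates(i: Individual, j: Individual) -> bool:
    """Pareto dominance: at least as fit and at least as young, strictly
    better in one. Irreflexive, antisymmetric and transitive."""
    if i.fitness is None or j.fitness is None:
        raise ValueError("individuals must be evaluated before comparison")
    return (
        i.fitness >= j.fitness
        and i.age <= j.age
        and (i.fitness > j.fitness or i.age < j.age)
    )


def select(
    pool: list[Individual],
    pop_size: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Reduce the pool to pop_size by random pairwise dominance tournaments.

    Repeatedly pick two distinct members; if one dominates the other, the
    dominated one is deleted. If pop_size^2 consecutive draws produce no
    deletion (a mutually non-dominated pool larger than pop_size), a random
    member of the largest-age cohort is deleted instead -- excluding the
    current fittest individual, which therefore always survives selection.
    """
    pool = list(pool)
    stall = 0
    max_stall = pop_size * pop_size
    while len(pool) > pop_size:
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        if dominates(a, b):
            del pool[int(j)]
            stall = 0
        elif dominates(b, a):
            del pool[int(i)]
            stall = 0
        else:
            stall += 1
            if stall >= max_stall:
                best = max(range(len(pool)), key=lambda k: pool[k].fitness)
                oldest = max(
                    ind.age for k, ind in enumerate(pool) if k != best
                )
                cohort = [
                    k
                    for k, ind in enumerate(pool)
                    if ind.age == oldest and k != best
                ]
                del pool[int(rng.choice(cohort))]
                stall = 0
    return pool


def afpo_generation(
    pop: list[Individual],
    cfg: EvoConfig,
    rng: np.random.Generator,
    evaluator,
    uid_counter: itertools.count,
) -> list[Individual]:
    """One AFPO generation: double by mutation, age everyone, inject one
    random age-0 individual (pool = 2 pop_size + 1), evaluate, select."""
    children = []
    for parent in pop:
        child_genome = mutate(parent.genome, cfg.mutation, rng)
        children.append(
            Individual(
                genome=child_genome,
                uid=next(uid_counter),
                age=parent.age,
                parent_uid=parent.uid,
            )
        )
    pool = pop + children
    for ind in pool:
        ind.age += 1
    pool.append(
        Individual(genome=random_genome(cfg.grid, cfg.treatment, rng), uid=next(uid_counter))
    )
    for ind in pool:
        if ind.fitness is None:
            ind.fitness = evaluator(ind.genome)
    return select(pool, cfg.pop_size, rng)


def run_trial(
    cfg: EvoConfig,
    seed: int | np.random.Generator = 0,
    evaluator=None,
    progress: bool = False,
) -> tuple[HistoryLog, Individual]:
    """Run one evolutionary trial; returns the full history log and the run
    champion (highest-fitness individual at termination).

    ``evaluator`` may override the physics-backed fitness function (any
    callable genome -> float), e.g. for cheap surrogate landscapes in tests.
    Deterministic given (cfg, seed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    evaluator = evaluator if evaluator is not None else SimulationEvaluator(cfg)
    uid_counter = itertools.count()

    pop = [
        Individual(genome=random_genome(cfg.grid, cfg.treatment, rng), uid=next(uid_counter))
        for _ in range(cfg.pop_size)
    ]
    for ind in pop:
        ind.fitness = evaluator(ind.genome)

    log = HistoryLog()
    log.record(0, pop)
    gens = range(1, cfg.generations + 1)
    if progress:
        try:
            from tqdm import tqdm

            gens = tqdm(gens, desc="generations")
        except ImportError:
            pass
    for g in gens:
        pop = afpo_generation(pop, cfg, rng, evaluator, uid_counter)
        log.record(g, pop)

    champion = max(pop, key=lambda ind: ind.fitness)
    return log, champion


def expected_mutation_impact(
    rate: float,
    treatment: str = EVO_DEVO,
    grid: GridSpec | None = None,
    type_prob: float = 0.5,
) -> float:
    """Expected fraction of genome parameters modified by one mutation.

    Closed form for the implemented two-stage scheme with a uniform per-site
    rate: each applicable parameter type is selected independently with
    probability ``type_prob`` (conditioned on at least one type selected),
    each site of a selected type mutates with probability ``rate``, and the
    whole draw is conditioned on at least one site changing. Morphology
    types have ceil(nx/2) ny nz independent sites; controller types nx ny nz.
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must lie in (0, 1]")
    grid = grid or GridSpec()
    n_morph = grid.n_left
    n_ctrl = grid.n_voxels
    if treatment == EVO_DEVO:
        site_counts = [n_ctrl, n_ctrl, n_morph, n_morph]
    else:
        site_counts = [n_ctrl, n_morph]
    T = len(site_counts)
    p = type_prob
    none_type = (1.0 - p) ** T
    p_sel = p / (1.0 - none_type)  # per-type selection prob given >=1 selected
    e_n = sum(p_sel * n_t * rate for n_t in site_counts)
    # P(no site changes | >=1 type selected)
    prod = math.prod((1.0 - p) + p * (1.0 - rate) ** n_t for n_t in site_counts)
    p_zero = (prod - none_type) / (1.0 - none_type)
    total = sum(site_counts)
    return e_n / (1.0 - p_zero) / total
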