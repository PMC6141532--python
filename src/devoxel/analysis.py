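"""Measurement battery: developmental windows, lineage canalization,
mutation-robustness random walks, rollover-onset heterochrony, and the
rank-based hypothesis test used to compare treatments.

The central statistic is the *developmental window*: the total lifetime
change of a subsystem's parameters, normalized by the maximum possible
change so that 0 means a static (canalized) subsystem and 1 maximal
development. A lineage whose morphological window rises and then collapses
toward zero while fitness rises has canalized its morphology -- the
signature of differential canalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .development import DevoConfig
from .genome import ELL_MAX, ELL_MIN, PHI_MAX, PHI_MIN, Genome, MutationParams, mutate
from .physics import PhysicsConfig, detect_rollover, simulate

__all__ = [
    "LineageRecord",
    "WalkResult",
    "window_morph",
    "window_ctrl",
    "trace_lineage",
    "robustness_walk",
    "rollover_onset_series",
    "mann_whitney_u",
    "canalization_summary",
]

# subsystem -> parameter types a robustness walk may perturb
_WALK_TYPES = {
    "control": ("phi_start", "phi_final"),
    "morphology": ("ell_start", "ell_final"),
}


def window_morph(genome: Genome) -> float:
    """Morphological developmental window W_L in [0, 1].

    Sum of |final - start| resting lengths over all (mirror-expanded) voxels
    divided by the maximum possible total change, n_voxels * 1.5 cm.
    """
    g = genome.grid
    total = float(np.sum(np.abs(genome.ell_final - genome.ell_start)))
    return total / (g.n_voxels * (ELL_MAX - ELL_MIN))


def window_ctrl(genome: Genome) -> float:
    """Controller developmental window W_Phi in [0, 1].

    Sum of |final - start| phase offsets over all voxels divided by the
    maximum possible total change, n_voxels * pi.
    """
    g = genome.grid
    total = float(np.sum(np.abs(genome.phi_final - genome.phi_start)))
    return total / (g.n_voxels * (PHI_MAX - PHI_MIN))


@dataclass
class LineageRecord:
    """Ancestor chain of a run champion, oldest ancestor first.

    Parallel arrays over the chain: uid, the generation each ancestor was
    first logged, fitness F, and the two windows; ``genomes`` archives the
    ancestors for re-simulation (rollover onset, development removal).
    """

    uids: np.ndarray
    generations: np.ndarray
    fitness: np.ndarray
    w_morph: np.ndarray
    w_ctrl: np.ndarray
    genomes: list[Genome]

    def __len__(self) -> int:
        return len(self.uids)

    @property
    def champion_genome(self) -> Genome:
        return self.genomes[-1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "uid": self.uids,
                "generation": self.generations,
                "fitness": self.fitness,
                "w_morph": self.w_morph,
                "w_ctrl": self.w_ctrl,
            }
        )


def trace_lineage(log, champion) -> LineageRecord:
    """Follow parent links from the run champion back to its founding
    ancestor (a generation-0 or injected individual).

    ``log`` is a :class:`devoxel.evolution.HistoryLog`; ``champion`` an
    Individual or uid present in it.
    """
    frame = log.to_dataframe()
    by_uid = {}
    for row in frame.itertuples(index=False):
        if row.uid not in by_uid:  # first appearance fixes generation of origin
            by_uid[row.uid] = row
    uid = champion if isinstance(champion, (int, np.integer)) else champion.uid
    if uid not in by_uid:
        raise ValueError(f"champion uid {uid} not present in history log")
    chain = []
    while uid != -1:
        if uid not in by_uid:
            raise ValueError(f"broken parent link: uid {uid} missing from log")
        row = by_uid[uid]
        chain.append(row)
        uid = row.parent_uid
    chain.reverse()
    return LineageRecord(
        uids=np.array([r.uid for r in chain]),
        generations=np.array([r.generation for r in chain]),
        fitness=np.array([r.fitness for r in chain], dtype=float),
        w_morph=np.array([r.w_morph for r in chain], dtype=float),
        w_ctrl=np.array([r.w_ctrl for r in chain], dtype=float),
        genomes=[log.genomes[r.uid] for r in chain],
    )


@dataclass
class WalkResult:
    """Fitness along cumulative random mutation walks from one champion.

    ``fitness`` has shape (n_walks, n_steps + 1); column 0 is the unmutated
    champion's fitness. ``kind`` records the perturbed subsystem.
    """

    kind: str
    fitness: np.ndarray
    seeds: list[int]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for w in range(self.fitness.shape[0]):
            frames.append(
                pd.DataFrame(
                    {
                        "walk": w,
                        "step": np.arange(self.fitness.shape[1]),
                        "fitness": self.fitness[w],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def robustness_walk(
    champion_genome: Genome,
    kind: str,
    evaluator,
    mutation: MutationParams | None = None,
    n_steps: int = 1000,
    n_walks: int = 10,
    rng: np.random.Generator | int | None = None,
) -> WalkResult:
    """Brownian trajectories in one subsystem's parameter space.

    Each walk applies ``n_steps`` successive random mutations restricted to
    the chosen subsystem ('control': phase offsets only; 'morphology':
    resting lengths only), re-evaluating fitness after every step; each step
    builds on the previous genome. Per-voxel mutation rates are frozen
    during walks so the walk probes the phenotype, not the rate landscape.
    """
    if kind not in _WALK_TYPES:
        raise ValueError(f"kind must be one of {sorted(_WALK_TYPES)}")
    mutation = mutation or MutationParams()
    master = np.random.default_rng(rng)
    seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_walks)]
    fits = np.empty((n_walks, n_steps + 1))
    base = evaluator(champion_genome)
    for w, s in enumerate(seeds):
        walk_rng = np.random.default_rng(s)
        g = champion_genome
        fits[w, 0] = base
        for i in range(1, n_steps + 1):
            g = mutate(
                g,
                mutation,
                walk_rng,
                allowed_types=_WALK_TYPES[kind],
                adapt_rates=False,
            )
            fits[w, i] = evaluator(g)
    return WalkResult(kind=kind, fitness=fits, seeds=seeds)


def rollover_onset_series(
    lineage: LineageRecord,
    devo_cfg: DevoConfig | None = None,
    phys_cfg: PhysicsConfig | None = None,
    record_interval: float = 0.01,
    contact_eps: float | None = None,
) -> list[float | None]:
    """Re-simulate every ancestor and report when (if ever) it first rolls.

    Rollover is the first sample at which any initially-top-layer particle
    touches the ground. A decreasing onset series along the lineage is the
    signature of progenesis: descendants roll earlier in life.
    """
    devo_cfg = devo_cfg or DevoConfig()
    phys_cfg = phys_cfg or PhysicsConfig()
    eps = contact_eps if contact_eps is not None else phys_cfg.contact_eps
    onsets: list[float | None] = []
    for g in lineage.genomes:
        traj = simulate(g, g.grid, devo_cfg, phys_cfg, record_interval)
        onsets.append(detect_rollover(traj, eps))
    return onsets


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided; returns (U of sample_a, p-value).

    For small samples (both n <= 8) the p-value is exact, computed by
    enumerating all assignments of the pooled observations to the two
    groups (which handles ties without approximation); otherwise the
    tie-corrected normal approximation with continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    from scipy.stats import mannwhitneyu, rankdata

    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)

    if n1 <= 8 and n2 <= 8:
        mid = n1 * n2 / 2.0
        obs_dev = abs(u1 - mid)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for comb in combinations(idx, n1):
            u = float(np.sum(ranks[list(comb)]) - n1 * (n1 + 1) / 2)
            total += 1
            if abs(u - mid) >= obs_dev - 1e-12:
                count += 1
        return u1, count / total
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def canalization_summary(lineages: list[LineageRecord]) -> pd.DataFrame:
    """Per-lineage window statistics ready for rank-based testing.

    For each champion lineage: the starting (most distant ancestor), maximum
    and final (champion) developmental window of each subsystem, plus the
    champion's fitness. The contrasts of interest are start vs max of the
    morphological window (plasticity first rises) and final vs start
    (then collapses: canalization), with the controller window as the
    non-canalized comparison.
    """
    if not lineages:
        raise ValueError("need at least one lineage")
    rows = []
    for i, lin in enumerate(lineages):
        rows.append(
            {
                "trial": i,
                "w_morph_start": lin.w_morph[0],
                "w_morph_max": lin.w_morph.max(),
                "w_morph_final": lin.w_morph[-1],
                "w_ctrl_start": lin.w_ctrl[0],
                "w_ctrl_max": lin.w_ctrl.max(),
                "w_ctrl_final": lin.w_ctrl[-1],
                "fitness_final": lin.fitness[-1],
            }
        )
    return pd.DataFrame(rows)
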