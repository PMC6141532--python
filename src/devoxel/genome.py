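"""Genomes for soft voxel robots with ballistic development.

A robot is a cartesian grid of voxels. Its morphology is the per-voxel
resting length (cm) and its controller the per-voxel phase offset (radians)
from a global sinusoidal drive. Under the ``EvoDevo`` treatment every
parameter has a start value and a final value and develops linearly between
them over the lifetime; under the ``Evo`` treatment final values are
constrained equal to start values, i.e. the phenotype is static.

Morphologies are bilaterally symmetric about the midsagittal plane normal to
the x axis: only the lefthand half of the resting lengths is free, the
righthand half is its mirror image. Controllers are unconstrained (asymmetric
gaits are common even on symmetric bodies).

Each voxel also carries its own mutation probability, which is itself
slightly perturbed every time a genome is copied (self-adaptation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ELL_MIN",
    "ELL_MAX",
    "PHI_MIN",
    "PHI_MAX",
    "EVO",
    "EVO_DEVO",
    "GridSpec",
    "MutationParams",
    "Genome",
    "expand_symmetry",
    "extract_left",
    "random_genome",
    "mutate",
    "remove_development",
    "degrees_of_freedom",
]

# Hard parameter bounds: resting lengths within 1.0 +/- 0.75 cm, phase
# offsets within 0 +/- pi/2 rad.
ELL_MIN = 0.25
ELL_MAX = 1.75
PHI_MIN = -math.pi / 2
PHI_MAX = math.pi / 2

EVO = "Evo"
EVO_DEVO = "EvoDevo"
_TREATMENTS = (EVO, EVO_DEVO)

# Parameter types a mutation may touch. Morphology types act on the
# independent (lefthand) sites only; controller types act on every voxel.
MORPH_TYPES = ("ell_start", "ell_final")
CTRL_TYPES = ("phi_start", "phi_final")
ALL_TYPES = ("phi_start", "phi_final", "ell_start", "ell_final")


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry.

    x is the left-right (mirror) axis, y the travel axis, z vertical.
    The reference configuration is 4 x 4 x 3 = 48 voxels of edge 1 cm,
    giving an undeformed body length of 4 cm along the travel axis.
    """

    nx: int = 4
    ny: int = 4
    nz: int = 3
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("all voxel counts must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def n_left(self) -> int:
        """Number of independent morphology sites (lefthand half; the center
        column maps to itself when nx is odd)."""
        return ((self.nx + 1) // 2) * self.ny * self.nz

    @property
    def half_nx(self) -> int:
        return (self.nx + 1) // 2

    @property
    def body_length(self) -> float:
        """Undeformed body length along the travel axis (4 cm at reference)."""
        return self.ny * self.voxel_size

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def left_shape(self) -> tuple[int, int, int]:
        return (self.half_nx, self.ny, self.nz)


@dataclass(frozen=True)
class MutationParams:
    """Mutation operator settings.

    sigma_ell / sigma_phi are the Gaussian perturbation scales for resting
    lengths (cm) and phase offsets (rad). meta_step is the log-normal step of
    per-voxel mutation-rate self-adaptation applied on every copy. fixed_rate,
    when set, disables self-adaptation and uses one rate for every voxel.
    type_prob is the probability with which each applicable parameter type is
    selected for mutation (redrawn until at least one type is selected).
    """

    sigma_ell: float = 0.75
    sigma_phi: float = math.pi / 2
    meta_step: float = 0.1
    fixed_rate: float | None = None
    type_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_ell <= 0 or self.sigma_phi <= 0:
            raise ValueError("perturbation scales must be positive")
        if self.fixed_rate is not None and not (0.0 < self.fixed_rate <= 1.0):
            raise ValueError("fixed_rate must be in (0, 1]")
        if not (0.0 < self.type_prob <= 1.0):
            raise ValueError("type_prob must be in (0, 1]")


def expand_symmetry(left_values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Mirror lefthand morphology values across the midsagittal plane.

    left_values holds the independent sites, shape (ceil(nx/2), ny, nz) or
    flat with that many entries. Returns the full (nx, ny, nz) field with
    value(x, y, z) == value(nx-1-x, y, z).
    """
    left = np.asarray(left_values, dtype=float)
    if left.size != grid.n_left:
        raise ValueError(
            f"expected {grid.n_left} lefthand values, got {left.size}"
        )
    left = left.reshape(grid.left_shape)
    full = np.empty(grid.shape, dtype=float)
    h = grid.half_nx
    full[:h] = left
    full[h:] = left[grid.nx - 1 - np.arange(h, grid.nx)]
    return full


def extract_left(full_values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Inverse of :func:`expand_symmetry` (keeps the lefthand half)."""
    full = np.asarray(full_values, dtype=float)
    if full.size != grid.n_voxels:
        raise ValueError(f"expected {grid.n_voxels} values, got {full.size}")
    return full.reshape(grid.shape)[: grid.half_nx].copy()


@dataclass
class Genome:
    """Heritable specification of one robot.

    Morphology arrays store only the independent lefthand sites, shape
    ``grid.left_shape``; controller and rate arrays cover every voxel,
    shape ``grid.shape``. All arrays are float64.
    """

    grid: GridSpec
    ell_start_left: np.ndarray
    ell_final_left: np.ndarray
    phi_start: np.ndarray
    phi_final: np.ndarray
    rates: np.ndarray
    treatment: str = EVO_DEVO

    def __post_init__(self) -> None:
        self.ell_start_left = np.asarray(self.ell_start_left, dtype=float).reshape(
            self.grid.left_shape
        )
        self.ell_final_left = np.asarray(self.ell_final_left, dtype=float).reshape(
            self.grid.left_shape
        )
        self.phi_start = np.asarray(self.phi_start, dtype=float).reshape(self.grid.shape)
        self.phi_final = np.asarray(self.phi_final, dtype=float).reshape(self.grid.shape)
        self.rates = np.asarray(self.rates, dtype=float).reshape(self.grid.shape)
        self.validate()

    # -- expanded (full grid) morphology ------------------------------------
    @property
    def ell_start(self) -> np.ndarray:
        return expand_symmetry(self.ell_start_left, self.grid)

    @property
    def ell_final(self) -> np.ndarray:
        return expand_symmetry(self.ell_final_left, self.grid)

    def validate(self) -> None:
        if self.treatment not in _TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        for name, arr, lo, hi in (
            ("ell_start", self.ell_start_left, ELL_MIN, ELL_MAX),
            ("ell_final", self.ell_final_left, ELL_MIN, ELL_MAX),
            ("phi_start", self.phi_start, PHI_MIN, PHI_MAX),
            ("phi_final", self.phi_final, PHI_MIN, PHI_MAX),
        ):
            if np.any(arr < lo) or np.any(arr > hi):
                raise ValueError(f"{name} outside [{lo}, {hi}]")
        if np.any(self.rates <= 0.0) or np.any(self.rates > 1.0):
            raise ValueError("mutation rates must lie in (0, 1]")
        if self.treatment == EVO:
            if not (
                np.array_equal(self.ell_start_left, self.ell_final_left)
                and np.array_equal(self.phi_start, self.phi_final)
            ):
                raise ValueError("Evo treatment requires final == start")

    def copy(self) -> "Genome":
        return Genome(
            grid=self.grid,
            ell_start_left=self.ell_start_left.copy(),
            ell_final_left=self.ell_final_left.copy(),
            phi_start=self.phi_start.copy(),
            phi_final=self.phi_final.copy(),
            rates=self.rates.copy(),
            treatment=self.treatment,
        )

    def key(self) -> bytes:
        """Hashable content key (used for evaluation caching)."""
        return b"".join(
            (
                self.treatment.encode(),
                self.ell_start_left.tobytes(),
                self.ell_final_left.tobytes(),
                self.phi_start.tobytes(),
                self.phi_final.tobytes(),
            )
        )

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "devoxel-genome-v1",
            "grid": {
                "nx": self.grid.nx,
                "ny": self.grid.ny,
                "nz": self.grid.nz,
                "voxel_size": self.grid.voxel_size,
            },
            "treatment": self.treatment,
            "ell_start_left": self.ell_start_left.ravel().tolist(),
            "ell_final_left": self.ell_final_left.ravel().tolist(),
            "phi_start": self.phi_start.ravel().tolist(),
            "phi_final": self.phi_final.ravel().tolist(),
            "rates": self.rates.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        grid = GridSpec(**d["grid"])
        return cls(
            grid=grid,
            ell_start_left=np.array(d["ell_start_left"]),
            ell_final_left=np.array(d["ell_final_left"]),
            phi_start=np.array(d["phi_start"]),
            phi_final=np.array(d["phi_final"]),
            rates=np.array(d["rates"]),
            treatment=d["treatment"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Genome":
        return cls.from_dict(json.loads(s))


def degrees_of_freedom(genome: Genome) -> dict[str, int]:
    """Free-parameter accounting: {'morphology': m, 'control': c}.

    Evo at the 4x4x3 reference: 24 morphological + 48 control parameters.
    EvoDevo doubles both: 48 morphological + 96 control.
    """
    g = genome.grid
    factor = 2 if genome.treatment == EVO_DEVO else 1
    return {
        "morphology": factor * g.n_left,
        "control": factor * g.n_voxels,
    }


def random_genome(
    grid: GridSpec,
    treatment: str = EVO_DEVO,
    rng: np.random.Generator | int | None = None,
) -> Genome:
    """Draw a genome uniformly within the legal parameter bounds.

    Per-voxel mutation rates initialize to 1/n_voxels so a single voxel is
    mutated on average. Evo genomes get final == start.
    """
    rng = np.random.default_rng(rng)
    ell_s = rng.uniform(ELL_MIN, ELL_MAX, size=grid.left_shape)
    phi_s = rng.uniform(PHI_MIN, PHI_MAX, size=grid.shape)
    if treatment == EVO_DEVO:
        ell_f = rng.uniform(ELL_MIN, ELL_MAX, size=grid.left_shape)
        phi_f = rng.uniform(PHI_MIN, PHI_MAX, size=grid.shape)
    else:
        ell_f = ell_s.copy()
        phi_f = phi_s.copy()
    rates = np.full(grid.shape, 1.0 / grid.n_voxels)
    return Genome(
        grid=grid,
        ell_start_left=ell_s,
        ell_final_left=ell_f,
        phi_start=phi_s,
        phi_final=phi_f,
        rates=rates,
        treatment=treatment,
    )


def _applicable_types(treatment: str) -> tuple[str, ...]:
    if treatment == EVO_DEVO:
        return ALL_TYPES
    return ("phi_start", "ell_start")


def _site_rates(genome: Genome, ptype: str) -> np.ndarray:
    """Per-site mutation probabilities for one parameter type."""
    if ptype in MORPH_TYPES:
        # morphology sites are the independent lefthand voxels
        return genome.rates[: genome.grid.half_nx]
    return genome.rates


_MAX_REDRAWS = 25


def mutate(
    genome: Genome,
    params: MutationParams,
    rng: np.random.Generator | int | None = None,
    allowed_types: tuple[str, ...] | None = None,
    adapt_rates: bool = True,
) -> Genome:
    """Produce a mutated copy of ``genome``.

    Two-stage draw: first select which parameter types to mutate (each
    applicable type independently with probability ``params.type_prob``,
    redrawn until at least one is selected), then for each selected type an
    independent per-site Bernoulli with that voxel's mutation rate decides
    which sites are perturbed. Perturbations are Gaussian (sigma_ell /
    sigma_phi) and clipped to the legal bounds. The whole draw is resampled
    if it would leave the child identical to the parent; after a bounded
    number of redraws one site is forced to change.

    Per-voxel rates are multiplied by exp(N(0,1) * meta_step) on every copy
    (clipped to [1/(10 n_voxels), 1]) unless ``params.fixed_rate`` is set, in
    which case every voxel uses the fixed rate and no adaptation occurs.

    ``allowed_types`` restricts the mutable parameter types (used by the
    mutation-robustness random walks to isolate one subsystem);
    ``adapt_rates=False`` freezes the rates on copy.
    """
    rng = np.random.default_rng(rng)
    child = genome.copy()

    n = genome.grid.n_voxels
    if params.fixed_rate is not None:
        child.rates = np.full(genome.grid.shape, params.fixed_rate)
    elif adapt_rates:
        child.rates = np.clip(
            child.rates * np.exp(rng.standard_normal(genome.grid.shape) * params.meta_step),
            1.0 / (10.0 * n),
            1.0,
        )

    types = _applicable_types(genome.treatment)
    if allowed_types is not None:
        types = tuple(t for t in types if t in allowed_types)
        if not types:
            raise ValueError("no applicable parameter types to mutate")

    arrays = {
        "ell_start": (child.ell_start_left, ELL_MIN, ELL_MAX, params.sigma_ell),
        "ell_final": (child.ell_final_left, ELL_MIN, ELL_MAX, params.sigma_ell),
        "phi_start": (child.phi_start, PHI_MIN, PHI_MAX, params.sigma_phi),
        "phi_final": (child.phi_final, PHI_MIN, PHI_MAX, params.sigma_phi),
    }
    parents = {
        "ell_start": genome.ell_start_left,
        "ell_final": genome.ell_final_left,
        "phi_start": genome.phi_start,
        "phi_final": genome.phi_final,
    }

    def attempt() -> bool:
        """One full mutation draw; returns True if the child changed."""
        # stage 1: parameter types, redrawn until at least one selected
        while True:
            selected = [t for t in types if rng.random() < params.type_prob]
            if selected:
                break
        changed = False
        for t in selected:
            arr, lo, hi, sigma = arrays[t]
            lam = params.fixed_rate if params.fixed_rate is not None else None
            site_rates = (
                np.full(arr.shape, lam) if lam is not None else _site_rates(child, t)
            )
            mask = rng.random(arr.shape) < site_rates
            if not mask.any():
                continue
            perturbed = np.clip(arr + rng.normal(0.0, sigma, size=arr.shape) * mask, lo, hi)
            arr[...] = np.where(mask, perturbed, arr)
            if not np.array_equal(arr, parents[t]):
                changed = True
        return changed

    changed = False
    for _ in range(_MAX_REDRAWS):
        # reset the mutable arrays to the parent's values before each redraw
        child.ell_start_left[...] = genome.ell_start_left
        child.ell_final_left[...] = genome.ell_final_left
        child.phi_start[...] = genome.phi_start
        child.phi_final[...] = genome.phi_final
        if attempt():
            changed = True
            break
    if not changed:
        # force exactly one site of one allowed type to move off its value
        t = types[int(rng.integers(len(types)))]
        arr, lo, hi, sigma = arrays[t]
        flat = arr.reshape(-1)
        k = int(rng.integers(flat.size))
        while True:
            v = float(np.clip(flat[k] + rng.normal(0.0, sigma), lo, hi))
            if v != flat[k]:
                flat[k] = v
                break

    if genome.treatment == EVO:
        child.ell_final_left = child.ell_start_left.copy()
        child.phi_final = child.phi_start.copy()
    child.validate()
    return child


def remove_development(genome: Genome) -> Genome:
    """Freeze the phenotype at birth: set final values equal to start values.

    Idempotent; the result has zero developmental window in both morphology
    and control while leaving the t=0 phenotype untouched. The treatment tag
    is preserved so removed robots remain distinguishable from Evo robots.
    """
    out = genome.copy()
    out.ell_final_left = out.ell_start_left.copy()
    out.phi_final = out.phi_start.copy()
    return out
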