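"""Deterministic genome fixtures with known qualitative behavior.

These are small hand-constructed robots used throughout the test suite and
the documentation: a motionless control, a two-particle harmonic oscillator
for the physics oracle, a phase-gradient "shuffler" that locomotes, and a
maximally developing body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import ELL_MAX, ELL_MIN, EVO, EVO_DEVO, Genome, GridSpec

__all__ = ["FixtureSpec", "FIXTURES", "make_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """A named deterministic genome recipe with its expected behavior tag."""

    name: str
    grid: GridSpec
    tag: str  # static | oscillate | shuffle | roll


FIXTURES = {
    "static": FixtureSpec("static", GridSpec(), "static"),
    "oscillator": FixtureSpec("oscillator", GridSpec(nx=2, ny=1, nz=1), "oscillate"),
    "shuffler": FixtureSpec("shuffler", GridSpec(), "shuffle"),
    "devo-max": FixtureSpec("devo-max", GridSpec(), "roll"),
}


def _uniform(grid: GridSpec, ell: float, phi: float, treatment: str = EVO) -> Genome:
    return Genome(
        grid=grid,
        ell_start_left=np.full(grid.left_shape, ell),
        ell_final_left=np.full(grid.left_shape, ell),
        phi_start=np.full(grid.shape, phi),
        phi_final=np.full(grid.shape, phi),
        rates=np.full(grid.shape, 1.0 / grid.n_voxels),
        treatment=treatment,
    )


def make_fixture(name: str, grid: GridSpec | None = None) -> tuple[Genome, GridSpec]:
    """Build a named fixture genome; ``grid`` overrides the default grid
    (the oscillator's 2x1x1 grid is fixed)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    spec = FIXTURES[name]
    grid = spec.grid if (grid is None or name == "oscillator") else grid

    if name == "static":
        g = _uniform(grid, 1.0, 0.0)
    elif name == "oscillator":
        g = _uniform(grid, 1.0, 0.0)
    elif name == "shuffler":
        # traveling-wave phase gradient along the travel (y) axis breaks
        # fore-aft symmetry and produces net displacement
        g = _uniform(grid, 1.0, 0.0)
        phase = np.linspace(-math.pi / 2, math.pi / 2, grid.ny)
        g.phi_start[...] = phase[None, :, None]
        g.phi_final = g.phi_start.copy()
    elif name == "devo-max":
        g = _uniform(grid, ELL_MIN, 0.0, treatment=EVO_DEVO)
        g.ell_final_left = np.full(grid.left_shape, ELL_MAX)
    g.validate()
    return g, grid
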