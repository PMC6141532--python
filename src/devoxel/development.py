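"""Ballistic development and actuation: the genotype-to-phenotype(t) map.

Every developing parameter changes linearly from its start value ``a`` to
its final value ``b`` over the lifetime ``tau``; development is open-loop
("ballistic"): predetermined, monotone, irreversible, and unaffected by the
environment. On top of the slowly developing resting length, each voxel
oscillates with a global sinusoidal drive (frequency f, amplitude A) shifted
by its own developing phase offset. Small voxels have their actuation
linearly damped to zero as the resting length approaches its lower bound,
which keeps the simulation stable.

All functions are pure and accept scalars or numpy arrays; time is
continuous and discretization is left to the physics integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import Genome

__all__ = [
    "DevoConfig",
    "ballistic",
    "damping_factor",
    "resting_length",
    "phase_offset",
    "actuation",
    "current_length",
]


@dataclass(frozen=True)
class DevoConfig:
    """Lifetime and actuation constants.

    amplitude A in cm (0.14), freq f in Hz (4), n_cycles actuation cycles per
    lifetime (40); the lifetime is tau = n_cycles / freq = 10 s by default.
    """

    amplitude: float = 0.14
    freq: float = 4.0
    n_cycles: float = 40.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.freq <= 0 or self.n_cycles <= 0:
            raise ValueError("freq and n_cycles must be positive")

    @property
    def tau(self) -> float:
        """Lifetime in seconds."""
        return self.n_cycles / self.freq


def _check_t(t, tau: float) -> None:
    t = np.asarray(t)
    if np.any(t < 0) or np.any(t > tau):
        raise ValueError(f"ontogenetic time must lie in [0, {tau}]")


def ballistic(a, b, t, tau: float):
    """Linear development from a (at t=0) to b (at t=tau): a + t (b - a)/tau.

    Degenerates to the constant a when a == b (the static, non-developing
    case), exactly in floating point.
    """
    _check_t(t, tau)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a + np.multiply(t, (b - a)) / tau


def damping_factor(x):
    """Actuation damping xi(x) = min{1, (4x - 1)/3} for resting length x.

    Equals 1 for x >= 1 cm (no damping) and falls linearly to 0 at the lower
    resting-length bound of 0.25 cm (no actuation).
    """
    return np.minimum(1.0, (4.0 * np.asarray(x, dtype=float) - 1.0) / 3.0)


def resting_length(genome: Genome, t, cfg: DevoConfig) -> np.ndarray:
    """Developing resting length of every voxel at time t, full (nx,ny,nz) grid."""
    return ballistic(genome.ell_start, genome.ell_final, t, cfg.tau)


def phase_offset(genome: Genome, t, cfg: DevoConfig) -> np.ndarray:
    """Developing phase offset of every voxel at time t."""
    return ballistic(genome.phi_start, genome.phi_final, t, cfg.tau)


def actuation(genome: Genome, t, cfg: DevoConfig) -> np.ndarray:
    """Voxel actuation displacement psi(t) in cm, full grid.

    psi_k(t) = A sin(2 pi f t + phase_k(t)) * xi(resting_length_k(t)),
    so |psi_k| <= A everywhere and small voxels actuate less.
    """
    rl = resting_length(genome, t, cfg)
    ph = phase_offset(genome, t, cfg)
    return cfg.amplitude * np.sin(2.0 * math.pi * cfg.freq * t + ph) * damping_factor(rl)


def current_length(genome: Genome, t, cfg: DevoConfig) -> np.ndarray:
    """Instantaneous voxel length L_k(t) = resting length + damped actuation."""
    rl = resting_length(genome, t, cfg)
    ph = phase_offset(genome, t, cfg)
    return rl + cfg.amplitude * np.sin(2.0 * math.pi * cfg.freq * t + ph) * damping_factor(rl)


def current_length_series(genome: Genome, times: np.ndarray, cfg: DevoConfig) -> np.ndarray:
    """Vectorized L_k(t) for a whole time grid.

    Returns shape (len(times), n_voxels) with voxels flattened in C order;
    used by the physics integrator to precompute per-step resting lengths.
    """
    times = np.asarray(times, dtype=float)
    _check_t(times, cfg.tau)
    frac = (times / cfg.tau)[:, None]
    ell_s = genome.ell_start.ravel()[None, :]
    ell_f = genome.ell_final.ravel()[None, :]
    phi_s = genome.phi_start.ravel()[None, :]
    phi_f = genome.phi_final.ravel()[None, :]
    rl = ell_s + frac * (ell_f - ell_s)
    ph = phi_s + frac * (phi_f - phi_s)
    psi = cfg.amplitude * np.sin(2.0 * math.pi * cfg.freq * times[:, None] + ph)
    return rl + psi * np.minimum(1.0, (4.0 * rl - 1.0) / 3.0)
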