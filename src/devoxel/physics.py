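"""Minimal mass-spring voxel soft-body simulator.

Each voxel contributes one point mass (particle) on a cartesian grid,
connected to its (up to six) axis-adjacent neighbors by spring-like beams.
Per-beam resting lengths are the average of the two incident voxels'
instantaneous lengths and are refreshed every step, so both slow
development and fast actuation drive the body. Rotational beam stiffness is
approximated by straightening springs spanning each collinear beam pair
(second-neighbor springs), which resist bending and buckling at a fraction
of the complexity of full beam elements.

Environment: uniform gravity, a flat ground plane at z = 0 modelled as a
one-sided penalty spring with viscous normal damping, and regularized
kinetic Coulomb friction capped by mu |N|. Integration is semi-implicit
(symplectic) Euler, the standard stable choice for stiff mass-spring
systems; the hot loop is JIT-compiled with numba.

Units: cm, grams, seconds (gravity 981 cm/s^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .development import DevoConfig, current_length_series
from .genome import Genome, GridSpec

__all__ = [
    "PhysicsConfig",
    "LatticeState",
    "Trajectory",
    "PhysicsInstabilityError",
    "build_lattice",
    "step",
    "simulate",
    "fitness",
    "detect_rollover",
    "mechanical_energy",
]


class PhysicsInstabilityError(RuntimeError):
    """Raised when the integration diverges (non-finite or runaway positions)."""


@dataclass(frozen=True)
class PhysicsConfig:
    """Material and contact constants (none are printed for the original
    engine, so these are this package's own calibration).

    dt: timestep (s). spring_k: translational beam stiffness (g/s^2).
    bend_k: stiffness of the straightening (second-neighbor) springs that
    stand in for rotational beam stiffness. damping_c: per-particle velocity
    damping (g/s). gravity (cm/s^2). ground_k / ground_c: contact penalty
    stiffness and normal viscous damping. mu: Coulomb friction coefficient.
    contact_eps: contact distance threshold (cm) used by rollover detection.
    slide_eps: regularization velocity (cm/s) for the friction direction.
    """

    dt: float = 1e-4
    spring_k: float = 4.0e4
    bend_k: float = 2.0e4
    damping_c: float = 20.0
    gravity: float = 981.0
    ground_k: float = 2.0e5
    ground_c: float = 50.0
    mu: float = 1.0
    contact_eps: float = 0.05
    slide_eps: float = 0.1
    particle_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("spring_k", "bend_k", "ground_k", "ground_c", "damping_c", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        k_max = max(self.spring_k, self.bend_k, self.ground_k, 1e-12)
        dt_max = 0.1 * math.sqrt(self.particle_mass / k_max)
        if self.dt > dt_max * (1 + 1e-9):
            raise ValueError(
                f"dt={self.dt:g} unstable for stiffness {k_max:g} "
                f"(require dt <= 0.1 sqrt(m/k) = {dt_max:g})"
            )

    @staticmethod
    def toy() -> "PhysicsConfig":
        """Softer, coarser constants for small demonstration grids."""
        return PhysicsConfig(
            dt=3e-4,
            spring_k=2.0e4,
            bend_k=1.0e4,
            damping_c=15.0,
            ground_k=1.0e5,
            ground_c=40.0,
        )


def _topology(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Beam and straightening-spring index arrays for a full cartesian grid.

    Particle index of voxel (x, y, z) is its C-order flat index. Beams is
    (B, 2); bends is (Bb, 3) storing (end, middle, end) along each axis.
    """
    nx, ny, nz = grid.shape
    idx = np.arange(grid.n_voxels).reshape(grid.shape)
    beams = []
    bends = []
    for axis, n in ((0, nx), (1, ny), (2, nz)):
        sl = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        if n >= 2:
            sl[axis] = slice(0, n - 1)
            sl2[axis] = slice(1, n)
            beams.append(
                np.stack([idx[tuple(sl)].ravel(), idx[tuple(sl2)].ravel()], axis=1)
            )
        if n >= 3:
            a = [slice(None)] * 3
            m = [slice(None)] * 3
            b = [slice(None)] * 3
            a[axis] = slice(0, n - 2)
            m[axis] = slice(1, n - 1)
            b[axis] = slice(2, n)
            bends.append(
                np.stack(
                    [idx[tuple(a)].ravel(), idx[tuple(m)].ravel(), idx[tuple(b)].ravel()],
                    axis=1,
                )
            )
    beams_arr = (
        np.concatenate(beams, axis=0) if beams else np.empty((0, 2), dtype=np.int64)
    )
    bends_arr = (
        np.concatenate(bends, axis=0) if bends else np.empty((0, 3), dtype=np.int64)
    )
    return beams_arr.astype(np.int64), bends_arr.astype(np.int64)


@dataclass
class LatticeState:
    """Positions/velocities of the particle lattice plus its topology.

    positions/velocities: (N, 3) arrays in cm and cm/s; beams: (B, 2)
    particle-index pairs (particle index == voxel flat index, so beams also
    identify the incident voxels whose current lengths are averaged into the
    per-beam resting length); bends: (Bb, 3) collinear triples carrying the
    straightening springs; top_particles: indices of the initially-top-layer
    particles, tracked for rollover detection.
    """

    grid: GridSpec
    positions: np.ndarray
    velocities: np.ndarray
    beams: np.ndarray
    bends: np.ndarray
    top_particles: np.ndarray
    particle_mass: float = 1.0
    time: float = 0.0

    def beam_rest_lengths(self, genome: Genome, cfg: DevoConfig) -> np.ndarray:
        """Per-beam resting length at the state's current time: the average
        of the two incident voxels' instantaneous lengths."""
        lv = current_length_series(genome, np.array([self.time]), cfg)[0]
        return 0.5 * (lv[self.beams[:, 0]] + lv[self.beams[:, 1]])

    def copy(self) -> "LatticeState":
        return LatticeState(
            grid=self.grid,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            beams=self.beams,
            bends=self.bends,
            top_particles=self.top_particles,
            particle_mass=self.particle_mass,
            time=self.time,
        )


@dataclass
class Trajectory:
    """Sampled behavior summary of one simulated lifetime."""

    times: np.ndarray
    com: np.ndarray  # (S, 3) center of mass, cm
    top_layer_min_height: np.ndarray  # (S,) lowest initially-top particle, cm
    instantaneous_velocity: np.ndarray  # (S,) horizontal COM speed, cm/s
    path_length: float = 0.0  # horizontal COM path length over the lifetime, cm

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "com_x": self.com[:, 0],
                "com_y": self.com[:, 1],
                "com_z": self.com[:, 2],
                "top_min_z": self.top_layer_min_height,
                "speed": self.instantaneous_velocity,
            }
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# devoxel-trajectory-v1\n")
            self.to_dataframe().to_csv(fh, index=False)


def build_lattice(
    genome: Genome,
    grid: GridSpec | None = None,
    devo_cfg: DevoConfig | None = None,
    t: float = 0.0,
    particle_mass: float = 1.0,
) -> LatticeState:
    """Place one particle per voxel with spacing equal to the mean of the
    adjacent voxels' instantaneous lengths at time t.

    Rows along x and y are centered on the midsagittal/midcoronal planes, so
    mirror-symmetric morphologies yield x-coordinates symmetric about x = 0.
    Columns along z start at the ground plane (min z = 0, robot resting on
    the ground). Velocities are zero.
    """
    grid = grid or genome.grid
    devo_cfg = devo_cfg or DevoConfig()
    nx, ny, nz = grid.shape
    lv = current_length_series(genome, np.array([t]), devo_cfg)[0].reshape(grid.shape)

    pos = np.zeros((nx, ny, nz, 3))
    # x chains, one per (y, z); center each chain at 0
    for axis in range(3):
        n = grid.shape[axis]
        mids = 0.5 * (np.take(lv, range(0, n - 1), axis=axis) + np.take(lv, range(1, n), axis=axis))
        coord = np.concatenate(
            [np.zeros_like(np.take(lv, [0], axis=axis)), np.cumsum(mids, axis=axis)],
            axis=axis,
        )
        if axis < 2:  # center x and y chains; z stacks up from the ground
            coord = coord - 0.5 * np.take(coord, [n - 1], axis=axis)
        pos[..., axis] = coord

    idx = np.arange(grid.n_voxels).reshape(grid.shape)
    beams, bends = _topology(grid)
    state = LatticeState(
        grid=grid,
        positions=pos.reshape(-1, 3),
        velocities=np.zeros((grid.n_voxels, 3)),
        beams=beams,
        bends=bends,
        top_particles=idx[:, :, nz - 1].ravel().copy(),
        particle_mass=particle_mass,
        time=float(t),
    )
    # rest exactly on the ground plane
    state.positions[:, 2] -= state.positions[:, 2].min()
    return state


@njit(cache=False)
def _integrate(
    pos,
    vel,
    beams,
    bends,
    lv,  # (T, V) per-voxel instantaneous lengths at every step time
    m,
    dt,
    spring_k,
    bend_k,
    damping_c,
    gravity,
    ground_k,
    ground_c,
    mu,
    slide_eps,
    steps_per_sample,
    n_samples,
):
    """Semi-implicit Euler integration, sampling the state every
    steps_per_sample steps (sample 0 is the initial state). Returns sampled
    positions/velocities and the index of the first divergent sample (-1 if
    stable)."""
    n = pos.shape[0]
    nb = beams.shape[0]
    nbb = bends.shape[0]
    out_pos = np.empty((n_samples, n, 3))
    out_vel = np.empty((n_samples, n, 3))
    force = np.empty((n, 3))
    step_i = 0
    diverged = -1
    for s in range(n_samples):
        for i in range(n):
            for d in range(3):
                out_pos[s, i, d] = pos[i, d]
                out_vel[s, i, d] = vel[i, d]
        # divergence check at sample granularity
        ok = True
        for i in range(n):
            for d in range(3):
                v = pos[i, d]
                if not np.isfinite(v) or abs(v) > 1.0e3:
                    ok = False
        if not ok:
            diverged = s
            break
        if s == n_samples - 1:
            break
        for _ in range(steps_per_sample):
            for i in range(n):
                force[i, 0] = -damping_c * vel[i, 0]
                force[i, 1] = -damping_c * vel[i, 1]
                force[i, 2] = -damping_c * vel[i, 2] - m * gravity
            # beams: spring toward the averaged instantaneous voxel lengths
            for e in range(nb):
                a = beams[e, 0]
                b = beams[e, 1]
                rest = 0.5 * (lv[step_i, a] + lv[step_i, b])
                dx = pos[b, 0] - pos[a, 0]
                dy = pos[b, 1] - pos[a, 1]
                dz = pos[b, 2] - pos[a, 2]
                dist = math.sqrt(dx * dx + dy * dy + dz * dz)
                if dist > 1e-12:
                    f = spring_k * (dist - rest) / dist
                    fx = f * dx
                    fy = f * dy
                    fz = f * dz
                    force[a, 0] += fx
                    force[a, 1] += fy
                    force[a, 2] += fz
                    force[b, 0] -= fx
                    force[b, 1] -= fy
                    force[b, 2] -= fz
            # straightening springs across collinear beam pairs
            for e in range(nbb):
                a = bends[e, 0]
                c = bends[e, 1]
                b = bends[e, 2]
                rest = 0.5 * lv[step_i, a] + lv[step_i, c] + 0.5 * lv[step_i, b]
                dx = pos[b, 0] - pos[a, 0]
                dy = pos[b, 1] - pos[a, 1]
                dz = pos[b, 2] - pos[a, 2]
                dist = math.sqrt(dx * dx + dy * dy + dz * dz)
                if dist > 1e-12:
                    f = bend_k * (dist - rest) / dist
                    fx = f * dx
                    fy = f * dy
                    fz = f * dz
                    force[a, 0] += fx
                    force[a, 1] += fy
                    force[a, 2] += fz
                    force[b, 0] -= fx
                    force[b, 1] -= fy
                    force[b, 2] -= fz
            # ground contact: one-sided penalty + viscous normal + friction
            for i in range(n):
                z = pos[i, 2]
                if z < 0.0:
                    nf = -ground_k * z - ground_c * vel[i, 2]
                    if nf < 0.0:
                        nf = 0.0
                    force[i, 2] += nf
                    vx = vel[i, 0]
                    vy = vel[i, 1]
                    vt = math.sqrt(vx * vx + vy * vy)
                    ft = mu * nf / (vt + slide_eps)
                    force[i, 0] -= ft * vx
                    force[i, 1] -= ft * vy
            for i in range(n):
                for d in range(3):
                    vel[i, d] += dt * force[i, d] / m
                    pos[i, d] += dt * vel[i, d]
            step_i += 1
    return out_pos, out_vel, diverged


def step(
    state: LatticeState,
    genome: Genome,
    cfg: PhysicsConfig,
    devo_cfg: DevoConfig,
) -> LatticeState:
    """Advance the lattice by one timestep (returns a new state).

    Beam resting lengths are refreshed from the developing voxel lengths at
    the state's current time before the update.
    """
    new = state.copy()
    lv = current_length_series(genome, np.array([state.time]), devo_cfg)
    out_pos, out_vel, diverged = _integrate(
        new.positions,
        new.velocities,
        state.beams,
        state.bends,
        lv,
        cfg.particle_mass,
        cfg.dt,
        cfg.spring_k,
        cfg.bend_k,
        cfg.damping_c,
        cfg.gravity,
        cfg.ground_k,
        cfg.ground_c,
        cfg.mu,
        cfg.slide_eps,
        1,
        2,
    )
    if diverged >= 0:
        raise PhysicsInstabilityError(
            f"simulation diverged at t={state.time:g}s "
            f"(dt={cfg.dt:g}, spring_k={cfg.spring_k:g})"
        )
    new.positions = out_pos[1]
    new.velocities = out_vel[1]
    new.time = state.time + cfg.dt
    return new


def simulate(
    genome: Genome,
    grid: GridSpec | None = None,
    devo_cfg: DevoConfig | None = None,
    phys_cfg: PhysicsConfig | None = None,
    record_interval: float = 0.01,
) -> Trajectory:
    """Simulate one lifetime t in [0, tau] and record a Trajectory.

    Deterministic given its inputs. Samples are taken every record_interval
    seconds (record_interval must be a multiple of dt); sample count is
    floor(tau / record_interval) + 1.
    """
    grid = grid or genome.grid
    devo_cfg = devo_cfg or DevoConfig()
    phys_cfg = phys_cfg or PhysicsConfig()

    steps_per_sample = int(round(record_interval / phys_cfg.dt))
    if steps_per_sample < 1 or abs(steps_per_sample * phys_cfg.dt - record_interval) > 1e-9:
        raise ValueError("record_interval must be a positive multiple of dt")
    n_samples = int(math.floor(devo_cfg.tau / record_interval + 1e-9)) + 1
    total_steps = (n_samples - 1) * steps_per_sample

    state = build_lattice(genome, grid, devo_cfg, t=0.0, particle_mass=phys_cfg.particle_mass)
    times = np.arange(total_steps) * phys_cfg.dt
    # development is open loop: per-voxel lengths precomputed for every step
    lv = current_length_series(genome, np.minimum(times, devo_cfg.tau), devo_cfg)

    out_pos, out_vel, diverged = _integrate(
        state.positions,
        state.velocities,
        state.beams,
        state.bends,
        lv,
        phys_cfg.particle_mass,
        phys_cfg.dt,
        phys_cfg.spring_k,
        phys_cfg.bend_k,
        phys_cfg.damping_c,
        phys_cfg.gravity,
        phys_cfg.ground_k,
        phys_cfg.ground_c,
        phys_cfg.mu,
        phys_cfg.slide_eps,
        steps_per_sample,
        n_samples,
    )
    if diverged >= 0:
        raise PhysicsInstabilityError(
            f"simulation diverged at sample {diverged} "
            f"(t={diverged * record_interval:g}s, dt={phys_cfg.dt:g}, "
            f"spring_k={phys_cfg.spring_k:g}, ground_k={phys_cfg.ground_k:g})"
        )

    sample_times = np.arange(n_samples) * record_interval
    com = out_pos.mean(axis=1)
    top_min = out_pos[:, state.top_particles, 2].min(axis=1)
    speed = np.linalg.norm(out_vel.mean(axis=1)[:, :2], axis=1)
    path = float(np.sum(np.linalg.norm(np.diff(com[:, :2], axis=0), axis=1)))
    return Trajectory(
        times=sample_times,
        com=com,
        top_layer_min_height=top_min,
        instantaneous_velocity=speed,
        path_length=path,
    )


def fitness(traj: Trajectory, grid: GridSpec, use_path_length: bool = False) -> float:
    """Distance traveled in undeformed body lengths.

    By default the Euclidean norm of the net horizontal center-of-mass
    displacement between birth and death, divided by the body length
    (4 cm at the reference grid). ``use_path_length=True`` instead divides
    the horizontal COM path length.
    """
    if use_path_length:
        return traj.path_length / grid.body_length
    d = traj.com[-1, :2] - traj.com[0, :2]
    return float(np.linalg.norm(d)) / grid.body_length


def detect_rollover(traj: Trajectory, contact_eps: float = 0.05) -> float | None:
    """First sample time at which any initially-top-layer particle touches
    the ground (height <= contact_eps); None if the robot never rolls."""
    hits = np.nonzero(traj.top_layer_min_height <= contact_eps)[0]
    if hits.size == 0:
        return None
    return float(traj.times[hits[0]])


def mechanical_energy(
    positions: np.ndarray,
    velocities: np.ndarray,
    state: LatticeState,
    lv_row: np.ndarray,
    cfg: PhysicsConfig,
) -> float:
    """Total mechanical energy (kinetic + gravitational + beam and
    straightening-spring elastic + ground penalty elastic) of one sampled
    configuration; used by the energy-dissipation diagnostics."""
    m = cfg.particle_mass
    kin = 0.5 * m * float(np.sum(velocities**2))
    pot = m * cfg.gravity * float(np.sum(positions[:, 2]))
    a, b = state.beams[:, 0], state.beams[:, 1]
    rest = 0.5 * (lv_row[a] + lv_row[b])
    d = np.linalg.norm(positions[b] - positions[a], axis=1)
    elastic = 0.5 * cfg.spring_k * float(np.sum((d - rest) ** 2))
    if state.bends.shape[0]:
        a2, m2, b2 = state.bends[:, 0], state.bends[:, 1], state.bends[:, 2]
        rest2 = 0.5 * lv_row[a2] + lv_row[m2] + 0.5 * lv_row[b2]
        d2 = np.linalg.norm(positions[b2] - positions[a2], axis=1)
        elastic += 0.5 * cfg.bend_k * float(np.sum((d2 - rest2) ** 2))
    pen = np.minimum(positions[:, 2], 0.0)
    ground = 0.5 * cfg.ground_k * float(np.sum(pen**2))
    return kin + pot + elastic + ground
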