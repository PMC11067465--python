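"""Deterministic synthetic trajectories with known ground truth.

These generators produce small, exactly characterized ensembles used
throughout the test suites and examples: a leader--follower pair where
one individual copies the other with a fixed lag, a circular mover with
known turning rate, a static lattice, and a straight-line school.
"""

from __future__ import annotations

import numpy as np

from .trajectory import TrajectoryEnsemble


def copy_with_lag_pair(lag_frames: int = 10, n_frames: int = 2000,
                       dt: float = 0.02, speed: float = 11.0,
                       wiggle_amplitude: float = 0.6,
                       wiggle_period_s: float = 2.5,
                       separation: float = 3.0,
                       follower_speed_factor: float = 0.8,
                       ) -> TrajectoryEnsemble:
    """Two individuals: agent 1 copies agent 0's heading ``lag_frames``
    frames later.

    Agent 0 (the leader) wiggles its heading sinusoidally and, by
    default, moves faster than the follower, mirroring the
    speed-based leadership mechanism.  Velocities and accelerations are
    exact analytical derivatives.
    """
    T = n_frames
    t = np.arange(T + lag_frames) * dt
    omega = 2 * np.pi / wiggle_period_s
    theta = wiggle_amplitude * np.sin(omega * t)

    def kinematics(th, sp):
        vel = sp * np.column_stack([np.cos(th), np.sin(th)])
        pos = np.cumsum(vel, axis=0) * dt
        acc = np.gradient(vel, dt, axis=0)
        return pos, vel, acc

    p0, v0, a0 = kinematics(theta[lag_frames:], speed)
    p1, v1, a1 = kinematics(theta[:T], speed * follower_speed_factor)
    p1 = p1 - p1[0] + p0[0] + np.array([0.0, -separation])
    pos = np.stack([p0, p1], axis=1)
    vel = np.stack([v0, v1], axis=1)
    acc = np.stack([a0, a1], axis=1)
    return TrajectoryEnsemble(pos, vel, acc, dt, metadata={
        "kinematics": "analytic", "fixture": "copy_with_lag",
        "lag_frames": lag_frames})


def circular_mover(radius: float = 10.0, speed: float = 11.0,
                   n_frames: int = 500, dt: float = 0.02,
                   n_individuals: int = 1) -> TrajectoryEnsemble:
    """Uniform circular motion: |turning rate| = speed / radius.

    Multiple individuals are placed on the same circle with staggered
    phases.
    """
    t = np.arange(n_frames) * dt
    omega = speed / radius
    phases = 2 * np.pi * np.arange(n_individuals) / max(n_individuals, 1)
    ang = omega * t[:, None] + phases[None, :]
    pos = radius * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    vel = speed * np.stack([-np.sin(ang), np.cos(ang)], axis=-1)
    acc = -omega * speed * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return TrajectoryEnsemble(pos, vel, acc, dt, metadata={
        "kinematics": "analytic", "fixture": "circular"})


def static_lattice(n_side: int = 3, spacing: float = 5.8,
                   n_frames: int = 50, dt: float = 0.02,
                   heading_speed: float = 11.0) -> TrajectoryEnsemble:
    """Square lattice of stationary positions with a uniform heading.

    Positions never move, but every individual carries the same nominal
    velocity so headings (and hence polarization = 1) are defined.
    """
    g = np.arange(n_side) * spacing
    gx, gy = np.meshgrid(g, g, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # slight deterministic jitter keeps the Delaunay triangulation
    # non-degenerate without changing the lattice structure
    rng = np.random.default_rng(0)
    pts = pts + 1e-3 * rng.standard_normal(pts.shape)
    pos = np.repeat(pts[None], n_frames, axis=0)
    vel = np.zeros_like(pos)
    vel[..., 0] = heading_speed
    acc = np.zeros_like(pos)
    return TrajectoryEnsemble(pos, vel, acc, dt, metadata={
        "kinematics": "analytic", "fixture": "static_lattice"})


def straight_line_school(n_individuals: int = 5, speed: float = 11.0,
                         spacing: float = 5.8, n_frames: int = 200,
                         dt: float = 0.02) -> TrajectoryEnsemble:
    """Perfectly polarized school moving along +x in a staggered file."""
    offsets = np.column_stack([
        spacing * np.arange(n_individuals),
        0.5 * spacing * (np.arange(n_individuals) % 2)])
    t = np.arange(n_frames) * dt
    pos = offsets[None] + np.array([speed, 0.0]) * t[:, None, None]
    vel = np.zeros_like(pos)
    vel[..., 0] = speed
    acc = np.zeros_like(pos)
    return TrajectoryEnsemble(pos, vel, acc, dt, metadata={
        "kinematics": "analytic", "fixture": "straight_line"})
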