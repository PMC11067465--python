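"""Individual force terms of the schooling model.

All forces are accelerations (mass m = 1, units cm/s^2).  The pairwise
functions operate on single 2-vectors and are the reference definitions;
the simulator evaluates vectorized equivalents of the same expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

#: speeds below this are treated as a degenerate state (heading undefined)
SPEED_EPS = 1e-9


class DegenerateStateError(ValueError):
    """Raised when a heading or pair separation is undefined."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < SPEED_EPS:
        raise DegenerateStateError("zero speed: heading undefined")
    return v / n


def perp(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counter-clockwise)."""
    return np.array([-v[1], v[0]])


def attraction_repulsion_force(pos_i: np.ndarray, pos_j: np.ndarray,
                               params: ModelParams) -> np.ndarray:
    """Pairwise restoring force toward the equilibrium distance d0.

    F_ij = -k (d_ij - d0) (x_i - x_j) / d_ij with k = k_rep for
    d_ij <= d0 and k = k_att for d_ij > d0: repulsive inside d0,
    attractive outside.
    """
    pos_i = np.asarray(pos_i, float)
    pos_j = np.asarray(pos_j, float)
    sep = pos_i - pos_j
    d = np.linalg.norm(sep)
    if d < SPEED_EPS:
        raise DegenerateStateError("coincident positions in pair force")
    k = params.k_rep if d <= params.d0 else params.k_att
    return -k * (d - params.d0) * sep / d


def alignment_force(vel_i: np.ndarray, vel_j: np.ndarray,
                    params: ModelParams) -> np.ndarray:
    """Pairwise alignment force -mu (v_i - v_j)."""
    return -params.mu * (np.asarray(vel_i, float) - np.asarray(vel_j, float))


def friction_propulsion_force(vel_i: np.ndarray,
                              params: ModelParams) -> np.ndarray:
    """Speed-relaxation force -((|v| - v0)/tau) v-hat.

    Drives the speed toward the preferred speed v0 on timescale tau_v;
    acts along the heading only, so it never turns the individual.
    """
    vel_i = np.asarray(vel_i, float)
    vhat = _unit(vel_i)
    speed = np.linalg.norm(vel_i)
    return -((speed - params.v0) / params.tau_v) * vhat


def noise_force(vel_i: np.ndarray, params: ModelParams,
                rng: np.random.Generator) -> np.ndarray:
    """Active-fluctuation force sigma_v xi_v v-hat + sigma_phi xi_phi phi-hat.

    xi_v, xi_phi are independent standard normals; phi-hat is the heading
    rotated +90 degrees.  The Euler--Maruyama 1/sqrt(dt) scaling is applied
    by the integrator, not here.
    """
    vhat = _unit(np.asarray(vel_i, float))
    xi_v, xi_phi = rng.standard_normal(2)
    return params.sigma_v * xi_v * vhat + params.sigma_phi * xi_phi * perp(vhat)


@dataclass
class PersistentRegister:
    """Per-individual state of the persistent-random-force variant."""

    direction: np.ndarray      # (n, 2) unit vectors
    remaining: np.ndarray      # (n,) seconds left
    active: np.ndarray         # (n,) bool

    @classmethod
    def empty(cls, n: int) -> "PersistentRegister":
        return cls(direction=np.zeros((n, 2)), remaining=np.zeros(n),
                   active=np.zeros(n, bool))

    def copy(self) -> "PersistentRegister":
        return PersistentRegister(self.direction.copy(),
                                  self.remaining.copy(), self.active.copy())


def persistent_random_force(register: PersistentRegister,
                            params: ModelParams, rng: np.random.Generator,
                            dt: float) -> np.ndarray:
    """Advance the persistent-force registers one step and return the force.

    Inactive individuals activate with probability rate*dt, drawing a
    uniformly random direction held for ``duration`` seconds; while active
    their social forces are switched off (handled by the simulator via
    ``register.active``) and they feel amplitude*direction.  Expired
    registers deactivate *after* contributing their final step.
    """
    pr = params.persistent
    if pr is None:
        raise ValueError("persistent parameters not configured")
    n = register.active.size
    activate = (~register.active) & (rng.random(n) < pr.rate * dt)
    if activate.any():
        theta = rng.uniform(0.0, 2 * np.pi, int(activate.sum()))
        register.direction[activate] = np.column_stack(
            [np.cos(theta), np.sin(theta)])
        register.remaining[activate] = pr.duration
        register.active[activate] = True
    force = np.where(register.active[:, None],
                     pr.amplitude * register.direction, 0.0)
    register.remaining[register.active] -= dt
    register.active &= register.remaining > SPEED_EPS
    return force


@dataclass
class ForceBreakdown:
    """Per-individual decomposition of the total deterministic force.

    Components are (n, 2) arrays in cm/s^2; ``total`` is their sum
    (noise is the realized stochastic increment divided by dt, recorded
    separately by the integrator).
    """

    attraction_repulsion: np.ndarray
    alignment: np.ndarray
    friction_propulsion: np.ndarray
    noise: np.ndarray
    persistent: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return (self.attraction_repulsion + self.alignment
                + self.friction_propulsion + self.noise + self.persistent)

    @property
    def social(self) -> np.ndarray:
        return self.attraction_repulsion + self.alignment
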