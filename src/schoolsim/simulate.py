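"""Stochastic integration of the schooling model and its variants.

The equations of motion are solved with the Euler--Maruyama scheme in
semi-implicit form: velocities are updated from the forces evaluated at
the current state, positions are then advanced with the *new* velocities.
Noise enters the velocity update scaled by sqrt(dt), consistent with the
cm/s^(3/2) units of the noise amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .forces import (DegenerateStateError, ForceBreakdown,
                     PersistentRegister, SPEED_EPS)
from .neighbors import NeighborGraph, social_weights, voronoi_adjacency
from .params import ModelParams
from .trajectory import TrajectoryEnsemble


@dataclass
class AgentState:
    """Positions and velocities of all individuals at one instant."""

    positions: np.ndarray   # (n, 2) cm
    velocities: np.ndarray  # (n, 2) cm/s
    persistent: Optional[PersistentRegister] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    def copy(self) -> "AgentState":
        return AgentState(self.positions.copy(), self.velocities.copy(),
                          None if self.persistent is None
                          else self.persistent.copy())


def _headings(velocities: np.ndarray) -> np.ndarray:
    speed = np.linalg.norm(velocities, axis=1)
    if np.any(speed < SPEED_EPS):
        raise DegenerateStateError("zero speed encountered; heading "
                                   "undefined")
    return velocities / speed[:, None]


def interacting_sets(state: AgentState, graph: NeighborGraph,
                     params: ModelParams) -> np.ndarray:
    """(n, n) bool matrix; row i = the neighbors individual i listens to.

    standard / explicit_antialignment / persistent_random: all Voronoi
    neighbors.  selective: Voronoi neighbors strictly faster than the
    focal individual (speed ties count as not faster).  nearest_only:
    only the nearest neighbor.
    """
    if params.variant == "selective":
        speed = np.linalg.norm(state.velocities, axis=1)
        return graph.adjacency & (speed[None, :] > speed[:, None])
    if params.variant == "nearest_only":
        sel = np.zeros_like(graph.adjacency)
        sel[np.arange(len(sel)), graph.nearest] = True
        return sel
    return graph.adjacency


def compose_social_force(state: AgentState, graph: NeighborGraph,
                         params: ModelParams) -> ForceBreakdown:
    """Distance-weighted social force per individual, split by term.

    Pairwise attraction--repulsion and alignment forces are averaged over
    each individual's interacting set with normalized 1/d_ij weights.  In
    the explicit_antialignment variant the alignment term is replaced by
    a tabulated-field lookup at the focal-frame relative velocity with
    the nearest neighbor.  Friction--propulsion/noise are not social and
    are left zero here.
    """
    x, v = state.positions, state.velocities
    n = len(x)
    interacting = interacting_sets(state, graph, params)
    w = social_weights(graph, x, interacting,
                       normalize=params.normalize_weights)

    diff = x[:, None, :] - x[None, :, :]          # x_i - x_j
    d = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    k = np.where(d <= params.d0, params.k_rep, params.k_att)
    with np.errstate(invalid="ignore"):
        factor = -(k * (d - params.d0) / d)
    np.fill_diagonal(factor, 0.0)
    att_pair = factor[..., None] * diff
    att = (w[..., None] * att_pair).sum(1)

    if params.variant == "explicit_antialignment":
        from .forcemap import focal_frame, focal_frame_inverse
        heading = _headings(v)
        nn = graph.nearest
        rel_v = focal_frame(v - v[nn], heading)
        align = focal_frame_inverse(
            np.asarray(params.antialign_field(rel_v), float), heading)
    else:
        dv = v[:, None, :] - v[None, :, :]
        align = (w[..., None] * (-params.mu * dv)).sum(1)

    zeros = np.zeros_like(att)
    return ForceBreakdown(attraction_repulsion=att, alignment=align,
                          friction_propulsion=zeros, noise=zeros,
                          persistent=zeros)


def total_deterministic_force(state: AgentState, params: ModelParams,
                              rng: np.random.Generator,
                              graph: Optional[NeighborGraph] = None
                              ) -> ForceBreakdown:
    """All force terms except noise, advancing persistent registers."""
    from .forces import persistent_random_force

    if graph is None:
        graph = voronoi_adjacency(state.positions)
    fb = compose_social_force(state, graph, params)

    v = state.velocities
    if np.isfinite(params.tau_v):  # tau_v = inf switches the term off
        speed = np.linalg.norm(v, axis=1)
        if np.any(speed < SPEED_EPS):
            raise DegenerateStateError("zero speed in friction-propulsion")
        fb.friction_propulsion = (
            -((speed - params.v0) / params.tau_v)[:, None]
            * (v / speed[:, None]))

    if params.variant == "persistent_random":
        if state.persistent is None:
            state.persistent = PersistentRegister.empty(len(v))
        # social forces switch off while the private force is active
        was_active = state.persistent.active.copy()
        fb.persistent = persistent_random_force(state.persistent, params,
                                                rng, params.dt)
        off = was_active | state.persistent.active
        fb.attraction_repulsion[off] = 0.0
        fb.alignment[off] = 0.0
        fb.persistent[~(was_active | state.persistent.active)] = 0.0
    return fb


def step(state: AgentState, params: ModelParams, rng: np.random.Generator,
         return_breakdown: bool = False):
    """One Euler--Maruyama step; returns (new_state, acceleration).

    The recorded acceleration is the realized velocity increment divided
    by dt (deterministic force plus noise increment / dt), which is what
    an observer differentiating the saved trajectory would measure.
    """
    fb = total_deterministic_force(state, params, rng)
    v = state.velocities
    if params.sigma_v > 0 or params.sigma_phi > 0:
        heading = _headings(v)
        xi = rng.standard_normal((len(v), 2))
        phi_hat = np.column_stack([-heading[:, 1], heading[:, 0]])
        noise = (params.sigma_v * xi[:, :1] * heading
                 + params.sigma_phi * xi[:, 1:] * phi_hat)
    else:
        noise = np.zeros_like(v)
    dv = fb.total * params.dt + noise * np.sqrt(params.dt)
    v_new = v + dv
    x_new = state.positions + v_new * params.dt
    acc = dv / params.dt
    new_state = AgentState(x_new, v_new, state.persistent)
    if return_breakdown:
        fb.noise = noise / np.sqrt(params.dt)  # cm/s^(3/2) white-noise rate
        return new_state, acc, fb
    return new_state, acc


def initial_state(params: ModelParams, rng: np.random.Generator
                  ) -> AgentState:
    """Random initial condition resembling a settled school.

    Positions uniform in a disc whose radius makes the expected nearest
    neighbor distance about d0; speeds v0; headings uniform at random.
    """
    n = params.n_individuals
    # mean NN distance of a Poisson process of intensity lam is
    # 0.5/sqrt(lam); match it to d0
    radius = 2.0 * params.d0 * np.sqrt(n / np.pi)
    r = radius * np.sqrt(rng.random(n))
    ang = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    theta = rng.uniform(0, 2 * np.pi, n)
    vel = params.v0 * np.column_stack([np.cos(theta), np.sin(theta)])
    return AgentState(pos, vel)


def simulate(params: ModelParams, n_frames: int, n_transient: int = 0,
             init: Optional[AgentState] = None,
             rng: Optional[np.random.Generator] = None
             ) -> TrajectoryEnsemble:
    """Integrate ``n_frames`` steps and return the post-transient ensemble.

    Parameters
    ----------
    n_frames : int
        Total number of integration steps; every step is saved.
    n_transient : int
        Number of initial frames discarded (ordering/cohesion burn-in).
    init : AgentState, optional
        Starting state; defaults to :func:`initial_state`.
    rng : numpy Generator, optional
        Defaults to ``np.random.default_rng(params.seed)``.
    """
    if not n_frames > n_transient >= 0:
        raise ValueError("need n_frames > n_transient >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init.copy() if init is not None else initial_state(params, rng)
    n = len(state.positions)
    T = n_frames
    pos = np.empty((T, n, 2))
    vel = np.empty((T, n, 2))
    acc = np.empty((T, n, 2))
    for t in range(T):
        pos[t] = state.positions
        vel[t] = state.velocities
        state, acc[t] = step(state, params, rng)
    meta = {"kinematics": "integrator", "variant": params.variant,
            "n_transient": n_transient, "params": params.to_dict()}
    if params.seed is not None:
        meta["seed"] = params.seed
    return TrajectoryEnsemble(pos[n_transient:], vel[n_transient:],
                              acc[n_transient:], params.dt, metadata=meta)
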