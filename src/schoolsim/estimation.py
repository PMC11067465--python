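"""Parameter recovery: closed-form limits and force-map closure.

Each routine generates (or receives) model output and recovers one of
the generating parameters, providing an end-to-end consistency check of
the simulator and the inference machinery: the preferred speed and
relaxation time from a single noiseless individual, the alignment
constant from a noiseless pair, the spring constants from the pairwise
force law, and the equilibrium distance from the radial zero crossing of
an inferred attraction--repulsion force map.

The exponential fits invert the one-step multiplier of the Euler scheme
rather than assuming continuous-time decay: data produced with time step
dt decay by a factor (1 - lambda dt) per step, so the continuous-rate
estimate from a log-linear fit is mapped back through
lambda = (1 - exp(slope * dt)) / dt.  For dt -> 0 this reduces to the
naive -slope.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .forces import attraction_repulsion_force
from .forcemap import force_map, radial_zero_crossing
from .params import ModelParams
from .simulate import AgentState, simulate
from .trajectory import TrajectoryEnsemble


def _log_decay_rate(times: np.ndarray, values: np.ndarray,
                    dt: float) -> float:
    """Discrete-aware exponential decay rate of |values| over time.

    Fits log|values| vs t by least squares and converts the fitted slope
    into the per-unit-time rate of the underlying one-step multiplier.
    """
    ok = values > 0
    slope = np.polyfit(times[ok], np.log(values[ok]), 1)[0]
    return (1.0 - np.exp(slope * dt)) / dt


def _noiseless(params: ModelParams) -> ModelParams:
    return params.replace(sigma_v=0.0, sigma_phi=0.0)


def stationary_speed(params: Optional[ModelParams] = None,
                     initial_speed: float = 5.0,
                     duration: float = 20.0) -> float:
    """Terminal speed of a single noiseless individual.

    Integrates one agent (no neighbors within interaction relevance: a
    distant, symmetric ghost pair is avoided entirely by turning off the
    social constants) for ``duration`` seconds and returns the final
    speed, which relaxes to the preferred speed v0.
    """
    params = _noiseless(params or ModelParams())
    params = params.replace(k_rep=0.0, k_att=0.0, mu=0.0, n_individuals=2)
    # a far-away partner keeps the state valid while all social
    # constants are zero, so the dynamics is exactly single-agent
    init = AgentState(np.array([[0.0, 0.0], [1e6, 0.0]]),
                      np.array([[initial_speed, 0.0], [params.v0, 0.0]]))
    n = int(round(duration / params.dt))
    traj = simulate(params, n, 0, init=init,
                    rng=np.random.default_rng(0))
    return float(traj.speeds[-1, 0])


def relaxation_time(params: Optional[ModelParams] = None,
                    fit_window: float = 3.0) -> float:
    """Speed-relaxation time constant of a single noiseless individual.

    Releases the agent at twice its preferred speed, fits log|v - v0|
    over the first ``fit_window`` seconds and returns the inverse
    discrete-aware decay rate (the recovered tau_v).
    """
    params = _noiseless(params or ModelParams())
    params = params.replace(k_rep=0.0, k_att=0.0, mu=0.0, n_individuals=2)
    init = AgentState(np.array([[0.0, 0.0], [1e6, 0.0]]),
                      np.array([[2.0 * params.v0, 0.0],
                                [params.v0, 0.0]]))
    n = int(round(fit_window / params.dt)) + 1
    traj = simulate(params, n, 0, init=init, rng=np.random.default_rng(0))
    dev = np.abs(traj.speeds[:, 0] - params.v0)
    return 1.0 / _log_decay_rate(traj.times, dev, params.dt)


def alignment_constant(params: Optional[ModelParams] = None,
                       fit_window: float = 1.0) -> float:
    """Alignment constant recovered from a noiseless interacting pair.

    With only the alignment force active (single-neighbor weight 1), the
    velocity difference of two agents decays at rate 2 mu; the function
    fits that decay and returns half the recovered rate.
    """
    params = _noiseless(params or ModelParams())
    params = params.replace(k_rep=0.0, k_att=0.0, tau_v=np.inf,
                            n_individuals=2)
    init = AgentState(np.array([[0.0, 0.0], [5.8, 0.0]]),
                      np.array([[11.0, 3.0], [8.0, -2.0]]))
    n = int(round(fit_window / params.dt)) + 1
    traj = simulate(params, n, 0, init=init, rng=np.random.default_rng(0))
    dv = np.linalg.norm(traj.velocities[:, 0] - traj.velocities[:, 1],
                        axis=1)
    return 0.5 * _log_decay_rate(traj.times, dv, params.dt)


def spring_constant(params: Optional[ModelParams] = None,
                    branch: str = "repulsive") -> float:
    """Spring constant recovered from the pairwise restoring force law.

    Evaluates the attraction--repulsion force at five distances inside
    (repulsive branch) or outside (attractive branch) the equilibrium
    distance and regresses the acceleration magnitude on |d - d0|; the
    slope is k_rep or k_att exactly.
    """
    params = params or ModelParams()
    d0 = params.d0
    if branch == "repulsive":
        dists = np.linspace(0.5 * d0, d0, 7)[1:-1]
    elif branch == "attractive":
        dists = np.linspace(d0, 2.0 * d0, 7)[1:-1]
    else:
        raise ValueError("branch must be 'repulsive' or 'attractive'")
    mags = [np.linalg.norm(attraction_repulsion_force(
        np.zeros(2), np.array([d, 0.0]), params)) for d in dists]
    return float(np.polyfit(np.abs(dists - d0), mags, 1)[0])


def equilibrium_distance(traj: Optional[TrajectoryEnsemble] = None,
                         params: Optional[ModelParams] = None,
                         n_frames: int = 31000, n_transient: int = 1000,
                         seed: int = 0, extent: float = 20.0,
                         n_bins: int = 80, min_count: int = 20
                         ) -> Tuple[float, TrajectoryEnsemble]:
    """Equilibrium distance from the force-map radial zero crossing.

    Simulates the standard model (unless a trajectory is supplied),
    builds the relative-position force map with nearest neighbors,
    angularly averages its radial projection and returns the distance at
    which it changes sign from outward (repulsion) to inward
    (attraction), together with the trajectory used.

    A finer grid than the display default (0.5 cm bins over +/-20 cm)
    keeps the crossing interpolation error well below the map's
    structure scale.
    """
    if traj is None:
        params = (params or ModelParams()).replace(seed=seed)
        traj = simulate(params, n_frames, n_transient)
    fmap = force_map(traj, "relative_position", extent=extent,
                     n_bins=n_bins, min_count=min_count)
    r, prof, _ = fmap.radial_profile()
    return radial_zero_crossing(r, prof), traj
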