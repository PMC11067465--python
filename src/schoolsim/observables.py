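"""Group- and individual-level observables for model/data comparison.

Covers the polarization order parameter, nearest-neighbor distance,
convex-hull area per individual, Voronoi contact durations, individual
speeds and turning rates, and binned PDFs with Bernoulli error bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .neighbors import pairwise_distances, voronoi_adjacency
from .trajectory import TrajectoryEnsemble


def polarization(velocities: np.ndarray) -> float:
    """Modulus of the mean unit-velocity vector, in [0, 1].

    1 when all individuals move in the same direction; near 0 for
    independent headings.
    """
    velocities = np.asarray(velocities, float)
    speed = np.linalg.norm(velocities, axis=1)
    if np.any(speed < 1e-12):
        raise ValueError("zero speed: heading undefined")
    return float(np.linalg.norm((velocities / speed[:, None]).mean(0)))


def mean_nn_distance(positions: np.ndarray) -> float:
    """Mean over individuals of the distance to their nearest neighbor."""
    positions = np.asarray(positions, float)
    if len(positions) < 2:
        raise ValueError("need at least two individuals")
    d = pairwise_distances(positions)
    np.fill_diagonal(d, np.inf)
    return float(d.min(1).mean())


def convex_hull_area_per_capita(positions: np.ndarray) -> float:
    """Area of the group's convex hull divided by the number of
    individuals; 0 (with a warning) for degenerate/collinear sets."""
    positions = np.asarray(positions, float)
    if len(positions) < 3:
        raise ValueError("need at least three individuals")
    try:
        hull = ConvexHull(positions)
    except QhullError:
        warnings.warn("degenerate (collinear) configuration: hull area 0")
        return 0.0
    return float(hull.volume / len(positions))  # 2D: volume is the area


def turning_rate(vel: np.ndarray, acc: np.ndarray) -> np.ndarray:
    """Signed heading angular velocity omega = (v x a) / |v|^2, rad/s.

    Positive for counter-clockwise turning; computed from the velocity--
    acceleration cross product, which avoids 2-pi wrap artifacts of
    finite-differencing heading angles.
    """
    vel = np.asarray(vel, float)
    acc = np.asarray(acc, float)
    v2 = (vel ** 2).sum(-1)
    if np.any(v2 < 1e-24):
        raise ValueError("zero speed: turning rate undefined")
    return (vel[..., 0] * acc[..., 1] - vel[..., 1] * acc[..., 0]) / v2


def voronoi_contact_durations(traj: TrajectoryEnsemble,
                              gap_tolerance: int = 0) -> np.ndarray:
    """Durations (s) of maximal runs of Voronoi adjacency per pair.

    A run of L consecutive adjacent frames contributes L*dt.  With the
    default ``gap_tolerance`` 0 a single non-adjacent frame ends the
    episode; a tolerance of g frames bridges gaps up to g.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    active: dict = {}        # pair -> [run length, gap run]
    durations: List[float] = []
    for t in range(traj.n_frames):
        adj = voronoi_adjacency(traj.positions[t]).edges
        for pair in adj:
            if pair in active:
                active[pair][0] += 1 + active[pair][1]
                active[pair][1] = 0
            else:
                active[pair] = [1, 0]
        for pair in list(active):
            if pair not in adj:
                active[pair][1] += 1
                if active[pair][1] > gap_tolerance:
                    durations.append(active[pair][0])
                    del active[pair]
    durations.extend(run for run, _ in active.values())
    return np.asarray(durations, float) * traj.dt


def pdf_with_error_band(samples: np.ndarray, edges: np.ndarray
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Binned probability density with a Bernoulli-SD error band.

    density_k = p_k / w_k with p_k the fraction of samples in bin k and
    w_k the bin width; band_k = sqrt(p_k (1 - p_k) / n) / w_k with n the
    total sample count.
    """
    samples = np.asarray(samples, float).ravel()
    if samples.size == 0:
        raise ValueError("empty sample set")
    counts, edges = np.histogram(samples, bins=edges)
    n = samples.size
    width = np.diff(edges)
    p = counts / n
    density = p / width
    band = np.sqrt(p * (1 - p) / n) / width
    return density, band


@dataclass
class ObservablesSummary:
    """Per-frame group observables and pooled individual observables."""

    polarization: np.ndarray        # (T,)
    nn_distance: np.ndarray         # (T,) cm
    hull_area_per_capita: np.ndarray  # (T,) cm^2
    contact_durations: np.ndarray   # episodes, s
    speeds: np.ndarray              # (T, n) cm/s
    turning_rates: np.ndarray       # (T, n) rad/s
    dt: float

    def to_dict(self) -> dict:
        return {
            "mean_polarization": float(self.polarization.mean()),
            "mean_nn_distance": float(self.nn_distance.mean()),
            "var_nn_distance": float(self.nn_distance.var()),
            "mean_hull_area_per_capita":
                float(self.hull_area_per_capita.mean()),
            "median_contact_duration":
                float(np.median(self.contact_durations)),
            "mean_speed": float(self.speeds.mean()),
            "var_speed": float(self.speeds.var()),
            "mean_abs_turning_rate": float(np.abs(self.turning_rates).mean()),
        }


def summarize(traj: TrajectoryEnsemble,
              gap_tolerance: int = 0) -> ObservablesSummary:
    """Compute every observable on a trajectory ensemble."""
    T = traj.n_frames
    pol = np.empty(T)
    dnn = np.empty(T)
    hull = np.empty(T)
    for t in range(T):
        pol[t] = polarization(traj.velocities[t])
        dnn[t] = mean_nn_distance(traj.positions[t])
        hull[t] = convex_hull_area_per_capita(traj.positions[t])
    return ObservablesSummary(
        polarization=pol, nn_distance=dnn, hull_area_per_capita=hull,
        contact_durations=voronoi_contact_durations(traj, gap_tolerance),
        speeds=traj.speeds,
        turning_rates=turning_rate(traj.velocities, traj.accelerations),
        dt=traj.dt)
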