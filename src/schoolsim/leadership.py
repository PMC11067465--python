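"""Time-delayed leadership analysis.

Two complementary constructions identify leader--follower relationships
from trajectories alone:

* surrogate self-delay force maps: a pseudo-pair made of an individual at
  time t (focal) and the *same* individual at t + tau (neighbor).  For
  tau > 0 the focal is, by construction, a follower and the alignment
  map shows pure alignment (inward); for tau < 0 it is a leader and the
  map shows pure antialignment (outward).
* delayed correlations: the mean heading dot product
  <v-hat_i(t) . v-hat_NN(t+tau)> and the Pearson correlation of speeds
  r(v_i(t), v_NN(t+tau)) as functions of the signed delay, optionally
  restricted to focal states (faster/slower than the neighbor, or
  frontal/rear of it).  A peak at tau > 0 marks the focal as leader.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .forcemap import (ForceMap, bin_map, focal_frame,
                       nearest_neighbor_series, symmetric_edges)
from .trajectory import TrajectoryEnsemble

STATE_LABELS = ("all", "faster", "slower", "frontal", "rear")


def _delay_frames(tau: float, dt: float) -> int:
    k = tau / dt
    if abs(k - round(k)) > 1e-6:
        raise ValueError(f"delay {tau} s is not a multiple of dt={dt} s")
    return int(round(k))


def surrogate_self_delay_map(traj: TrajectoryEnsemble, tau: float,
                             extent: float = 15.0, n_bins: int = 30,
                             min_count: int = 50) -> ForceMap:
    """Relative-velocity force map of the self-delay pseudo-pair.

    The "neighbor" kinematics of focal i at time t are those of i at
    t + tau; tau must be a nonzero multiple of dt (positive: the focal
    acts as follower; negative: as leader).
    """
    k = _delay_frames(tau, traj.dt)
    T = traj.n_frames
    if abs(k) >= T:
        raise ValueError("delay longer than the recording")
    v, a = traj.velocities, traj.accelerations
    heading = traj.headings()
    if k >= 0:
        now, then = slice(0, T - k), slice(k, T)
    else:
        now, then = slice(-k, T), slice(0, T + k)
    rel_v = v[now] - v[then]
    coords = focal_frame(rel_v, heading[now]).reshape(-1, 2)
    resp = focal_frame(a[now], heading[now]).reshape(-1, 2)
    edges = symmetric_edges(extent, n_bins)
    return bin_map(coords, resp, edges, edges, min_count,
                   kind="relative_velocity")


def _state_masks(traj: TrajectoryEnsemble, nn: np.ndarray
                 ) -> Dict[str, np.ndarray]:
    """(T, n) state masks evaluated at the reference time."""
    x, v = traj.positions, traj.velocities
    rows = np.arange(traj.n_frames)[:, None]
    speed = traj.speeds
    nn_speed = speed[rows, nn]
    heading = traj.headings()
    front = ((x - x[rows, nn]) * heading).sum(-1)
    return {
        "all": np.ones_like(front, bool),
        "faster": speed > nn_speed,
        "slower": speed < nn_speed,
        "frontal": front > 0,
        "rear": front < 0,
    }


def state_filter(traj: TrajectoryEnsemble, frame: int, focal: int,
                 label: str) -> bool:
    """Whether (focal, frame) is in the given state w.r.t. its NN.

    faster/slower compare speeds (strict; ties are neither); frontal/
    rear use the sign of the NN-relative position along the focal
    heading.
    """
    if label not in STATE_LABELS:
        raise ValueError(f"unknown state label {label!r}")
    nn = nearest_neighbor_series(traj)
    return bool(_state_masks(traj, nn)[label][frame, focal])


@dataclass
class DelayedCorrelationCurve:
    """Orientation and speed correlations vs signed delay for one state."""

    label: str
    tau: np.ndarray            # (m,) s, multiples of dt
    orientation: np.ndarray    # (m,) mean heading dot product, NaN if empty
    speed_pearson: np.ndarray  # (m,) Pearson r of speeds, NaN if empty
    n_samples: np.ndarray      # (m,)

    def peak(self, which: str = "orientation") -> tuple:
        """(tau_at_max, max_value) of the requested curve."""
        vals = getattr(self, which)
        ok = np.isfinite(vals)
        idx = np.flatnonzero(ok)[np.argmax(vals[ok])]
        return float(self.tau[idx]), float(vals[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "filter": self.label, "tau": self.tau,
            "orient_corr": self.orientation,
            "speed_corr": self.speed_pearson, "n": self.n_samples})


def delayed_correlations(traj: TrajectoryEnsemble,
                         tau_grid: Optional[np.ndarray] = None,
                         label: str = "all",
                         nn: Optional[np.ndarray] = None
                         ) -> DelayedCorrelationCurve:
    """Correlations between a focal individual and its time-t nearest
    neighbor evaluated at t + tau, pooled over all individuals and frames.

    The nearest neighbor is fixed at the reference time t and followed
    (by identity) to t + tau; frames where t + tau falls outside the
    recording are dropped.  ``tau_grid`` defaults to +/-2 s in steps of
    dt.
    """
    if label not in STATE_LABELS:
        raise ValueError(f"unknown state label {label!r}")
    dt = traj.dt
    if tau_grid is None:
        tau_grid = np.arange(-100, 101) * dt
    ks = [_delay_frames(t, dt) for t in tau_grid]
    if nn is None:
        nn = nearest_neighbor_series(traj)
    mask = _state_masks(traj, nn)[label]
    heading = traj.headings()
    speed = traj.speeds
    T = traj.n_frames
    rows = np.arange(T)[:, None]

    orient = np.full(len(ks), np.nan)
    pearson = np.full(len(ks), np.nan)
    nsamp = np.zeros(len(ks), int)
    for m, k in enumerate(ks):
        if k >= 0:
            ref = slice(0, T - k) if k else slice(0, T)
        else:
            ref = slice(-k, T)
        sel = mask[ref]
        if not sel.any():
            continue
        r = rows[ref]
        partner = nn[ref]
        hdot = (heading[ref] * heading[r + k, partner]).sum(-1)[sel]
        s_i = speed[ref][sel]
        s_nn = speed[r + k, partner][sel]
        nsamp[m] = hdot.size
        orient[m] = hdot.mean()
        if s_i.size > 1 and s_i.std() > 0 and s_nn.std() > 0:
            pearson[m] = np.corrcoef(s_i, s_nn)[0, 1]
    return DelayedCorrelationCurve(label=label,
                                   tau=np.asarray(tau_grid, float),
                                   orientation=orient,
                                   speed_pearson=pearson, n_samples=nsamp)


def leadership_report(curves: Iterable[DelayedCorrelationCurve]
                      ) -> pd.DataFrame:
    """Tabulate peak delay and peak height per state filter.

    A positive orientation-peak delay marks the state's individuals as
    leaders (their heading is adopted by the neighbor later); negative
    marks them as followers.
    """
    rows = []
    for c in curves:
        to, vo = c.peak("orientation")
        ts, vs = c.peak("speed_pearson")
        rows.append({"filter": c.label,
                     "orient_peak_tau": to, "orient_peak_value": vo,
                     "speed_peak_tau": ts, "speed_peak_value": vs,
                     "role": ("leader" if to > 0 else
                              "follower" if to < 0 else "symmetric")})
    return pd.DataFrame(rows)
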