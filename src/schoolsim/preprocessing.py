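"""Experimental-trajectory preprocessing.

Replicates the pipeline applied to tracked fish positions before any
analysis: spline interpolation of short occlusion gaps, perspective
projection of image coordinates onto the (square) tank plane, and
Gaussian smoothing with velocities/accelerations obtained from
Gaussian-derivative kernels.  The same smoothing/differentiation is
applied to simulated positions when an analysis (e.g. the self-delay
leadership maps) must treat model output exactly like tracked data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.transform import ProjectiveTransform, estimate_transform

from .trajectory import TrajectoryEnsemble


@dataclass
class RawTrack:
    """Per-frame, per-id positions, possibly with invalid (NaN) entries.

    ``positions`` is (T, n, 2) in pixels or cm; invalid samples
    (occlusions) are NaN.
    """

    positions: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("expected positions of shape (frames, n, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def mask(self) -> np.ndarray:
        """(T, n) True where the sample is invalid."""
        return np.isnan(self.positions).any(-1)


@dataclass
class TankGeometry:
    """Square tank seen in image coordinates.

    ``corners`` are the four tank-wall corners in the image, ordered
    counter-clockwise starting from the corner mapped to (0, 0);
    ``side_cm`` is the physical side length.
    """

    corners: np.ndarray
    side_cm: float

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, float)
        if self.corners.shape != (4, 2):
            raise ValueError("need exactly four corner points")
        # convexity: all cross products of consecutive edges same sign
        rolled = np.roll(self.corners, -1, axis=0)
        edges = rolled - self.corners
        nxt = np.roll(edges, -1, axis=0)
        cross = edges[:, 0] * nxt[:, 1] - edges[:, 1] * nxt[:, 0]
        if np.any(cross == 0) or not (np.all(cross > 0)
                                      or np.all(cross < 0)):
            raise ValueError("corners must form a convex quadrilateral")

    def homography(self) -> ProjectiveTransform:
        s = self.side_cm
        dst = np.array([[0.0, 0.0], [s, 0.0], [s, s], [0.0, s]])
        return estimate_transform("projective", self.corners, dst)


def interpolate_gaps(track: RawTrack, max_gap: int = 10) -> RawTrack:
    """Fill interior occlusion gaps up to ``max_gap`` frames per id.

    Gaps are filled coordinate-wise with a cubic spline through the
    valid samples; longer gaps and gaps touching the sequence boundary
    stay NaN and are excluded downstream.
    """
    pos = track.positions.copy()
    T, n, _ = pos.shape
    for i in range(n):
        bad = np.isnan(pos[:, i]).any(-1)
        if not bad.any() or bad.all():
            continue
        good = np.flatnonzero(~bad)
        spline = CubicSpline(good, pos[good, i], axis=0)
        # enumerate interior gap runs
        run_start = None
        for t in range(T):
            if bad[t] and run_start is None:
                run_start = t
            if not bad[t] and run_start is not None:
                length = t - run_start
                if run_start > 0 and length <= max_gap:
                    frames = np.arange(run_start, t)
                    pos[frames, i] = spline(frames)
                run_start = None
        # trailing gap (boundary) stays masked
    return RawTrack(pos, track.fps)


def project_to_plane(track: RawTrack, geometry: TankGeometry) -> RawTrack:
    """Warp image coordinates onto the physical tank plane (cm).

    Applies the homography mapping the four imaged tank corners to a
    square of side ``geometry.side_cm``; straight lines map to straight
    lines, and the corners map exactly to the square's corners.
    """
    tf = geometry.homography()
    pos = track.positions
    flat = pos.reshape(-1, 2)
    ok = ~np.isnan(flat).any(-1)
    out = np.full_like(flat, np.nan)
    out[ok] = tf(flat[ok])
    return RawTrack(out.reshape(pos.shape), track.fps)


# ---------------------------------------------------------------------------
# Gaussian smoothing and differentiation


def gaussian_derivative_kernels(sigma: float, truncate: float = 5.0
                                ) -> tuple:
    """Discrete Gaussian kernels of derivative orders 0, 1 and 2.

    The sampled derivative-of-Gaussian kernels are moment-corrected so
    that order 0 sums to one, order 1 exactly differentiates linear
    sequences, and order 2 exactly yields the second derivative of
    quadratic sequences (offsets in frame units; divide the filter
    outputs by dt and dt^2 for physical rates).
    """
    radius = int(np.ceil(truncate * sigma))
    k = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (k / sigma) ** 2)
    w0 = g / g.sum()
    w1 = -k / sigma ** 2 * g
    w1 = w1 / (w1 * k).sum()          # sum w k = 1; sum w = 0 by symmetry
    w2 = (k ** 2 / sigma ** 4 - 1.0 / sigma ** 2) * g
    w2 = w2 - g * (w2.sum() / g.sum())  # zero total mass
    w2 = 2.0 * w2 / (w2 * k ** 2).sum()  # sum w k^2 = 2
    return w0, w1, w2


def smooth_and_differentiate(track: RawTrack, sigma_frames: float = 2.0,
                             truncate: float = 5.0) -> TrajectoryEnsemble:
    """Gaussian-smooth positions and differentiate with Gaussian kernels.

    Positions are convolved with a Gaussian of ``sigma_frames`` frames
    truncated at ``truncate`` sigma; velocities and accelerations come
    from the first and second Gaussian-derivative kernels divided by dt
    and dt^2.  Boundaries are reflect-padded and the first/last
    ``truncate*sigma`` frames are flagged as boundary-affected in the
    metadata.  The track must be gap-free.
    """
    if track.mask.any():
        raise ValueError("track has invalid samples; interpolate or trim "
                         "gaps first")
    radius = int(np.ceil(truncate * sigma_frames))
    T = track.positions.shape[0]
    if T <= 2 * radius:
        raise ValueError("track shorter than the filter support")
    w0, w1, w2 = gaussian_derivative_kernels(sigma_frames, truncate)
    dt = track.dt

    def conv(kernel: np.ndarray) -> np.ndarray:
        # correlate so that positive-offset taps read future frames
        return ndimage.correlate1d(track.positions, kernel, axis=0,
                                   mode="reflect")

    pos = conv(w0)
    vel = conv(w1) / dt
    acc = conv(w2) / dt ** 2
    return TrajectoryEnsemble(pos, vel, acc, dt, metadata={
        "kinematics": "gaussian_derivative",
        "sigma_frames": sigma_frames, "truncate": truncate,
        "boundary_frames": radius})


def reprocess_like_experiment(traj: TrajectoryEnsemble,
                              sigma_frames: float = 2.0,
                              truncate: float = 5.0,
                              trim_boundary: bool = True
                              ) -> TrajectoryEnsemble:
    """Run simulated positions through the experimental kinematics pipeline.

    Discards the integrator's velocities/accelerations and recomputes
    them with the Gaussian-derivative convention, optionally trimming
    the boundary-affected frames, so simulated and tracked data can be
    compared like for like.
    """
    track = RawTrack(traj.positions, fps=1.0 / traj.dt)
    out = smooth_and_differentiate(track, sigma_frames, truncate)
    if trim_boundary:
        r = out.metadata["boundary_frames"]
        out = out.slice_frames(r, out.n_frames - r)
    out.metadata.update({k: v for k, v in traj.metadata.items()
                         if k not in out.metadata})
    out.metadata["kinematics"] = "gaussian_derivative"
    return out
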