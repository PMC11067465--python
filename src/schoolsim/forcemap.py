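"""Force-map inference: binned mean accelerations in focal-frame coordinates.

The force-map (averaging) method infers an effective force as a function
of one relative variable by binning that variable over the whole dataset
and averaging the observed accelerations per bin; every other force term
is assumed to average to zero.  Two map kinds are used:

* ``relative_position`` -- acceleration vs x_i - x_NN (attraction--repulsion)
* ``relative_velocity`` -- acceleration vs v_i - v_NN (alignment)

Both coordinates and the acceleration response are expressed in the focal
frame: y-axis along the focal individual's direction of motion, x-axis to
its right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .neighbors import voronoi_adjacency
from .trajectory import TrajectoryEnsemble

# ---------------------------------------------------------------------------
# focal-frame rotation


def focal_frame(vec: np.ndarray, heading: np.ndarray) -> np.ndarray:
    """Rotate lab-frame vectors into the focal frame of ``heading``.

    The focal heading maps to (0, 1); the focal individual's right-hand
    side is +x.  Accepts arrays broadcastable to (..., 2); ``heading``
    must be unit-norm.
    """
    vec = np.asarray(vec, float)
    heading = np.asarray(heading, float)
    norm = np.sqrt((heading ** 2).sum(-1))
    if not np.allclose(norm, 1.0, atol=1e-8):
        raise ValueError("heading must be unit norm")
    hx, hy = heading[..., 0], heading[..., 1]
    cx, cy = vec[..., 0], vec[..., 1]
    return np.stack([hy * cx - hx * cy, hx * cx + hy * cy], axis=-1)


def focal_frame_inverse(vec: np.ndarray, heading: np.ndarray) -> np.ndarray:
    """Rotate focal-frame vectors back to the lab frame."""
    vec = np.asarray(vec, float)
    heading = np.asarray(heading, float)
    hx, hy = heading[..., 0], heading[..., 1]
    cx, cy = vec[..., 0], vec[..., 1]
    return np.stack([hy * cx + hx * cy, -hx * cx + hy * cy], axis=-1)


# ---------------------------------------------------------------------------
# sample collection


def nearest_neighbor_series(traj: TrajectoryEnsemble,
                            chunk: int = 2000) -> np.ndarray:
    """(T, n) index of each individual's nearest neighbor per frame."""
    x = traj.positions
    T, n, _ = x.shape
    out = np.empty((T, n), int)
    for lo in range(0, T, chunk):
        hi = min(lo + chunk, T)
        diff = x[lo:hi, :, None, :] - x[lo:hi, None, :, :]
        d = (diff ** 2).sum(-1)
        idx = np.arange(n)
        d[:, idx, idx] = np.inf
        out[lo:hi] = d.argmin(-1)
    return out


@dataclass
class SampleFilter:
    """Conjunctive per-(focal, frame) sample predicates.

    All bounds are closed-open intervals (lo, hi); any field left None is
    not applied.  ``wall_distance`` requires ``tank_side`` (square tank
    with walls at 0 and ``tank_side`` in both coordinates) and exists for
    experimental data; simulations are unbounded.
    """

    nn_distance: Optional[Tuple[float, float]] = None     # cm
    wall_distance: Optional[Tuple[float, float]] = None   # cm
    tank_side: Optional[float] = None                     # cm
    approach: Optional[str] = None        # "approaching" | "receding"
    relative_heading: Optional[Tuple[float, float]] = None  # rad, in [0, pi]
    focal_speed: Optional[Tuple[float, float]] = None     # cm/s
    neighbor_speed: Optional[str] = None  # "faster" | "slower"
    group_size: Optional[int] = None

    def mask(self, traj: TrajectoryEnsemble,
             nn_idx: np.ndarray) -> np.ndarray:
        """(T, n) boolean mask of samples passing every predicate."""
        T, n, _ = traj.positions.shape
        keep = np.ones((T, n), bool)
        rows = np.arange(T)[:, None]
        x, v = traj.positions, traj.velocities
        xn = x[rows, nn_idx]
        vn = v[rows, nn_idx]
        if self.group_size is not None:
            keep &= (n == self.group_size)
        if self.nn_distance is not None:
            d = np.linalg.norm(x - xn, axis=2)
            keep &= (d >= self.nn_distance[0]) & (d < self.nn_distance[1])
        if self.wall_distance is not None:
            if self.tank_side is None:
                raise ValueError("wall_distance filter needs tank_side")
            s = self.tank_side
            dw = np.minimum.reduce([x[..., 0], s - x[..., 0],
                                    x[..., 1], s - x[..., 1]])
            keep &= (dw >= self.wall_distance[0]) \
                & (dw < self.wall_distance[1])
        if self.approach is not None:
            ddot = ((x - xn) * (v - vn)).sum(-1)  # sign of d(d_ij)/dt
            if self.approach == "approaching":
                keep &= ddot < 0
            elif self.approach == "receding":
                keep &= ddot > 0
            else:
                raise ValueError("approach must be 'approaching' or "
                                 "'receding'")
        if self.relative_heading is not None:
            sp = np.linalg.norm(v, axis=2) * np.linalg.norm(vn, axis=2)
            cosang = np.clip((v * vn).sum(-1) / sp, -1, 1)
            ang = np.arccos(cosang)
            keep &= (ang >= self.relative_heading[0]) \
                & (ang < self.relative_heading[1])
        if self.focal_speed is not None:
            sp = np.linalg.norm(v, axis=2)
            keep &= (sp >= self.focal_speed[0]) & (sp < self.focal_speed[1])
        if self.neighbor_speed is not None:
            sp = np.linalg.norm(v, axis=2)
            spn = np.linalg.norm(vn, axis=2)
            if self.neighbor_speed == "faster":
                keep &= spn > sp
            elif self.neighbor_speed == "slower":
                keep &= spn < sp
            else:
                raise ValueError("neighbor_speed must be 'faster' or "
                                 "'slower'")
        return keep


def collect_samples(traj: TrajectoryEnsemble, kind: str,
                    sample_filter: Optional[SampleFilter] = None,
                    neighbor: str = "nearest"
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Focal-frame (coordinate, acceleration) samples for a force map.

    Parameters
    ----------
    kind : "relative_position" or "relative_velocity"
    neighbor : "nearest" (default, one sample per focal per frame) or
        "voronoi" (one sample per focal--Voronoi-neighbor pair).

    Returns ``(coords, responses)``, each (M, 2).
    """
    if kind not in ("relative_position", "relative_velocity"):
        raise ValueError("kind must be 'relative_position' or "
                         "'relative_velocity'")
    x, v, a = traj.positions, traj.velocities, traj.accelerations
    T, n, _ = x.shape
    heading = traj.headings()

    if neighbor == "nearest":
        nn = nearest_neighbor_series(traj)
        keep = (np.ones((T, n), bool) if sample_filter is None
                else sample_filter.mask(traj, nn))
        rows = np.arange(T)[:, None]
        other_x, other_v = x[rows, nn], v[rows, nn]
        rel = (x - other_x) if kind == "relative_position" else (v - other_v)
        coords = focal_frame(rel, heading)[keep]
        responses = focal_frame(a, heading)[keep]
        return coords, responses

    if neighbor != "voronoi":
        raise ValueError("neighbor must be 'nearest' or 'voronoi'")
    coords_list, resp_list = [], []
    for t in range(T):
        adj = voronoi_adjacency(x[t]).adjacency
        i, j = np.nonzero(adj)
        rel = (x[t, i] - x[t, j] if kind == "relative_position"
               else v[t, i] - v[t, j])
        coords_list.append(focal_frame(rel, heading[t, i]))
        resp_list.append(focal_frame(a[t, i], heading[t, i]))
    return np.concatenate(coords_list), np.concatenate(resp_list)


# ---------------------------------------------------------------------------
# binning


@dataclass
class ForceMap:
    """2D binned mean-acceleration vector field with per-bin counts."""

    kind: str                 # "relative_position" | "relative_velocity"
    x_edges: np.ndarray
    y_edges: np.ndarray
    mean: np.ndarray          # (nx, ny, 2), NaN where count < min_count
    count: np.ndarray         # (nx, ny)
    min_count: int = 50

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def valid(self) -> np.ndarray:
        return self.count >= self.min_count

    @property
    def modulus(self) -> np.ndarray:
        return np.sqrt((self.mean ** 2).sum(-1))

    def bin_radii(self) -> np.ndarray:
        cx, cy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return np.sqrt(cx ** 2 + cy ** 2)

    def radial_projection(self) -> np.ndarray:
        """Per-bin component of the mean vector along the outward radial
        direction of the map; > 0 points away from the origin
        (repulsion/antialignment), < 0 toward it (attraction/alignment).
        NaN for invalid bins and for a bin centered at the origin.
        """
        cx, cy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        r = np.sqrt(cx ** 2 + cy ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            proj = (self.mean[..., 0] * cx + self.mean[..., 1] * cy) / r
        proj[r < 1e-12] = np.nan
        proj[~self.valid] = np.nan
        return proj

    def radial_profile(self, r_edges: Optional[np.ndarray] = None
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Angularly averaged radial projection vs distance from origin.

        Bins of the 2D map are pooled by their center radius, weighting
        each by its sample count.  Returns (r_centers, profile, counts);
        radial bins with no valid map bin are NaN.
        """
        proj = self.radial_projection()
        r = self.bin_radii()
        ok = np.isfinite(proj)
        if r_edges is None:
            width = self.x_edges[1] - self.x_edges[0]
            r_edges = np.arange(0.0, r.max() + width, width)
        idx = np.digitize(r[ok], r_edges) - 1
        nbin = len(r_edges) - 1
        wsum = np.zeros(nbin)
        psum = np.zeros(nbin)
        inside = (idx >= 0) & (idx < nbin)
        np.add.at(wsum, idx[inside], self.count[ok][inside])
        np.add.at(psum, idx[inside],
                  (proj[ok] * self.count[ok])[inside])
        with np.errstate(invalid="ignore"):
            prof = np.where(wsum > 0, psum / np.maximum(wsum, 1), np.nan)
        r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
        return r_centers, prof, wsum

    def to_dataframe(self) -> pd.DataFrame:
        """Quiver-ready table: bin_x, bin_y, Fx, Fy, modulus, count."""
        cx, cy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame({
            "bin_x": cx.ravel(), "bin_y": cy.ravel(),
            "Fx": self.mean[..., 0].ravel(),
            "Fy": self.mean[..., 1].ravel(),
            "modulus": self.modulus.ravel(),
            "count": self.count.ravel().astype(int)})

    def to_hdf5(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("x_edges", data=self.x_edges)
            fh.create_dataset("y_edges", data=self.y_edges)
            fh.create_dataset("mean", data=self.mean)
            fh.create_dataset("count", data=self.count)
            fh.attrs["kind"] = self.kind
            fh.attrs["min_count"] = self.min_count

    @classmethod
    def from_hdf5(cls, path: str) -> "ForceMap":
        import h5py
        with h5py.File(path, "r") as fh:
            return cls(kind=str(fh.attrs["kind"]),
                       x_edges=fh["x_edges"][...],
                       y_edges=fh["y_edges"][...],
                       mean=fh["mean"][...], count=fh["count"][...],
                       min_count=int(fh.attrs["min_count"]))


def symmetric_edges(extent: float, n_bins: int) -> np.ndarray:
    """Uniform bin edges on [-extent, extent], symmetric about 0."""
    return np.linspace(-extent, extent, n_bins + 1)


def bin_map(coords: np.ndarray, responses: np.ndarray,
            x_edges: np.ndarray, y_edges: np.ndarray,
            min_count: int = 50,
            kind: str = "relative_position") -> ForceMap:
    """Vector-mean the responses on a uniform 2D grid of the coordinates.

    Bins holding fewer than ``min_count`` samples are masked (NaN mean);
    samples outside the grid are dropped.
    """
    coords = np.asarray(coords, float).reshape(-1, 2)
    responses = np.asarray(responses, float).reshape(-1, 2)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    ix = np.digitize(coords[:, 0], x_edges) - 1
    iy = np.digitize(coords[:, 1], y_edges) - 1
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    flat = ix[ok] * ny + iy[ok]
    count = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    sums = np.empty((nx, ny, 2))
    for c in range(2):
        sums[..., c] = np.bincount(flat, weights=responses[ok, c],
                                   minlength=nx * ny).reshape(nx, ny)
    with np.errstate(invalid="ignore"):
        mean = sums / np.maximum(count, 1)[..., None]
    mean[count < min_count] = np.nan
    return ForceMap(kind=kind, x_edges=np.asarray(x_edges, float),
                    y_edges=np.asarray(y_edges, float), mean=mean,
                    count=count, min_count=min_count)


def force_map(traj: TrajectoryEnsemble, kind: str,
              sample_filter: Optional[SampleFilter] = None,
              neighbor: str = "nearest", extent: Optional[float] = None,
              n_bins: int = 30, min_count: int = 50) -> ForceMap:
    """Convenience wrapper: collect samples and bin them.

    Default extents: +/-20 cm for relative-position maps, +/-15 cm/s for
    relative-velocity maps.
    """
    if extent is None:
        extent = 20.0 if kind == "relative_position" else 15.0
    coords, responses = collect_samples(traj, kind, sample_filter, neighbor)
    edges = symmetric_edges(extent, n_bins)
    return bin_map(coords, responses, edges, edges, min_count, kind)


def radial_zero_crossing(r: np.ndarray, profile: np.ndarray
                         ) -> float:
    """Distance at which a radial profile first crosses + to - .

    Linear interpolation between the last positive and first negative
    adjacent finite values; NaN if no such crossing exists.
    """
    r = np.asarray(r, float)
    p = np.asarray(profile, float)
    ok = np.isfinite(p)
    r, p = r[ok], p[ok]
    for a in range(len(p) - 1):
        if p[a] > 0 >= p[a + 1]:
            return float(r[a] + (r[a + 1] - r[a]) * p[a] / (p[a] - p[a + 1]))
    return float("nan")


# ---------------------------------------------------------------------------
# smoothing / interpolation (explicit-antialignment driving field)


@dataclass
class TabulatedField:
    """Bilinearly interpolated 2D vector field on a regular grid.

    Queries outside the grid are clamped to the boundary value.  Used as
    the driving alignment force of the explicit-antialignment variant.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    values: np.ndarray        # (nx, ny, 2)
    _interp: Optional[RegularGridInterpolator] = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._interp = RegularGridInterpolator(
            (self.x_centers, self.y_centers), self.values,
            method="linear", bounds_error=False)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        shape = pts.shape
        pts = pts.reshape(-1, 2).copy()
        pts[:, 0] = np.clip(pts[:, 0], self.x_centers[0], self.x_centers[-1])
        pts[:, 1] = np.clip(pts[:, 1], self.y_centers[0], self.y_centers[-1])
        return self._interp(pts).reshape(shape)

    @classmethod
    def from_function(cls, func: Callable[[np.ndarray], np.ndarray],
                      extent: float, n_bins: int = 30) -> "TabulatedField":
        centers = 0.5 * (symmetric_edges(extent, n_bins)[:-1]
                         + symmetric_edges(extent, n_bins)[1:])
        cx, cy = np.meshgrid(centers, centers, indexing="ij")
        pts = np.stack([cx, cy], axis=-1)
        return cls(centers.copy(), centers.copy(),
                   np.asarray(func(pts), float))

    def to_csv(self, path: str) -> None:
        cx, cy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        pd.DataFrame({"x": cx.ravel(), "y": cy.ravel(),
                      "Fx": self.values[..., 0].ravel(),
                      "Fy": self.values[..., 1].ravel()}
                     ).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str) -> "TabulatedField":
        df = pd.read_csv(path)
        x = np.unique(df["x"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        vals = np.empty((len(x), len(y), 2))
        ix = np.searchsorted(x, df["x"].to_numpy())
        iy = np.searchsorted(y, df["y"].to_numpy())
        vals[ix, iy, 0] = df["Fx"].to_numpy()
        vals[ix, iy, 1] = df["Fy"].to_numpy()
        return cls(x, y, vals)


def smooth_and_interpolate_field(fmap: ForceMap,
                                 sigma_bins: float = 2.0) -> TabulatedField:
    """Gaussian-smooth a force map and expose bilinear interpolation.

    Masked bins are first filled with the value of the nearest valid bin
    so the smoothing kernel never mixes in mask sentinels; each vector
    component is then smoothed over the bin grid with a Gaussian of
    ``sigma_bins`` bins.
    """
    if not fmap.valid.any():
        raise ValueError("fully masked force map")
    filled = fmap.mean.copy()
    invalid = ~fmap.valid
    if invalid.any():
        _, (ii, jj) = ndimage.distance_transform_edt(
            invalid, return_indices=True)
        filled = filled[ii, jj]
    smoothed = np.stack(
        [ndimage.gaussian_filter(filled[..., c], sigma_bins, mode="nearest")
         for c in range(2)], axis=-1)
    return TabulatedField(fmap.x_centers, fmap.y_centers, smoothed)
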