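"""Trajectory container and columnar / HDF5 I/O.

A :class:`TrajectoryEnsemble` holds positions, velocities and
accelerations of ``n`` identified individuals on a uniform time grid.
Kinematics come either from the integrator (per-step realized
accelerations) or from the Gaussian-derivative preprocessing pipeline --
never mixed within one ensemble; ``metadata["kinematics"]`` records which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import h5py
import numpy as np
import pandas as pd

_COLUMNS = ["frame", "id", "x_cm", "y_cm", "vx", "vy", "ax", "ay"]


@dataclass
class TrajectoryEnsemble:
    """Positions/velocities/accelerations of n individuals over T frames.

    Arrays are shaped (T, n, 2); units cm, cm/s, cm/s^2; the time grid is
    uniform with spacing ``dt`` seconds.
    """

    positions: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray
    dt: float
    ids: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        self.accelerations = np.asarray(self.accelerations, float)
        if not (self.positions.shape == self.velocities.shape
                == self.accelerations.shape):
            raise ValueError("positions/velocities/accelerations shapes "
                             "must match")
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("expected arrays of shape (frames, n, 2)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.ids is None:
            self.ids = np.arange(self.n_individuals)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def speeds(self) -> np.ndarray:
        """(T, n) speed of every individual at every frame."""
        return np.linalg.norm(self.velocities, axis=2)

    def headings(self) -> np.ndarray:
        """(T, n, 2) unit velocity vectors."""
        s = self.speeds
        if np.any(s < 1e-12):
            raise ValueError("zero speed: heading undefined")
        return self.velocities / s[..., None]

    def slice_frames(self, start: int, stop: Optional[int] = None
                     ) -> "TrajectoryEnsemble":
        sl = slice(start, stop)
        return TrajectoryEnsemble(self.positions[sl], self.velocities[sl],
                                  self.accelerations[sl], self.dt,
                                  ids=self.ids, metadata=dict(self.metadata))

    # -- tabular I/O -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        T, n, _ = self.positions.shape
        frame = np.repeat(np.arange(T), n)
        ids = np.tile(self.ids, T)
        flat = [a.reshape(T * n, 2) for a in
                (self.positions, self.velocities, self.accelerations)]
        return pd.DataFrame({
            "frame": frame, "id": ids,
            "x_cm": flat[0][:, 0], "y_cm": flat[0][:, 1],
            "vx": flat[1][:, 0], "vy": flat[1][:, 1],
            "ax": flat[2][:, 0], "ay": flat[2][:, 1]})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float,
                       **metadata: Any) -> "TrajectoryEnsemble":
        df = df.sort_values(["frame", "id"], kind="stable")
        ids = np.sort(df["id"].unique())
        T = df["frame"].nunique()
        n = len(ids)
        if len(df) != T * n:
            raise ValueError("trajectory table is not a complete "
                             "frame x id grid")
        def grab(cols):
            return df[cols].to_numpy(float).reshape(T, n, 2)
        return cls(grab(["x_cm", "y_cm"]), grab(["vx", "vy"]),
                   grab(["ax", "ay"]), dt, ids=ids, metadata=metadata)

    def to_csv(self, path: str) -> None:
        df = self.to_dataframe()
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str, dt: float, **metadata: Any
                 ) -> "TrajectoryEnsemble":
        return cls.from_dataframe(pd.read_csv(path), dt, **metadata)

    # -- binary container ------------------------------------------------

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions", data=self.positions)
            fh.create_dataset("velocities", data=self.velocities)
            fh.create_dataset("accelerations", data=self.accelerations)
            fh.create_dataset("ids", data=np.asarray(self.ids))
            fh.attrs["dt"] = self.dt
            for k, v in self.metadata.items():
                if isinstance(v, (int, float, str, bool)):
                    fh.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str) -> "TrajectoryEnsemble":
        with h5py.File(path, "r") as fh:
            meta = {k: v for k, v in fh.attrs.items() if k != "dt"}
            return cls(fh["positions"][...], fh["velocities"][...],
                       fh["accelerations"][...], float(fh.attrs["dt"]),
                       ids=fh["ids"][...], metadata=meta)
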