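"""Container for 3D marker trajectories from optical motion capture.

Coordinate convention used throughout the package: ``x`` is the direction
of travel (anterior), ``y`` is vertical (up), ``z`` is mediolateral.
Units are metres; time is derived from the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Markers every trajectory set must carry, on both sides ("L_" / "R_").
REQUIRED_MARKERS = ("heel", "toe", "ankle", "knee", "hip", "shoulder")


def required_marker_names() -> list[str]:
    """Bilateral marker names required by the feature extractors."""
    return [f"{side}_{m}" for side in ("L", "R") for m in REQUIRED_MARKERS]


@dataclass
class MarkerTrajectorySet:
    """Time-indexed 3D positions for a named marker set.

    Parameters
    ----------
    marker_names
        Ordered marker labels; must include heel, toe, ankle, knee, hip and
        shoulder for both sides (prefixes ``L_`` and ``R_``).  The left side
        is the perturbed limb, the right side the unperturbed limb.
    positions
        Array of shape ``(n_frames, n_markers, 3)`` holding (x, y, z) in
        metres.
    sampling_rate
        Frames per second (Hz).
    meta
        Free-form metadata (e.g. ground-truth values for synthetic trials).
    """

    marker_names: list[str]
    positions: np.ndarray
    sampling_rate: float = 120.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must be (frames, markers, 3); got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.marker_names):
            raise ValueError(
                f"{len(self.marker_names)} marker names but "
                f"{self.positions.shape[1]} marker columns"
            )
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in marker trajectories")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        missing = [m for m in required_marker_names() if m not in self.marker_names]
        if missing:
            raise ValueError(f"required markers missing: {missing}")
        self._index = {m: i for i, m in enumerate(self.marker_names)}

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time stamps in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.sampling_rate

    def marker(self, name: str) -> np.ndarray:
        """Full (n_frames, 3) trajectory of one marker."""
        try:
            return self.positions[:, self._index[name], :]
        except KeyError:
            raise KeyError(f"marker {name!r} not in trajectory set") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns frame, time_s, marker, x, y, z."""
        n, m, _ = self.positions.shape
        frames = np.repeat(np.arange(n), m)
        rows = pd.DataFrame(
            {
                "frame": frames,
                "time_s": frames / self.sampling_rate,
                "marker": np.tile(np.asarray(self.marker_names, dtype=object), n),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "z": self.positions[:, :, 2].ravel(),
            }
        )
        return rows

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sampling_rate: float | None = None) -> "MarkerTrajectorySet":
        """Rebuild a trajectory set from the long-format table."""
        required_cols = {"frame", "marker", "x", "y", "z"}
        missing = required_cols - set(df.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        if sampling_rate is None:
            if "time_s" not in df.columns:
                raise ValueError("sampling_rate not given and no time_s column")
            per_frame = df.drop_duplicates("frame").sort_values("frame")
            dt = np.diff(per_frame["time_s"].to_numpy())
            if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time_s does not define a constant sampling interval")
            sampling_rate = 1.0 / dt[0]
        markers = list(pd.unique(df["marker"]))
        wide = df.pivot_table(index="frame", columns="marker", values=["x", "y", "z"], sort=False)
        wide = wide.sort_index()
        n = len(wide)
        pos = np.empty((n, len(markers), 3))
        for j, m in enumerate(markers):
            for k, axis in enumerate(("x", "y", "z")):
                pos[:, j, k] = wide[(axis, m)].to_numpy()
        return cls(marker_names=markers, positions=pos, sampling_rate=float(sampling_rate))

    @classmethod
    def from_csv(cls, path, sampling_rate: float | None = None) -> "MarkerTrajectorySet":
        return cls.from_frame(pd.read_csv(path), sampling_rate=sampling_rate)
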