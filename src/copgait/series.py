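"""Core time-series containers shared across the package.

All positions are in millimetres, angular velocities in rad/s, and the
accelerometer/magnetometer channels are unit-normalized field *directions*
(dimensionless).  Time grids are uniform at the session sampling rate
(100 Hz by default, step 0.01 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

SEGMENT_OF_LOCATION: dict[int, str] = {
    2: "back",
    3: "right_thigh",
    4: "right_shank",
    5: "right_foot",
    6: "left_thigh",
    7: "left_shank",
    8: "left_foot",
}
LOCATION_OF_SEGMENT: dict[str, int] = {v: k for k, v in SEGMENT_OF_LOCATION.items()}
SEGMENTS = tuple(SEGMENT_OF_LOCATION.values())
LOCATIONS = tuple(SEGMENT_OF_LOCATION.keys())

#: axis labels in the canonical 9-channel order of one IMU
GAM_CHANNELS = ("gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz")


def _check_uniform_time(t: np.ndarray) -> float:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(t[-1])):
        raise ValueError("time grid must have a constant step")
    return float(dt[0])


@dataclass
class QuaternionSeries:
    """Unit-quaternion orientation track of one body segment."""

    t: np.ndarray
    q: np.ndarray  # (n, 4) scalar-first, sensor→earth
    segment_label: str = "back"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ValueError("q must have shape (n, 4)")
        if self.t.shape[0] != self.q.shape[0]:
            raise ValueError("t and q length mismatch")

    @property
    def dt(self) -> float:
        return _check_uniform_time(self.t)

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class GamSeries:
    """Raw 9-channel IMU signal of one sensor: gyro (rad/s), accel and
    magnetometer direction channels (unit-normalized, dimensionless)."""

    t: np.ndarray
    g: np.ndarray  # (n, 3) rad/s, sensor frame
    a: np.ndarray  # (n, 3) gravity direction, sensor frame
    m: np.ndarray  # (n, 3) magnetic direction, sensor frame

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("g", "a", "m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.t.shape[0], 3):
                raise ValueError(f"{name} must have shape (n, 3) matching t")
            setattr(self, name, arr)

    def as_matrix(self) -> np.ndarray:
        """(n, 9) matrix in the canonical gx..gz, ax..az, mx..mz order."""
        return np.hstack([self.g, self.a, self.m])

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class CopSeries:
    """2-D centre-of-pressure trajectory: x anterior, y lateral, in mm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame: str = "pelvis"  # "treadmill" or "pelvis"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.t.shape or self.y.shape != self.t.shape:
            raise ValueError("t, x, y must share shape")
        if self.frame not in ("treadmill", "pelvis"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("COP values must be finite")

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class Session:
    """Synchronized bundle of a 7-IMU constellation, COP, pelvis track and
    per-sample protocol-step labels.

    ``imu`` maps the location labels 2..8 (back, right/left thigh, shank,
    foot) to :class:`GamSeries`.  The earth-reference unit (location 1) is
    not a model input and is not stored.
    """

    rate_hz: float
    t: np.ndarray
    imu: Mapping[int, GamSeries]
    cop: CopSeries
    pelvis: np.ndarray  # (n, 2) mm, treadmill frame
    step_labels: np.ndarray  # (n,) int
    protocol: list | None = None  # list of ProtocolStep, if known
    segment_quats: Mapping[int, QuaternionSeries] | None = field(
        default=None, repr=False
    )  # noiseless generator orientations, kept for round-trip checks

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        self.pelvis = np.asarray(self.pelvis, dtype=float)
        self.step_labels = np.asarray(self.step_labels)
        bad = set(self.imu) - set(LOCATIONS)
        if bad:
            raise ValueError(f"unknown IMU location labels: {sorted(bad)}")
        for loc, series in self.imu.items():
            if len(series) != n:
                raise ValueError(f"IMU {loc} series length mismatch")
        if len(self.cop) != n or self.pelvis.shape != (n, 2) or self.step_labels.shape != (n,):
            raise ValueError("all session series must share length")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def step_runs(self) -> list[tuple[int, slice]]:
        """Contiguous runs of constant step label (and contiguous time)."""
        labels = self.step_labels
        dt = 1.0 / self.rate_hz
        breaks = [0]
        for k in range(1, self.n_samples):
            if labels[k] != labels[k - 1] or (self.t[k] - self.t[k - 1]) > 1.5 * dt:
                breaks.append(k)
        breaks.append(self.n_samples)
        return [
            (int(labels[breaks[i]]), slice(breaks[i], breaks[i + 1]))
            for i in range(len(breaks) - 1)
        ]

    def take(self, idx: np.ndarray) -> "Session":
        """New session holding the given sample indices (in order)."""
        idx = np.asarray(idx)
        imu = {
            loc: GamSeries(s.t[idx], s.g[idx], s.a[idx], s.m[idx])
            for loc, s in self.imu.items()
        }
        cop = CopSeries(self.cop.t[idx], self.cop.x[idx], self.cop.y[idx], self.cop.frame)
        quats = None
        if self.segment_quats is not None:
            quats = {
                loc: QuaternionSeries(qs.t[idx], qs.q[idx], qs.segment_label)
                for loc, qs in self.segment_quats.items()
            }
        return Session(
            rate_hz=self.rate_hz,
            t=self.t[idx],
            imu=imu,
            cop=cop,
            pelvis=self.pelvis[idx],
            step_labels=self.step_labels[idx],
            protocol=self.protocol,
            segment_quats=quats,
        )
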