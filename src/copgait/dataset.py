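"""Session handling: coordinate frames, channel/IMU selection, history
windowing, train/test splitting and CSV I/O.

Design-matrix column order (stable, documented contract): IMU locations in
ascending label order; within an IMU the selected components in G, A, M
order; within a component the x, y, z axes; within an axis the history lags
newest first (lag 0 = current sample, lag 1 = one sample earlier, ...).
Selecting a subset of IMUs or components therefore yields exactly the
corresponding column subset of the full matrix.

History windows cover the most recent ``history`` samples *including* the
current one (10 samples ≡ 0.1 s at 100 Hz) and never straddle a
protocol-step boundary: windows are built per contiguous step run and the
first ``history − 1`` samples of each run are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import CopSeries, GamSeries, LOCATIONS, Session

__all__ = [
    "ChannelSpec",
    "cop_to_pelvis_frame",
    "build_windows",
    "build_design_matrix",
    "split_train_test",
    "sample_contiguous_train",
    "write_session_csv",
    "read_session_csv",
]

_COMPONENT_SLICE = {"G": slice(0, 3), "A": slice(3, 6), "M": slice(6, 9)}


@dataclass(frozen=True)
class ChannelSpec:
    """Input-channel selection: components ⊆ {G, A, M}, IMU locations
    ⊆ {2..8}, and history length in samples (≥ 1)."""

    components: tuple[str, ...] = ("G", "A", "M")
    imus: tuple[int, ...] = LOCATIONS
    history: int = 1

    def __post_init__(self) -> None:
        comps = tuple(c for c in "GAM" if c in self.components)
        if not comps or set(self.components) - set("GAM"):
            raise ValueError("components must be a non-empty subset of {G, A, M}")
        object.__setattr__(self, "components", comps)
        imus = tuple(sorted(set(int(i) for i in self.imus)))
        if not imus or set(imus) - set(LOCATIONS):
            raise ValueError("imus must be a non-empty subset of {2..8}")
        object.__setattr__(self, "imus", imus)
        if int(self.history) < 1:
            raise ValueError("history must be ≥ 1")
        object.__setattr__(self, "history", int(self.history))

    @property
    def width(self) -> int:
        """Channels per time sample: 3 axes × components × IMUs."""
        return 3 * len(self.components) * len(self.imus)

    @property
    def n_features(self) -> int:
        """Design-matrix feature count: width × history."""
        return self.width * self.history

    @classmethod
    def from_string(cls, components: str, imus=LOCATIONS, history: int = 1) -> "ChannelSpec":
        return cls(tuple(components.upper()), tuple(imus), history)

    def to_dict(self) -> dict:
        return {
            "components": list(self.components),
            "imus": list(self.imus),
            "history": self.history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSpec":
        return cls(tuple(d["components"]), tuple(d["imus"]), int(d["history"]))


def cop_to_pelvis_frame(cop: CopSeries, pelvis: np.ndarray) -> CopSeries:
    """Translate a treadmill-frame COP into the pelvis-centred frame.

    Componentwise subtraction of the pelvis-centre track; the transform is
    translation-only (axes stay treadmill-aligned).  Applying it to a COP
    already tagged as pelvis-frame is an error.
    """
    if cop.frame == "pelvis":
        raise ValueError("COP is already in the pelvis frame")
    pelvis = np.asarray(pelvis, dtype=float)
    if pelvis.shape != (len(cop), 2):
        raise ValueError("pelvis track must have shape (n, 2) matching the COP")
    return CopSeries(
        t=cop.t.copy(),
        x=cop.x - pelvis[:, 0],
        y=cop.y - pelvis[:, 1],
        frame="pelvis",
    )


def _channel_matrix(session: Session, spec: ChannelSpec) -> np.ndarray:
    """(n, width) matrix of the selected channels in canonical order."""
    cols = []
    for loc in spec.imus:
        if loc not in session.imu:
            raise ValueError(f"session has no IMU at location {loc}")
        mat = session.imu[loc].as_matrix()
        for comp in spec.components:
            cols.append(mat[:, _COMPONENT_SLICE[comp]])
    return np.hstack(cols)


def build_windows(
    session: Session, spec: ChannelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample history windows and targets for sequence models.

    Returns ``(W, Y)`` with ``W`` of shape (n, history, width) ordered
    oldest → newest along the time axis, and ``Y`` of shape (n, 2) holding
    (COPx, COPy) at the window's final (current) sample.  Windows are built
    within contiguous protocol-step runs only.
    """
    if session.cop.frame != "pelvis":
        raise ValueError("session COP must be in the pelvis frame")
    Z = _channel_matrix(session, spec)
    Y_full = session.cop.as_array()
    h = spec.history

    wins, targets = [], []
    for _, sl in session.step_runs():
        z = Z[sl]
        n = z.shape[0]
        if n < h:
            continue
        idx = np.arange(h)[None, :] + np.arange(n - h + 1)[:, None]
        wins.append(z[idx])
        targets.append(Y_full[sl][h - 1 :])
    if not wins:
        raise ValueError("no step run is long enough for the requested history")
    return np.concatenate(wins, axis=0), np.concatenate(targets, axis=0)


def build_design_matrix(
    session: Session, spec: ChannelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Flat regression design matrix and targets.

    Row k concatenates, per channel, the samples at lags 0 … history−1
    (newest first); feature count is ``spec.n_features``.
    """
    W, Y = build_windows(session, spec)
    # W is (n, h, width) oldest→newest; flatten to channel-major, lag-newest-first
    X = W[:, ::-1, :].transpose(0, 2, 1).reshape(W.shape[0], -1)
    return X, Y


def split_train_test(
    session: Session, train_fraction: float = 0.5
) -> tuple[Session, Session]:
    """Within every protocol step, first ``⌊fraction·n⌋`` samples train,
    the remainder test (both non-empty for every step)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    train_idx, test_idx = [], []
    for _, sl in session.step_runs():
        n = sl.stop - sl.start
        if n < 2:
            raise ValueError("every protocol step needs at least 2 samples to split")
        k = int(np.floor(train_fraction * n))
        k = min(max(k, 1), n - 1)
        train_idx.append(np.arange(sl.start, sl.start + k))
        test_idx.append(np.arange(sl.start + k, sl.stop))
    return (
        session.take(np.concatenate(train_idx)),
        session.take(np.concatenate(test_idx)),
    )


def sample_contiguous_train(
    session: Session, size_s: float, rng: np.random.Generator
) -> tuple[Session, Session]:
    """One uniformly-random contiguous block of ``size_s`` seconds as the
    train view; the complement (possibly two pieces) as the test view."""
    n_block = int(round(size_s * session.rate_hz))
    n = session.n_samples
    if n_block < 1:
        raise ValueError("block size must cover at least one sample")
    if n_block >= n:
        raise ValueError("train block must leave a non-empty test set")
    start = int(rng.integers(0, n - n_block + 1))
    block = np.arange(start, start + n_block)
    rest = np.concatenate([np.arange(0, start), np.arange(start + n_block, n)])
    return session.take(block), session.take(rest)


# ---------------------------------------------------------------------------
# CSV interface


def write_session_csv(path, session: Session) -> None:
    """Write the session as a flat CSV (full float precision round trip)."""
    data: dict[str, np.ndarray] = {"time_s": session.t, "step_label": session.step_labels}
    for loc in sorted(session.imu):
        mat = session.imu[loc].as_matrix()
        for j, ch in enumerate(("gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz")):
            data[f"imu{loc}_{ch}"] = mat[:, j]
    data["copx_mm"] = session.cop.x
    data["copy_mm"] = session.cop.y
    data["pelvis_x_mm"] = session.pelvis[:, 0]
    data["pelvis_y_mm"] = session.pelvis[:, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_session_csv(path, rate_hz: float = 100.0, cop_frame: str = "pelvis") -> Session:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    imu = {}
    for loc in LOCATIONS:
        cols = [f"imu{loc}_{ch}" for ch in ("gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz")]
        if all(c in df.columns for c in cols):
            mat = df[cols].to_numpy()
            imu[loc] = GamSeries(t=t, g=mat[:, 0:3], a=mat[:, 3:6], m=mat[:, 6:9])
    if not imu:
        raise ValueError("no IMU channel columns found in session file")
    for required in ("copx_mm", "copy_mm", "pelvis_x_mm", "pelvis_y_mm", "step_label"):
        if required not in df.columns:
            raise ValueError(f"session file is missing column {required!r}")
    cop = CopSeries(
        t=t, x=df["copx_mm"].to_numpy(), y=df["copy_mm"].to_numpy(), frame=cop_frame
    )
    return Session(
        rate_hz=rate_hz,
        t=t,
        imu=imu,
        cop=cop,
        pelvis=df[["pelvis_x_mm", "pelvis_y_mm"]].to_numpy(),
        step_labels=df["step_label"].to_numpy(dtype=int),
    )


def write_channel_spec(path, spec: ChannelSpec) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)


def read_channel_spec(path) -> ChannelSpec:
    with open(path) as fh:
        return ChannelSpec.from_dict(json.load(fh))
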