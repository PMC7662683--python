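"""Seeded synthetic treadmill-walking sessions.

The generator emulates the measurement setting the package targets: seven
body-worn IMUs (lower back, both thighs, shanks and feet) sampled at 100 Hz
while a subject walks at slow treadmill speeds, with the net ("global")
centre of pressure expressed in a pelvis-centred frame.  Over each gait
cycle that COP traces the characteristic butterfly: it dwells under the
stance foot (offset laterally by half the step width) while advancing
anteriorly, then sweeps diagonally to the other foot during double support.

Design of the kinematics:

* One periodic cycle *template* (anterior and lateral COP as a function of
  cycle fraction u ∈ [0,1)) is built piecewise from the gait parameters and
  smoothed circularly; a mirror-symmetrization step makes the symmetric
  (asymmetry = 0) template exactly antisymmetric in the lateral component
  under u → u + ½.
* Segment orientations are driven by the same cycle clock.  The back
  (pelvis) segment is pelvis-driven in the strong sense: its roll/pitch
  carry the first harmonics of the lateral/anterior COP templates, so the
  lower back is the single most informative sensor, as expected for a
  quantity tied to the motion of the body centre of mass.  Limb segments
  carry generic first/second-harmonic flexion patterns with side-specific
  phases.
* Raw signals are synthesized from the orientation tracks through
  :func:`copgait.orientation.quat_to_gam` and corrupted with zero-mean
  Gaussian noise of standard deviation ``noise_rel`` × the channel's RMS
  (default 3%, the fluctuation size of a static sensor relative to walking
  signals).  The treadmill-side ground truth (COP, pelvis track) is left
  noiseless: the instrumented treadmill is the reference instrument.

Mediolateral perturbations (10/15% body weight, 150 ms) appear only inside
perturbation-labelled protocol steps as lateral COP deflections with ≥ 6 s
recovery spacing, mirrored by a small balance-response roll of the trunk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import quaternion as qt
from .orientation import ReferenceFields, quat_to_gam
from .series import CopSeries, GamSeries, QuaternionSeries, SEGMENT_OF_LOCATION, Session

__all__ = [
    "GaitParams",
    "ProtocolStep",
    "make_protocol",
    "simulate_session",
    "simulate_linear_session",
    "LinearCopTruth",
    "make_cohort",
]

SPEED_REF = 0.5  # m/s; amplitudes and cadence are specified at this speed
PERTURB_GAIN_MM_PER_PCT = 3.0  # lateral COP deflection per % body weight
LEAN_TILT_RAD_PER_MM = 0.002  # habitual-lean trunk tilt accompanying a COP offset


@dataclass(frozen=True)
class GaitParams:
    """Subject-level gait parameters of the synthetic generator.

    ``cadence`` (steps/s), ``step_length``/``step_width`` (mm) and
    ``double_support_fraction`` (fraction of each step spent in double
    support) are specified at the 0.5 m/s reference speed and scale with
    the protocol speed.  ``asymmetry`` in [0, 1] skews left/right dwell and
    excursion (0 = symmetric).  ``noise_rel`` is the relative sensor-noise
    amplitude (default 0.03).  ``lean_x_mm``/``lean_y_mm`` encode a habitual
    postural lean: a constant COP offset accompanied by a matching static
    trunk tilt.
    """

    cadence: float = 1.4
    step_length: float = 500.0
    step_width: float = 100.0
    double_support_fraction: float = 0.25
    asymmetry: float = 0.0
    noise_rel: float = 0.03
    perturb_force_pct: float = 0.0
    perturb_duration_s: float = 0.15
    lean_x_mm: float = 0.0
    lean_y_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.step_width < 0:
            raise ValueError("step_width must be non-negative")
        if not (0.0 < self.double_support_fraction < 0.5):
            raise ValueError("double_support_fraction must lie in (0, 0.5)")
        if not (0.0 <= self.asymmetry <= 1.0):
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be non-negative")
        if self.perturb_force_pct not in (0, 10, 15):
            raise ValueError("perturb_force_pct must be one of {0, 10, 15}")
        if self.perturb_duration_s <= 0:
            raise ValueError("perturb_duration_s must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GaitParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class ProtocolStep:
    """One step of a measurement protocol."""

    speed: float  # m/s
    perturb_pct: float  # % body weight
    duration_s: float
    label: str

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("step duration must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")


_HEALTHY_PROTOCOL = [
    (0.0, 0, 30.0, "QS"),
    (0.38, 0, 180.0, "walk_0.38"),
    (0.38, 10, 420.0, "walk_0.38_p10"),
    (0.38, 15, 420.0, "walk_0.38_p15"),
    (0.5, 0, 180.0, "walk_0.50"),
    (0.5, 10, 420.0, "walk_0.50_p10"),
    (0.5, 15, 420.0, "walk_0.50_p15"),
    (0.8, 0, 180.0, "walk_0.80"),
    (0.0, 0, 30.0, "QS_end"),
]

_STROKE_PROTOCOL = [
    (0.0, 0, 30.0, "QS"),
    (0.38, 0, 180.0, "walk_0.38"),
    (0.38, 10, 420.0, "walk_0.38_p10"),
    (0.5, 0, 180.0, "walk_0.50"),
    (0.5, 10, 420.0, "walk_0.50_p10"),
    (0.0, 0, 30.0, "QS_end"),
]


def make_protocol(subject_class: str = "healthy") -> list[ProtocolStep]:
    """Measurement protocol schedule for a subject class.

    Healthy subjects: 9 steps (quiet standing, then walking at 0.38, 0.5 and
    0.8 m/s with 0/10/15 %BW mediolateral perturbations, quiet standing).
    Stroke subjects: 6 steps (0.8 m/s and 15 %BW steps omitted).
    """
    table = {"healthy": _HEALTHY_PROTOCOL, "stroke": _STROKE_PROTOCOL}.get(subject_class)
    if table is None:
        raise ValueError(f"unknown subject class {subject_class!r}")
    return [ProtocolStep(*row) for row in table]


# ---------------------------------------------------------------------------
# cycle template


def _circular_gaussian_smooth(y: np.ndarray, sigma_frac: float) -> np.ndarray:
    """Gaussian smoothing on a periodic signal, via the Fourier multiplier."""
    M = y.shape[0]
    Y = np.fft.rfft(y)
    k = np.arange(Y.shape[0], dtype=float)
    Y *= np.exp(-0.5 * (2.0 * np.pi * k * sigma_frac) ** 2)
    return np.fft.irfft(Y, n=M)


def _truncate_harmonics(y: np.ndarray, k_max: int) -> np.ndarray:
    Y = np.fft.rfft(y)
    Y[k_max + 1 :] = 0.0
    return np.fft.irfft(Y, n=y.shape[0])


def _cop_cycle_template(params: GaitParams, M: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Anterior/lateral COP over one gait cycle at the reference speed.

    Returns (x_template, y_template) in mm, sampled on M points of u∈[0,1).
    Cycle layout: right single support, double support 1, left single
    support, double support 2.  Asymmetry shortens the left stance dwell and
    shrinks left-side excursions.
    """
    a = params.asymmetry
    d = params.double_support_fraction
    h_r = 0.5 * (1.0 + 0.3 * a)  # right step occupies the larger share
    h_l = 1.0 - h_r
    w_r = 0.5 * params.step_width * (1.0 + 0.5 * a)
    w_l = 0.5 * params.step_width * (1.0 - 0.5 * a)
    x_r = 0.2 * params.step_length * (1.0 + 0.5 * a)
    x_l = 0.2 * params.step_length * (1.0 - 0.5 * a)

    u = np.arange(M) / M
    knots = np.array([0.0, h_r * (1.0 - d), h_r, 1.0 - h_l * d, 1.0])
    y_vals = np.array([w_r, w_r, -w_l, -w_l, w_r])
    x_vals = np.array([x_r, -x_r, x_l, -x_l, x_r])
    y = np.interp(u, knots, y_vals)
    x = np.interp(u, knots, x_vals)

    if a == 0.0:
        # enforce exact half-cycle mirror symmetry on the discrete grid
        half = M // 2
        y = 0.5 * (y - np.roll(y, half))
        x = 0.5 * (x + np.roll(x, half))

    sigma = 0.015  # cycle fractions; shapes the sharpness of the butterfly
    return _circular_gaussian_smooth(x, sigma), _circular_gaussian_smooth(y, sigma)


# body-segment angle patterns over the cycle, (harmonic, amplitude, phase)
# triples per Euler angle; left-side segments reuse them half a cycle later
_LIMB_PATTERNS = {
    "thigh": {
        "pitch": [(1, 0.35, 0.0), (2, 0.09, 0.6)],
        "roll": [(1, 0.04, 1.1)],
        "yaw": [(1, 0.03, -0.4)],
    },
    "shank": {
        "pitch": [(1, 0.50, -0.5), (2, 0.22, -0.2)],
        "roll": [(1, 0.05, 0.8)],
        "yaw": [(1, 0.04, 0.3)],
    },
    "foot": {
        "pitch": [(1, 0.30, -1.0), (2, 0.15, 0.3)],
        "roll": [(1, 0.03, -0.9)],
        "yaw": [(1, 0.03, 1.4)],
    },
}

_BACK_HARMONICS = 4  # cycle harmonics of the COP carried by the trunk
_BACK_ROLL_AMP = 0.06  # rad, at reference speed
_BACK_PITCH_AMP = 0.05
_BACK_YAW_AMP = 0.07

_SWAY_FREQS_HZ = (0.23, 0.41)  # quiet-standing postural sway components
_SWAY_AMPS_MM = (2.5, 1.2)
_SWAY_TILT_RAD_PER_MM = 0.002


def _eval_pattern(pattern, u: np.ndarray, phase_shift: float = 0.0, scale: float = 1.0):
    out = np.zeros_like(u)
    for harmonic, amp, phase in pattern:
        out += scale * amp * np.sin(2.0 * np.pi * harmonic * (u + phase_shift) + phase)
    return out


def _perturbation_track(
    n: int,
    rate_hz: float,
    pct: float,
    rng: np.random.Generator,
    duration_s: float,
) -> np.ndarray:
    """Lateral deflection pulses with ≥ 6 s spacing, zero outside events."""
    track = np.zeros(n)
    if pct <= 0:
        return track
    t_end = n / rate_hz
    amp = PERTURB_GAIN_MM_PER_PCT * pct
    tau = max(duration_s, 0.05)
    t_event = 5.0
    while t_event + 4.0 < t_end:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        k0 = int(round(t_event * rate_hz))
        span = int(round(min(3.0, t_end - t_event) * rate_hz))
        tt = np.arange(span) / rate_hz
        pulse = sign * amp * (tt / tau) * np.exp(1.0 - tt / tau)
        track[k0 : k0 + span] += pulse[: max(0, n - k0)]
        t_event += 6.0 + 2.0 * rng.random()  # ≥ 6 s recovery between events
    return track


def simulate_session(
    params: GaitParams,
    protocol: Sequence[ProtocolStep] | None = None,
    rate_hz: float = 100.0,
    ref: ReferenceFields | None = None,
) -> Session:
    """Simulate one synchronized 7-IMU + COP walking session.

    Deterministic given ``params.seed``; the kinematics stream and the
    sensor-noise stream are decoupled, so changing ``noise_rel`` (or only
    the noise draw) never alters the underlying motion.
    """
    if protocol is None:
        protocol = make_protocol("healthy")
    protocol = list(protocol)
    if not protocol:
        raise ValueError("protocol must contain at least one step")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    ref = ref or ReferenceFields()

    ss = np.random.SeedSequence(params.seed)
    kin_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    dt = 1.0 / rate_hz
    n_steps = [int(round(s.duration_s * rate_hz)) for s in protocol]
    n_total = int(np.sum(n_steps))
    t = np.arange(n_total) * dt

    speed_raw = np.concatenate(
        [np.full(n, s.speed) for n, s in zip(n_steps, protocol)]
    )
    step_labels = np.concatenate(
        [np.full(n, i, dtype=int) for i, n in enumerate(n_steps)]
    )

    # smooth speed transitions over ~1 s so angular velocities stay bounded
    speed_s = gaussian_filter1d(speed_raw, sigma=rate_hz * 0.5, mode="nearest")
    s_amp = np.sqrt(speed_s / SPEED_REF)
    f_cycle = 0.5 * params.cadence * s_amp  # cycle (stride) frequency, Hz
    u = np.cumsum(f_cycle) * dt
    u -= u[0]
    u %= 1.0

    # --- COP in the pelvis frame -----------------------------------------
    x_tpl, y_tpl = _cop_cycle_template(params)
    M = x_tpl.shape[0]
    idx = u * M
    cop_x = s_amp * np.interp(idx, np.arange(M + 1), np.append(x_tpl, x_tpl[0]))
    cop_y = s_amp * np.interp(idx, np.arange(M + 1), np.append(y_tpl, y_tpl[0]))

    # quiet-standing sway, faded out once the belt moves
    sway_gate = np.clip(1.0 - speed_s / 0.1, 0.0, 1.0)
    sway_phases = kin_rng.uniform(0, 2 * np.pi, size=4)
    sway_x = sum(
        a * np.sin(2 * np.pi * f * t + p)
        for a, f, p in zip(_SWAY_AMPS_MM, _SWAY_FREQS_HZ, sway_phases[:2])
    )
    sway_y = sum(
        a * np.sin(2 * np.pi * f * t + p)
        for a, f, p in zip(_SWAY_AMPS_MM, _SWAY_FREQS_HZ, sway_phases[2:])
    )
    cop_x = cop_x + sway_gate * sway_x + params.lean_x_mm
    cop_y = cop_y + sway_gate * sway_y + params.lean_y_mm

    # mediolateral perturbation deflections, per perturbation-labelled step
    perturb = np.zeros(n_total)
    offset = 0
    for n, step in zip(n_steps, protocol):
        if step.perturb_pct > 0:
            perturb[offset : offset + n] = _perturbation_track(
                n, rate_hz, step.perturb_pct, kin_rng, params.perturb_duration_s
            )
        offset += n
    cop_y = cop_y + perturb

    # --- segment orientation tracks ---------------------------------------
    x_enc = _truncate_harmonics(x_tpl, _BACK_HARMONICS)
    y_enc = _truncate_harmonics(y_tpl, _BACK_HARMONICS)
    x_enc /= max(np.max(np.abs(x_enc)), 1e-9)
    y_enc /= max(np.max(np.abs(y_enc)), 1e-9)
    back_pitch_cycle = _BACK_PITCH_AMP * np.interp(
        idx, np.arange(M + 1), np.append(x_enc, x_enc[0])
    )
    back_roll_cycle = _BACK_ROLL_AMP * np.interp(
        idx, np.arange(M + 1), np.append(y_enc, y_enc[0])
    )

    lean_pitch = LEAN_TILT_RAD_PER_MM * params.lean_x_mm
    lean_roll = LEAN_TILT_RAD_PER_MM * params.lean_y_mm
    sway_pitch = _SWAY_TILT_RAD_PER_MM * sway_gate * sway_x
    sway_roll = _SWAY_TILT_RAD_PER_MM * sway_gate * sway_y

    angles: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    angles[2] = (
        _BACK_YAW_AMP * s_amp * np.sin(2 * np.pi * u),
        s_amp * back_pitch_cycle + lean_pitch + sway_pitch,
        s_amp * back_roll_cycle + lean_roll + sway_roll + 0.0015 * perturb,
    )

    left_scale = 1.0 - 0.5 * params.asymmetry
    for seg_kind, right_loc, left_loc in (
        ("thigh", 3, 6),
        ("shank", 4, 7),
        ("foot", 5, 8),
    ):
        pat = _LIMB_PATTERNS[seg_kind]
        for loc, shift, scale in ((right_loc, 0.0, 1.0), (left_loc, 0.5, left_scale)):
            angles[loc] = (
                s_amp * _eval_pattern(pat["yaw"], u, shift, scale),
                s_amp * _eval_pattern(pat["pitch"], u, shift, scale)
                + sway_pitch * 0.3,
                s_amp * _eval_pattern(pat["roll"], u, shift, scale)
                + sway_roll * 0.3,
            )

    quats: dict[int, QuaternionSeries] = {}
    imu: dict[int, GamSeries] = {}
    for loc, (yaw, pitch, roll) in angles.items():
        q = qt.sign_align(qt.from_euler_zyx(yaw, pitch, roll))
        qs = QuaternionSeries(t=t, q=q, segment_label=SEGMENT_OF_LOCATION[loc])
        quats[loc] = qs
        gam = quat_to_gam(qs, ref)
        if params.noise_rel > 0:
            for arr in (gam.g, gam.a, gam.m):
                rms = np.sqrt(np.mean(arr**2, axis=0))
                arr += noise_rng.normal(0.0, params.noise_rel * rms, size=arr.shape)
        imu[loc] = gam

    # pelvis-centre track in the treadmill frame: bounded oscillation about
    # the belt centre (step-frequency bob + stride-frequency sway)
    pelvis = np.column_stack(
        [
            8.0 * s_amp * np.sin(4 * np.pi * u) + 0.3 * sway_gate * sway_x,
            12.0 * s_amp * np.sin(2 * np.pi * u + 0.4) + 0.3 * sway_gate * sway_y,
        ]
    )

    cop = CopSeries(t=t, x=cop_x, y=cop_y, frame="pelvis")
    return Session(
        rate_hz=rate_hz,
        t=t,
        imu=imu,
        cop=cop,
        pelvis=pelvis,
        step_labels=step_labels,
        protocol=protocol,
        segment_quats=quats,
    )


# ---------------------------------------------------------------------------
# linear-ground-truth variant


@dataclass
class LinearCopTruth:
    """Generating coefficients of a linear-COP session, the per-channel
    noise levels injected, and the clean-feature covariance, for analytic
    noise-floor accounting."""

    weights: np.ndarray  # (63, 2): columns of the h=1 GAM design matrix
    intercept: np.ndarray  # (2,)
    noise_sigmas: np.ndarray  # (63,)
    feature_cov: np.ndarray  # (63, 63) covariance of the clean channels

    def noise_floor_rms(self) -> tuple[float, float, float]:
        """(lateral, anterior, total) RMS error of the *best* linear
        predictor given the injected input noise.

        With clean features z (covariance C), target y = Wᵀz and observed
        x = z + ε (Cov ε = D, diagonal), the optimal linear predictor has
        coefficients (C + D)⁻¹ C W and mean squared error
        WᵀC W − WᵀC (C + D)⁻¹ C W per component.  Channel redundancy lowers
        this below the naive per-channel propagation, because weight spread
        over correlated channels averages their noise.
        """
        C = self.feature_cov
        D = np.diag(self.noise_sigmas**2)
        CW = C @ self.weights  # (p, 2)
        sol = np.linalg.solve(C + D, CW)
        mse = np.einsum("jc,jc->c", self.weights, CW) - np.einsum("jc,jc->c", CW, sol)
        mse = np.clip(mse, 0.0, None)
        ant, lat = np.sqrt(mse[0]), np.sqrt(mse[1])
        return lat, ant, np.sqrt(0.5 * (lat**2 + ant**2))


def simulate_linear_session(
    params: GaitParams,
    protocol: Sequence[ProtocolStep] | None = None,
    rate_hz: float = 100.0,
    target_rms_mm: float = 30.0,
) -> tuple[Session, LinearCopTruth]:
    """Session whose COP is an *exact* linear map of the current clean GAM
    sample (all 7 IMUs), with noise then injected into the GAM channels only.

    The generating weights are drawn from the session's kinematics seed and
    scaled so each COP component has roughly ``target_rms_mm`` RMS.
    """
    clean = simulate_session(replace(params, noise_rel=0.0), protocol, rate_hz)
    Z = np.hstack([clean.imu[loc].as_matrix() for loc in sorted(clean.imu)])
    rms = np.sqrt(np.mean(Z**2, axis=0))
    rms = np.where(rms < 1e-12, 1.0, rms)

    wrng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x1EA5]).generate_state(1)[0])
    raw = wrng.standard_normal((Z.shape[1], 2)) / rms[:, None]
    # restrict the generating map to the well-conditioned subspace of the
    # clean features so the target is exactly learnable from any split
    Zc = Z - Z.mean(axis=0)
    _, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    V = Vt[S >= 1e-3 * S[0]].T
    W = V @ (V.T @ raw)
    y_sd = np.std(Zc @ W, axis=0)
    W = W * (target_rms_mm / np.where(y_sd < 1e-12, 1.0, y_sd))
    c = np.array([0.0, 0.0])
    Y = Z @ W + c

    sigmas = params.noise_rel * rms
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0x0D15E]).generate_state(1)[0]
    )
    imu = {}
    for j, loc in enumerate(sorted(clean.imu)):
        s = clean.imu[loc]
        noisy = s.as_matrix() + noise_rng.normal(
            0.0, sigmas[9 * j : 9 * (j + 1)], size=(len(s), 9)
        )
        imu[loc] = GamSeries(t=s.t, g=noisy[:, 0:3], a=noisy[:, 3:6], m=noisy[:, 6:9])

    session = Session(
        rate_hz=clean.rate_hz,
        t=clean.t,
        imu=imu,
        cop=CopSeries(t=clean.t, x=Y[:, 0], y=Y[:, 1], frame="pelvis"),
        pelvis=clean.pelvis,
        step_labels=clean.step_labels,
        protocol=clean.protocol,
        segment_quats=clean.segment_quats,
    )
    return session, LinearCopTruth(
        weights=W,
        intercept=c,
        noise_sigmas=sigmas,
        feature_cov=np.cov(Zc, rowvar=False, bias=True),
    )


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_subjects: int,
    base: GaitParams,
    inter_subject_sd: float = 0.1,
    seed: int = 0,
    protocol: Sequence[ProtocolStep] | None = None,
    subject_classes: Sequence[str] | None = None,
    rate_hz: float = 100.0,
) -> list[tuple[str, Session]]:
    """Simulate a cohort with lognormal inter-subject parameter spread.

    Each subject's cadence, step length/width and double-support fraction
    are the base values times unit-mean lognormal factors with coefficient
    of variation ``inter_subject_sd``; a habitual postural lean is drawn
    with standard deviation ``80 mm × inter_subject_sd`` per axis.  With
    ``inter_subject_sd = 0`` every subject reduces exactly to ``base``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if subject_classes is not None and len(subject_classes) != n_subjects:
        raise ValueError("subject_classes length must match n_subjects")

    ss = np.random.SeedSequence([seed, 0xC0407])
    draw_rng = np.random.default_rng(ss)
    sd = float(inter_subject_sd)
    sigma = np.sqrt(np.log1p(sd**2)) if sd > 0 else 0.0

    cohort = []
    for i in range(n_subjects):
        factors = np.exp(draw_rng.normal(-0.5 * sigma**2, sigma, size=4)) if sd > 0 else np.ones(4)
        lean = draw_rng.normal(0.0, 80.0 * sd, size=2) if sd > 0 else np.zeros(2)
        subj_seed = int(draw_rng.integers(0, 2**31 - 1)) if sd > 0 else base.seed
        params = replace(
            base,
            cadence=base.cadence * factors[0],
            step_length=base.step_length * factors[1],
            step_width=base.step_width * factors[2],
            double_support_fraction=float(
                np.clip(base.double_support_fraction * factors[3], 0.05, 0.45)
            ),
            lean_x_mm=base.lean_x_mm + lean[0],
            lean_y_mm=base.lean_y_mm + lean[1],
            seed=subj_seed,
        )
        cls = subject_classes[i] if subject_classes is not None else "healthy"
        proto = protocol if protocol is not None else make_protocol(cls)
        cohort.append((f"S{i + 1}", simulate_session(params, proto, rate_hz)))
    return cohort
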