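"""RMS error metrics and the four study designs: intra-subject accuracy,
train-set-size curves, IMU-subset ablation, and inter-subject transfer with
standing calibration.

Error convention: lateral and anterior RMS are reported separately and the
total pools the squared errors of both components,

    total = sqrt((lateral² + anterior²) / 2),

so the printed totals of a results table are reproducible from its lateral
and anterior cells.  Averages over subjects are unweighted means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    ChannelSpec,
    build_design_matrix,
    build_windows,
    sample_contiguous_train,
    split_train_test,
)
from .models import (
    LSTMCOP,
    LinearCOP,
    TrainConfig,
    fine_tune,
)
from .series import Session

__all__ = [
    "RmsReport",
    "rms_error",
    "evaluate_intra_subject",
    "learning_curve",
    "ablate_imu_subsets",
    "loso_transfer",
    "subject_average",
]


@dataclass(frozen=True)
class RmsReport:
    """Component-wise RMS error in mm. ``total`` pools both components."""

    lateral: float
    anterior: float
    total: float
    n: int

    def __post_init__(self) -> None:
        if min(self.lateral, self.anterior, self.total) < 0:
            raise ValueError("RMS components must be non-negative")

    @classmethod
    def from_components(cls, lateral: float, anterior: float, n: int = 0) -> "RmsReport":
        return cls(
            lateral=float(lateral),
            anterior=float(anterior),
            total=float(np.sqrt(0.5 * (lateral**2 + anterior**2))),
            n=n,
        )

    def as_dict(self) -> dict:
        return {
            "lateral_mm": self.lateral,
            "anterior_mm": self.anterior,
            "total_mm": self.total,
            "n": self.n,
        }


def rms_error(pred, truth, frame: str | None = None) -> RmsReport:
    """RMS error between predicted and ground-truth COP.

    Accepts (n, 2) arrays with columns (anterior x, lateral y) or
    :class:`~copgait.series.CopSeries` pairs (which must share frame).
    """
    from .series import CopSeries

    if isinstance(pred, CopSeries) and isinstance(truth, CopSeries):
        if pred.frame != truth.frame:
            raise ValueError("prediction and truth are in different frames")
        pred, truth = pred.as_array(), truth.as_array()
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 2 or pred.shape[1] != 2:
        raise ValueError("pred and truth must both have shape (n, 2)")
    n = pred.shape[0]
    if n == 0:
        raise ValueError("cannot compute RMS of an empty series")
    err = pred - truth
    anterior = float(np.sqrt(np.mean(err[:, 0] ** 2)))
    lateral = float(np.sqrt(np.mean(err[:, 1] ** 2)))
    return RmsReport.from_components(lateral=lateral, anterior=anterior, n=n)


def _fit_on(train: Session, model_kind: str, spec: ChannelSpec, cfg: TrainConfig | None):
    if model_kind == "linear":
        return LinearCOP.from_session(train, spec).fit()
    if model_kind == "lstm":
        return LSTMCOP.from_session(train, spec, config=cfg).fit()
    raise ValueError(f"unknown model kind {model_kind!r}")


def _score_on(results, test: Session) -> RmsReport:
    pred, truth = results.predict_session(test)
    return rms_error(pred, truth)


def evaluate_intra_subject(
    session: Session,
    model_kind: str = "linear",
    spec: ChannelSpec | None = None,
    cfg: TrainConfig | None = None,
    train_fraction: float = 0.5,
    return_results: bool = False,
):
    """Intra-subject protocol: train on the first half of every protocol
    step, test on the second half, report test RMS."""
    spec = spec or ChannelSpec()
    train, test = split_train_test(session, train_fraction)
    results = _fit_on(train, model_kind, spec, cfg)
    report = _score_on(results, test)
    if return_results:
        return report, results
    return report


def learning_curve(
    session: Session,
    sizes_s: Sequence[float],
    n_repeats: int = 5,
    model_kind: str = "linear",
    spec: ChannelSpec | None = None,
    seed: int = 0,
    cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Test RMS versus train-set size, over repeated contiguous blocks.

    For each size, ``n_repeats`` uniformly-placed contiguous train blocks
    are drawn; a model is fitted per block and scored on the complement.
    Returns a tidy frame with per-size mean and sd of the total RMS.
    """
    spec = spec or ChannelSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes_s:
        totals = []
        for _rep in range(n_repeats):
            train, test = sample_contiguous_train(session, size, rng)
            results = _fit_on(train, model_kind, spec, cfg)
            totals.append(_score_on(results, test).total)
        rows.append(
            {
                "size_s": float(size),
                "mean_rms_mm": float(np.mean(totals)),
                "sd_rms_mm": float(np.std(totals, ddof=1)) if len(totals) > 1 else 0.0,
                "n_repeats": n_repeats,
            }
        )
    return pd.DataFrame(rows)


def ablate_imu_subsets(
    session: Session,
    model_kind: str = "linear",
    components: tuple[str, ...] = ("G", "A", "M"),
    history: int = 1,
    cfg: TrainConfig | None = None,
    train_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exhaustive sensor-placement ablation over all 127 non-empty subsets
    of the 7 IMU locations, retraining from scratch per subset.

    Returns ``(rows, summary)``: one row per subset with its RMS report,
    and per subset-size the best and worst placements by total RMS.
    """
    locations = sorted(session.imu)
    rows = []
    for r in range(1, len(locations) + 1):
        for subset in combinations(locations, r):
            spec = ChannelSpec(components=components, imus=subset, history=history)
            report = evaluate_intra_subject(
                session, model_kind, spec, cfg, train_fraction
            )
            rows.append(
                {
                    "n_imus": r,
                    "imus": ",".join(map(str, subset)),
                    **report.as_dict(),
                }
            )
    df = pd.DataFrame(rows)
    summary_rows = []
    for r, grp in df.groupby("n_imus"):
        best = grp.loc[grp["total_mm"].idxmin()]
        worst = grp.loc[grp["total_mm"].idxmax()]
        summary_rows.append(
            {
                "n_imus": int(r),
                "best_imus": best["imus"],
                "best_total_mm": float(best["total_mm"]),
                "worst_imus": worst["imus"],
                "worst_total_mm": float(worst["total_mm"]),
            }
        )
    return df, pd.DataFrame(summary_rows)


def _standing_calibration(
    session: Session, spec: ChannelSpec, calib_s: float, model_kind: str
):
    """First ``calib_s`` seconds of the session's quiet-standing step."""
    if session.protocol is None:
        raise ValueError("session carries no protocol; cannot locate standing data")
    standing_ids = [i for i, st in enumerate(session.protocol) if st.speed == 0.0]
    if not standing_ids:
        raise ValueError("no quiet-standing protocol step in session")
    sid = standing_ids[0]
    mask = np.flatnonzero(session.step_labels == sid)
    n_cal = int(round(calib_s * session.rate_hz))
    if n_cal > mask.size:
        raise ValueError(
            f"requested {calib_s} s of standing data but only "
            f"{mask.size / session.rate_hz:.1f} s available"
        )
    calib = session.take(mask[:n_cal])
    if model_kind == "linear":
        return build_design_matrix(calib, spec)
    return build_windows(calib, spec)


def loso_transfer(
    cohort: Sequence[tuple[str, Session]],
    model_kind: str = "linear",
    spec: ChannelSpec | None = None,
    calib_s: float = 30.0,
    cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-subject-out transfer with optional standing calibration.

    For each held-out subject: case A fits one model on all other subjects
    pooled and scores it on the held-out subject's test half; case B
    additionally fine-tunes with the first ``calib_s`` seconds of the
    held-out subject's quiet-standing step before scoring.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("transfer study needs a cohort of at least 2 subjects")
    spec = spec or ChannelSpec()

    feats = {}
    for sid, session in cohort:
        if model_kind == "linear":
            feats[sid] = build_design_matrix(session, spec)
        else:
            feats[sid] = build_windows(session, spec)

    rows = []
    for sid, session in cohort:
        X_pool = np.concatenate([feats[o][0] for o, _ in cohort if o != sid], axis=0)
        Y_pool = np.concatenate([feats[o][1] for o, _ in cohort if o != sid], axis=0)
        if model_kind == "linear":
            base = LinearCOP(X_pool, Y_pool, channel_spec=spec).fit()
        elif model_kind == "lstm":
            base = LSTMCOP(X_pool, Y_pool, config=cfg, channel_spec=spec).fit()
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")

        _, test = split_train_test(session)
        rms_a = _score_on(base, test)

        rms_b = rms_a
        if calib_s > 0:
            calib_X, calib_Y = _standing_calibration(session, spec, calib_s, model_kind)
            tuned = fine_tune(base, calib_X, calib_Y, cfg)
            rms_b = _score_on(tuned, test)

        rows.append(
            {
                "subject_id": sid,
                "rms_no_calibration_mm": rms_a.total,
                "rms_with_calibration_mm": rms_b.total,
                "lateral_A_mm": rms_a.lateral,
                "anterior_A_mm": rms_a.anterior,
                "lateral_B_mm": rms_b.lateral,
                "anterior_B_mm": rms_b.anterior,
                "n_test": rms_a.n,
            }
        )
    return pd.DataFrame(rows)


def subject_average(values: Sequence[float]) -> float:
    """Unweighted mean over subjects, the convention of the AVG table rows."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no subjects to average")
    return float(np.mean(arr))
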