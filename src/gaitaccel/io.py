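"""File formats and run configuration.

One flat CSV dialect for every time series: comma separator, dot decimal,
UTF-8, one header row, optional ``#``-prefixed comment lines (used to carry
the config hash).  Angles are degrees in files and radians in memory; gyro
columns are rad/s, accelerometer columns m/s^2, magnetometer columns
arbitrary consistent units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import AccelComponentSeries, EulerPoseSeries, ImuSeries, SensorGeometry
from .ekf import NoiseTuningParams
from .errors import ConfigurationError, FormatError
from .gait import GaitCycleEnsemble, GaitEvents, PhaseStats

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]
POSE_COLUMNS = ["t", "roll_deg", "pitch_deg", "yaw_deg"]
COMPONENT_GROUPS = ["grav", "cen", "tan", "tra", "raw"]

_DT_TOLERANCE = 0.01  # non-uniformity tolerance as a fraction of dt


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[list(required_columns)]
    bad_rows = []
    for c in required_columns:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[col.isna() & df[c].notna()].tolist()
        bad_rows.extend(bad)
        df[c] = col
    na_rows = df.index[df.isna().any(axis=1)].tolist()
    bad_rows = sorted(set(bad_rows) | set(na_rows))
    if bad_rows:
        lines = [r + 2 for r in bad_rows[:5]]  # +2: header + 1-based
        raise FormatError(f"{path}: malformed rows at lines {lines}" +
                          (" ..." if len(bad_rows) > 5 else ""))
    return df


def _uniform_dt(t: np.ndarray, path) -> float:
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    diffs = np.diff(t)
    dt = float(np.median(diffs))
    if dt <= 0:
        raise FormatError(f"{path}: non-increasing timestamps")
    bad = np.nonzero(np.abs(diffs - dt) > _DT_TOLERANCE * dt)[0]
    if len(bad):
        row = int(bad[0]) + 2  # line of the second sample of the bad pair
        raise FormatError(
            f"{path}: non-uniform sampling at line {row + 1} "
            f"(interval {diffs[bad[0]]:.6g} s vs dt {dt:.6g} s)"
        )
    return dt


def _write_table(path, df: pd.DataFrame, config_hash: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_imu_csv(path) -> ImuSeries:
    """Read a 9-axis record (header-driven; column order free)."""
    df = _read_table(path, IMU_COLUMNS)
    t = df["t"].to_numpy()
    dt = _uniform_dt(t, path)
    return ImuSeries(
        dt=dt,
        t0=float(t[0]),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        mag=df[["mx", "my", "mz"]].to_numpy(),
    )


def write_imu_csv(path, imu: ImuSeries, config_hash=None) -> None:
    df = pd.DataFrame(
        np.column_stack([imu.t, imu.gyro, imu.accel, imu.mag]), columns=IMU_COLUMNS
    )
    _write_table(path, df, config_hash)


def read_pose_csv(path) -> EulerPoseSeries:
    df = _read_table(path, POSE_COLUMNS)
    t = df["t"].to_numpy()
    dt = _uniform_dt(t, path)
    angles = np.radians(df[["roll_deg", "pitch_deg", "yaw_deg"]].to_numpy())
    return EulerPoseSeries(dt=dt, t0=float(t[0]), angles=angles)


def write_pose_csv(path, poses: EulerPoseSeries, config_hash=None) -> None:
    df = pd.DataFrame(
        np.column_stack([poses.t, np.degrees(poses.angles)]), columns=POSE_COLUMNS
    )
    _write_table(path, df, config_hash)


def _component_columns():
    cols = ["t"]
    for group in COMPONENT_GROUPS:
        cols += [f"{group}_{ax}" for ax in "xyz"]
    return cols


def write_components_csv(path, comp: AccelComponentSeries, config_hash=None) -> None:
    data = np.column_stack(
        [comp.t, comp.gravitational, comp.centrifugal, comp.tangential,
         comp.translational, comp.raw]
    )
    _write_table(path, pd.DataFrame(data, columns=_component_columns()), config_hash)


def read_components_csv(path) -> AccelComponentSeries:
    df = _read_table(path, _component_columns())
    t = df["t"].to_numpy()
    dt = _uniform_dt(t, path)
    get = lambda g: df[[f"{g}_{ax}" for ax in "xyz"]].to_numpy()
    grav, cen, tan, tra, raw = (get(g) for g in COMPONENT_GROUPS)
    return AccelComponentSeries(
        dt=dt, t0=float(t[0]), gravitational=grav, centrifugal=cen, tangential=tan,
        translational=tra, coriolis=np.zeros_like(cen), raw=raw,
    )


def read_events_csv(path, side: str = "right") -> GaitEvents:
    """Events file: columns ``time_s,event`` with event in {contact, toe_off}."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for c in ("time_s", "event"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column '{c}'")
    kinds = set(df["event"].astype(str))
    unknown = kinds - {"contact", "toe_off"}
    if unknown:
        raise FormatError(f"{path}: unknown event kinds {sorted(unknown)}")
    contacts = df.loc[df["event"] == "contact", "time_s"].astype(float).to_numpy()
    toe_offs = df.loc[df["event"] == "toe_off", "time_s"].astype(float).to_numpy()
    return GaitEvents(foot_contacts=contacts, toe_offs=toe_offs, side=side)


def write_events_csv(path, events: GaitEvents, config_hash=None) -> None:
    rows = [(t, "contact") for t in events.foot_contacts]
    rows += [(t, "toe_off") for t in events.toe_offs]
    rows.sort()
    _write_table(path, pd.DataFrame(rows, columns=["time_s", "event"]), config_hash)


def write_ensemble_csv(path, ens: GaitCycleEnsemble, config_hash=None) -> None:
    names = ens.channel_names or [f"ch{i}" for i in range(ens.mean.shape[1])]
    data = {"pct": ens.grid}
    for i, name in enumerate(names):
        data[f"{name}_mean"] = ens.mean[:, i]
        data[f"{name}_sd"] = ens.sd[:, i]
    _write_table(path, pd.DataFrame(data), config_hash)


def write_stats_csv(path, stats: list, config_hash=None) -> None:
    """``stats`` is a list of (channel_pair, PhaseStats)."""
    rows = [
        {
            "channel_pair": pair,
            "phase": ps.phase,
            "r_mean": ps.r_mean,
            "r_sd": ps.r_sd,
            "rmse_mean": ps.rmse_mean,
            "rmse_sd": ps.rmse_sd,
        }
        for pair, ps in stats
    ]
    _write_table(path, pd.DataFrame(rows), config_hash)


def write_diagnostics_csv(path, poses: EulerPoseSeries, config_hash=None) -> None:
    """Per-step filter diagnostics: innovations and log-likelihood terms."""
    if poses.innovation is None or poses.innovation_cov is None:
        raise ConfigurationError("pose series carries no innovation diagnostics")
    from .ekf import innovation_log_likelihood

    rep = innovation_log_likelihood(poses)
    ll_step = np.concatenate([[np.nan], rep.per_step])
    df = pd.DataFrame(
        {
            "t": poses.t,
            "innovation_yaw": poses.innovation[:, 0],
            "innovation_ax": poses.innovation[:, 1],
            "innovation_ay": poses.innovation[:, 2],
            "innovation_az": poses.innovation[:, 3],
            "loglik_step": ll_step,
        }
    )
    _write_table(path, df, config_hash)


def write_tuning_result(path, params: NoiseTuningParams, ll: float, config_hash=None) -> None:
    """Key-value file with the tuned coefficients and final log-likelihood."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        for name in ("a", "b", "c", "d", "e", "f"):
            fh.write(f"{name} = {getattr(params, name):.10g}\n")
        fh.write(f"mag_norm_ref = {params.mag_norm_ref:.10g}\n")
        fh.write(f"log_likelihood = {ll:.10g}\n")


def read_tuning_result(path) -> NoiseTuningParams:
    values = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = float(val)
    kwargs = {k: values[k] for k in ("a", "b", "c", "d", "e", "f")}
    return NoiseTuningParams(mag_norm_ref=values.get("mag_norm_ref"), **kwargs)


@dataclass
class RunConfig:
    """Pipeline configuration; precedence is CLI flags > file > defaults."""

    dt: float = 0.01
    gravity: float = 9.8
    sensor_r: tuple = (0.0, -0.05, -0.2025)
    differentiator_n: float = 0.01
    calibration_window: float = 5.0
    noise_params: Optional[dict] = None   # a..f, or None -> defaults; "tune" via tune flag
    tune: bool = False
    tune_max_evals: int = 300
    stance_window: Optional[tuple] = None  # default [0, toe-off]
    swing_window: Optional[tuple] = None   # default (toe-off, 100]
    imu_path: Optional[str] = None         # None -> simulate
    events_path: Optional[str] = None      # None -> detect
    seed: int = 0
    n_cycles: int = 10
    sensor_noise: bool = False             # simulate with realistic sensor noise
    verbosity: int = 1

    def __post_init__(self):
        for name in ("dt", "gravity", "differentiator_n", "calibration_window"):
            if not (getattr(self, name) > 0):
                raise ConfigurationError(f"{name} must be > 0")
        self.sensor_r = tuple(float(v) for v in self.sensor_r)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "sensor_r" in raw:
            raw["sensor_r"] = tuple(raw["sensor_r"])
        if "stance_window" in raw and raw["stance_window"] is not None:
            raw["stance_window"] = tuple(raw["stance_window"])
        if "swing_window" in raw and raw["swing_window"] is not None:
            raw["swing_window"] = tuple(raw["swing_window"])
        return cls(**raw)

    def geometry(self) -> SensorGeometry:
        return SensorGeometry(r=self.sensor_r)

    def tuning_params(self) -> NoiseTuningParams:
        if self.noise_params is None:
            return NoiseTuningParams()
        return NoiseTuningParams(**self.noise_params)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable short hash of the configuration (carried by output tables)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
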