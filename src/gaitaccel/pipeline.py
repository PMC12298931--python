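"""End-to-end pipeline: simulate? -> tune? -> pose -> decompose -> cycles -> stats.

Every stage writes its table before the next one runs, so a failure leaves
the partial artifact set on disk; the run log names the failing stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io as gio
from .core import DifferentiatorSpec
from .decomposition import decompose_acceleration
from .ekf import innovation_log_likelihood, run_pose_estimation, tune_noise_parameters
from .errors import GaitAccelError, PipelineError
from .gait import detect_gait_events, normalize_to_gait_cycle, phase_component_stats
from .simulate import GaitModelParams, simulate_gait

logger = logging.getLogger("gaitaccel")

COMPONENT_CHANNELS = [
    f"{group}_{ax}" for group in ("grav", "cen", "tan", "tra", "raw") for ax in "xyz"
]


class RunLog:
    """Timestamped stage records plus de-duplicated warnings."""

    def __init__(self):
        self.records: list[tuple[float, str, str]] = []
        self._warnings: dict[str, None] = {}

    def stage(self, name: str, message: str = "") -> None:
        self.records.append((time.time(), name, message))
        logger.info("%s %s", name, message)

    def warn(self, message: str) -> None:
        self._warnings.setdefault(message)
        logger.warning(message)

    @property
    def warnings(self) -> list[str]:
        return list(self._warnings)

    def write(self, path, config_hash: str, version: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# gaitaccel {version} run log\n# config_hash={config_hash}\n")
            for ts, name, message in self.records:
                fh.write(f"{ts:.3f} {name} {message}\n".rstrip() + "\n")
            for w in self.warnings:
                fh.write(f"WARNING {w}\n")


def run_pipeline(config: "gio.RunConfig", out_dir) -> dict:
    """Execute the full workflow; returns a dict of artifact paths.

    Raises :class:`PipelineError` naming the stage on failure; artifacts
    written before the failure are left in place.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    log = RunLog()
    paths: dict[str, Path] = {}
    truth = None
    stage = "setup"

    try:
        stage = "simulate" if config.imu_path is None else "load"
        if config.imu_path is None:
            params = GaitModelParams(
                dt=config.dt,
                n_cycles=config.n_cycles,
                calibration_time=config.calibration_window,
                geometry=config.geometry(),
                gravity=config.gravity,
                seed=config.seed,
            )
            if config.sensor_noise:
                params = params.with_sensor_noise()
            imu, truth = simulate_gait(params)
            paths["imu"] = out / "imu.csv"
            gio.write_imu_csv(paths["imu"], imu, chash)
            paths["truth_pose"] = out / "truth_pose.csv"
            gio.write_pose_csv(paths["truth_pose"], truth.poses, chash)
            paths["truth_components"] = out / "truth_components.csv"
            gio.write_components_csv(paths["truth_components"], truth.components, chash)
            log.stage(stage, f"{len(imu)} samples, seed {config.seed}")
        else:
            imu = gio.read_imu_csv(config.imu_path)
            log.stage(stage, f"{config.imu_path}: {len(imu)} samples")

        noise_params = config.tuning_params()
        if config.tune:
            stage = "tune"
            result = tune_noise_parameters(
                imu,
                noise_params,
                calibration_window=config.calibration_window,
                gravity_constant=config.gravity,
                max_evals=config.tune_max_evals,
            )
            noise_params = result.params
            paths["tuning"] = out / "tuning.txt"
            gio.write_tuning_result(paths["tuning"], noise_params, result.ll_final, chash)
            log.stage(stage, f"LL {result.ll_initial:.1f} -> {result.ll_final:.1f} "
                             f"({result.n_evaluations} evaluations)")

        stage = "estimate-pose"
        poses = run_pose_estimation(
            imu,
            noise_params,
            calibration_window=config.calibration_window,
            gravity_constant=config.gravity,
        )
        for w in poses.warnings:
            log.warn(w)
        ll = innovation_log_likelihood(poses).ll
        paths["pose"] = out / "pose.csv"
        gio.write_pose_csv(paths["pose"], poses, chash)
        log.stage(stage, f"LL {ll:.1f}")

        stage = "decompose"
        comp = decompose_acceleration(
            imu,
            poses,
            geometry=config.geometry(),
            spec=DifferentiatorSpec(n=config.differentiator_n, dt=imu.dt),
            gravity_constant=config.gravity,
        )
        paths["components"] = out / "components.csv"
        gio.write_components_csv(paths["components"], comp, chash)
        log.stage(stage, f"max identity residual {np.abs(comp.identity_residual()).max():.2e}")

        stage = "gait-cycle"
        if config.events_path is not None:
            events = gio.read_events_csv(config.events_path)
            log.stage(stage, f"events from {config.events_path}")
        elif truth is not None:
            events = truth.events
            log.stage(stage, "events from simulator ground truth")
        else:
            events = detect_gait_events(imu.gyro[:, 0], imu.dt, t0=imu.t0)
            log.warn("gait events detected from the sagittal gyro; supply an "
                     "events file for validated timing")
            log.stage(stage, f"{len(events.foot_contacts)} contacts detected")
        channels = np.hstack(
            [comp.gravitational, comp.centrifugal, comp.tangential, comp.translational,
             comp.raw]
        )
        ens = normalize_to_gait_cycle(
            comp.t, channels, events, channel_names=COMPONENT_CHANNELS
        )
        paths["ensemble"] = out / "ensemble.csv"
        gio.write_ensemble_csv(paths["ensemble"], ens, chash)
        log.stage(stage, f"{ens.n_cycles} cycles, toe-off {ens.toe_off_pct:.1f}%")

        stage = "stats"
        stance = config.stance_window or (0.0, ens.toe_off_pct)
        swing = config.swing_window or (ens.toe_off_pct, 100.0)
        idx = {name: i for i, name in enumerate(COMPONENT_CHANNELS)}
        stats = []
        for axis in "xyz":
            a = ens.cycles[:, :, idx[f"raw_{axis}"]]
            for group in ("grav", "tra"):
                b = ens.cycles[:, :, idx[f"{group}_{axis}"]]
                for phase, window in (("stance", stance), ("swing", swing)):
                    ps = phase_component_stats(a, b, window, phase=phase)
                    stats.append((f"raw_{axis}:{group}_{axis}", ps))
        paths["stats"] = out / "stats.csv"
        gio.write_stats_csv(paths["stats"], stats, chash)
        log.stage(stage, f"{len(stats)} channel-pair stats")

        paths["run_log"] = out / "run_log.txt"
        log.write(paths["run_log"], chash, __version__)
        return {k: str(v) for k, v in paths.items()}

    except GaitAccelError as exc:
        log.stage(stage, f"FAILED: {exc}")
        log.write(out / "run_log.txt", chash, __version__)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
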