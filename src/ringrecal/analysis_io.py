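"""Configs, trajectory containers, I/O and summary analysis.

A :class:`Trajectory` wraps a uniformly sampled ``pandas.DataFrame`` of
simulation records (time, velocity, bump and landmark locations, wrapped
positional error, gains, population mean rates) plus a metadata dict; it
round-trips through CSV (data) + JSON (metadata) and can attach full
rate/weight snapshots to an HDF5 container.  An :class:`ExperimentConfig`
is a plain serializable mapping that dispatches to the reduced, full or
plastic simulators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml



__all__ = [
    "Trajectory",
    "ExperimentConfig",
    "run_experiment",
    "summarize_trajectory",
]


@dataclass
class Trajectory:
    """Time-indexed record of a simulation run."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "t" not in self.frame.columns:
            raise ValueError("trajectory frame requires a 't' column")
        t = self.frame["t"].to_numpy()
        if t.shape[0] and np.any(np.diff(t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self):
        return len(self.frame)

    @property
    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def to_csv(self, path, float_format="%.10g"):
        """Write records as CSV and metadata as a sidecar ``<path>.meta.json``."""
        path = Path(path)
        self.frame.to_csv(path, index=False, float_format=float_format)
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(_jsonable(self.meta), fh, indent=2)

    @classmethod
    def from_csv(cls, path):
        path = Path(path)
        frame = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(frame=frame, meta=meta)

    def to_hdf5(self, path, snapshots: dict | None = None):
        """Store columns plus optional named arrays (rates/weights) in HDF5."""
        import h5py

        with h5py.File(path, "w") as fh:
            grp = fh.create_group("trajectory")
            for col in self.frame.columns:
                grp.create_dataset(col, data=self.frame[col].to_numpy())
            fh.attrs["meta"] = json.dumps(_jsonable(self.meta))
            if snapshots:
                snap = fh.create_group("snapshots")
                for name, arr in snapshots.items():
                    snap.create_dataset(name, data=np.asarray(arr))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def summarize_trajectory(traj: Trajectory, window_frac: float = 0.1) -> dict:
    """Steady-state and final summaries of a trajectory.

    Steady-state positional error is the trailing-window circular mean of
    ``theta_tilde`` over the last ``window_frac`` of the samples.
    """
    frame = traj.frame
    if len(frame) == 0:
        raise ValueError("empty trajectory")
    out: dict = {"t_final": float(frame["t"].iloc[-1]), "n_samples": int(len(frame))}
    if "theta_tilde" in frame.columns:
        err = frame["theta_tilde"].to_numpy()
        n_tail = max(1, int(round(window_frac * err.shape[0])))
        tail = err[-n_tail:]
        out["theta_tilde_final"] = float(err[-1])
        out["theta_tilde_steady"] = float(
            np.arctan2(np.mean(np.sin(tail)), np.mean(np.cos(tail)))
        )
        out["abs_theta_tilde_final"] = abs(out["theta_tilde_final"])
    if "k0" in frame.columns:
        out["k0_final"] = float(frame["k0"].iloc[-1])
        if "k_star" in traj.meta and traj.meta["k_star"] is not None:
            out["k_tilde_final"] = float(traj.meta["k_star"]) - out["k0_final"]
    if "gain_estimate" in frame.columns:
        est = frame["gain_estimate"].dropna()
        if len(est):
            out["gain_estimate_final"] = float(est.iloc[-1])
    return out


@dataclass
class ExperimentConfig:
    """Serializable experiment description dispatched by :func:`run_experiment`.

    ``kind`` selects the simulator: ``reduced``, ``full``, ``recalibrate``
    (plastic network), or ``error_correction``.  ``params`` holds the
    simulator-specific settings; unknown keys are rejected downstream.
    """

    kind: str
    label: str = "experiment"
    seed: int = 0
    params: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "label": self.label,
            "seed": int(self.seed),
            "params": _jsonable(self.params),
            "outputs": _jsonable(self.outputs),
        }

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        missing = {"kind"} - set(data)
        if missing:
            raise ValueError(f"config missing required fields: {sorted(missing)}")
        return cls(
            kind=data["kind"],
            label=data.get("label", "experiment"),
            seed=int(data.get("seed", 0)),
            params=data.get("params", {}) or {},
            outputs=data.get("outputs", {}) or {},
        )


def _run_reduced(config: ExperimentConfig) -> Trajectory:
    from .gain_adaptation import (
        gain_rule_linear,
        gain_rule_velocity_biased,
    )
    from .reduced_model import ReducedState, beta_sinusoidal, simulate_reduced
    from .synthetic_inputs import make_velocity_profile

    p = dict(config.params)
    velocity = make_velocity_profile(
        kind=p.get("velocity_kind", "pause_resume"),
        duration=float(p.get("duration", 1800.0)),
        mean_v=float(p.get("mean_v", 0.5)),
        seed=config.seed,
    )
    rule_name = p.get("rule", "linear")
    mu = float(p.get("mu", 0.02))
    if rule_name == "linear":
        rule = gain_rule_linear(mu)
    elif rule_name == "velocity_biased":
        rule = gain_rule_velocity_biased(mu, float(p.get("eta", 0.12)))
    elif rule_name in (None, "none"):
        rule = None
    else:
        raise ValueError(f"unknown rule {rule_name!r} in config {config.label!r}")
    return simulate_reduced(
        initial=ReducedState(k0=float(p.get("k0_initial", 1.0))),
        velocity=velocity,
        k_star=float(p.get("k_star", 1.5)),
        beta=beta_sinusoidal(float(p.get("beta_amplitude", 0.66))),
        rule=rule,
        dt=float(p.get("dt", 0.01)),
        record_dt=float(p.get("record_dt", 0.5)),
    )


def _run_full(config: ExperimentConfig) -> Trajectory:
    from .network_core import default_network, make_visual_drive, simulate_full
    from .synthetic_inputs import make_velocity_profile

    p = dict(config.params)
    params = default_network(n=int(p.get("n", 256)))
    velocity = make_velocity_profile(
        kind=p.get("velocity_kind", "constant"),
        duration=float(p.get("duration", 10.0)),
        mean_v=float(p.get("mean_v", 0.5)),
        seed=config.seed,
    )
    visual = None
    if p.get("landmarks", False):
        visual = make_visual_drive(params, amplitude=float(p.get("visual_amplitude", 3.0)))
    return simulate_full(
        params,
        velocity,
        duration=velocity.duration,
        visual=visual,
        k_star=float(p.get("k_star", 1.0)),
        record_dt=float(p.get("record_dt", 0.01)),
    )


def run_experiment(config: ExperimentConfig, out_dir=None) -> tuple[Trajectory, dict]:
    """Dispatch a config to the matching simulator; optionally write outputs.

    Returns ``(trajectory, summary)``.  With ``out_dir`` set, writes
    ``<label>.csv`` (+ metadata sidecar) and ``<label>.summary.json``.
    """
    if config.kind == "reduced":
        traj = _run_reduced(config)
    elif config.kind == "full":
        traj = _run_full(config)
    elif config.kind == "recalibrate":
        from .plastic_network import run_recalibration_protocol

        traj = run_recalibration_protocol(seed=config.seed, **config.params)
    elif config.kind == "error_correction":
        from .plastic_network import run_error_correction_protocol

        traj = run_error_correction_protocol(seed=config.seed, **config.params)
    else:
        raise ValueError(f"unknown experiment kind {config.kind!r} (field: kind)")
    traj.meta.setdefault("label", config.label)
    traj.meta.setdefault("seed", config.seed)
    summary = summarize_trajectory(traj)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        traj.to_csv(out_dir / f"{config.label}.csv")
        with open(out_dir / f"{config.label}.summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2)
    return traj, summary
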