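"""Session-bundle I/O and validation.

A session bundle is a directory of plain-text files:

- ``events.csv`` — trial, target_id, cue_on_s, target_on_s
- ``kinematics.csv`` — t_s, x_mm, y_mm, z_mm, valid (120 frames/s nominal)
- ``spikes.csv`` — unit_id, t_s (one row per spike)
- ``config.yaml`` — task geometry/timing (:class:`vimreach.synthetic.TaskConfig`)
- ``ground_truth.json`` — optional; generator ground truth for validation

Times are seconds from recording start; positions mm in a right-handed
frame with x rightward and y upward on the display plane, z toward the
subject.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vimreach.kinematics import TrajectorySeries
from vimreach.synthetic import SyntheticSession, TaskConfig

EVENT_SCHEMA = ["trial", "target_id", "cue_on_s", "target_on_s"]
KINEMATIC_SCHEMA = ["t_s", "x_mm", "y_mm", "z_mm", "valid"]
SPIKE_SCHEMA = ["unit_id", "t_s"]


@dataclass
class SessionBundle:
    """An on-disk session loaded into memory."""

    config: TaskConfig
    events: pd.DataFrame
    trajectory: TrajectorySeries
    spikes: dict[str, np.ndarray]
    ground_truth: dict | None = None


def write_bundle(session: SyntheticSession, path: str | Path) -> Path:
    """Write a synthetic session as a plain-text bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.events[EVENT_SCHEMA].to_csv(path / "events.csv", index=False)
    kin = session.trajectory.to_frame()
    kin["valid"] = kin["valid"].astype(int)
    kin.to_csv(path / "kinematics.csv", index=False, float_format="%.6f")
    rows = [
        {"unit_id": uid, "t_s": float(t)}
        for uid, times in session.spikes.items()
        for t in times
    ]
    pd.DataFrame(rows, columns=SPIKE_SCHEMA).to_csv(
        path / "spikes.csv", index=False, float_format="%.6f"
    )
    (path / "config.yaml").write_text(
        yaml.safe_dump(
            {
                "task": dataclasses.asdict(session.config),
                "motor": dataclasses.asdict(session.motor),
                "seed": session.seed,
            },
            sort_keys=True,
        )
    )
    truth = {
        "seed": session.seed,
        "units": [dataclasses.asdict(gt) for gt in session.ground_truth],
        "reaches": session.reach_truth.to_dict(orient="list"),
    }
    (path / "ground_truth.json").write_text(json.dumps(truth, indent=1, default=float))
    return path


def read_bundle(path: str | Path) -> SessionBundle:
    """Load a session bundle, validating schemas along the way."""
    path = Path(path)
    validate_bundle(path, strict=True)  # raises on schema errors
    events = pd.read_csv(path / "events.csv")
    kin = pd.read_csv(path / "kinematics.csv")
    kin["valid"] = kin["valid"].astype(bool)
    spikes_df = pd.read_csv(path / "spikes.csv")
    spikes = {
        str(uid): g["t_s"].to_numpy(dtype=float)
        for uid, g in spikes_df.groupby("unit_id", sort=True)
    }
    raw = yaml.safe_load((path / "config.yaml").read_text())
    task_cfg = raw.get("task", raw) if isinstance(raw, dict) else {}
    if "visible_targets" in task_cfg and task_cfg["visible_targets"] is not None:
        task_cfg["visible_targets"] = tuple(task_cfg["visible_targets"])
    config = TaskConfig(**task_cfg)
    truth = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        truth = json.loads(gt_path.read_text())
    return SessionBundle(
        config=config,
        events=events,
        trajectory=TrajectorySeries.from_frame(kin),
        spikes=spikes,
        ground_truth=truth,
    )


class BundleValidationError(ValueError):
    pass


def validate_bundle(path: str | Path, strict: bool = False) -> list[str]:
    """Schema and consistency checks on a bundle directory.

    Checks required files and columns, strictly increasing time stamps,
    nominal 120 frames/s kinematic sampling, monotone per-unit spike
    times, and that the trajectory spans the task events.  Returns a list
    of findings (empty when clean); with ``strict`` the first error
    raises :class:`BundleValidationError` (warnings never raise).
    """
    path = Path(path)
    findings: list[str] = []
    errors: list[str] = []

    def err(msg: str) -> None:
        errors.append(msg)

    for fname, schema in [
        ("events.csv", EVENT_SCHEMA),
        ("kinematics.csv", KINEMATIC_SCHEMA),
        ("spikes.csv", SPIKE_SCHEMA),
    ]:
        f = path / fname
        if not f.exists():
            err(f"{fname}: missing")
            continue
        cols = pd.read_csv(f, nrows=0).columns
        missing = [c for c in schema if c not in cols]
        if missing:
            err(f"{fname}: missing columns {missing}")
    if not (path / "config.yaml").exists():
        err("config.yaml: missing")
    if errors:
        if strict:
            raise BundleValidationError("; ".join(errors))
        return errors

    events = pd.read_csv(path / "events.csv")
    if not events["target_on_s"].is_monotonic_increasing:
        err("events.csv: target_on_s not increasing")
    kin = pd.read_csv(path / "kinematics.csv")
    t = kin["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = np.nonzero(np.diff(t) <= 0)[0][:5] + 2
        err(f"kinematics.csv: t_s not strictly increasing at rows {bad.tolist()}")
    else:
        fs = 1.0 / float(np.median(np.diff(t)))
        if not 119.0 <= fs <= 121.0:
            findings.append(
                f"kinematics.csv: sampling rate {fs:.1f} frames/s deviates from "
                "nominal 120 (lag steps assume 1/120 s)"
            )
        if len(events) and t[-1] < events["target_on_s"].iloc[-1]:
            err("kinematics.csv: trajectory ends before the last task event")
    spikes = pd.read_csv(path / "spikes.csv")
    for uid, g in spikes.groupby("unit_id"):
        st = g["t_s"].to_numpy()
        if np.any(np.diff(st) < 0):
            rows = g.index[np.nonzero(np.diff(st) < 0)[0] + 1][:5]
            err(f"spikes.csv: unit {uid} spike times decrease at rows {list(rows)}")
        if len(st) and len(t) and (st[0] < t[0] - 1e-9 or st[-1] > t[-1] + 1e-9):
            findings.append(f"spikes.csv: unit {uid} has spikes outside the recording span")
    if errors and strict:
        raise BundleValidationError("; ".join(errors))
    return errors + findings


__all__ = [
    "BundleValidationError",
    "SessionBundle",
    "read_bundle",
    "validate_bundle",
    "write_bundle",
]
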