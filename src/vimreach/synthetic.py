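"""Synthetic center-out-and-back sessions with known ground truth.

Emulates the intraoperative reaching task: a central target and 8 outer
targets evenly spaced on a circle of radius 178 mm in the display plane.
Each trial shows the center for 3 s, overlays a 0.7 s directional cue, then
shows the outer target for 3 s; outer targets cycle in a pseudorandom,
load-balanced order until at least 24 out-and-back sequences (48 reaches)
have been presented.

The fingertip trajectory is piecewise: holds at target positions carrying
4-12 Hz tremor plus white positional noise, joined by minimum-jerk
point-to-point reaches whose speed profile is smooth, unimodal and
analytically known (peak speed = 1.875 · distance / duration).  Frames are
dropped at random to emulate tracking failures.

Spiking units are inhomogeneous Poisson processes whose intensity couples a
baseline rate to z-scored kinematic/error features of the *noiseless*
trajectory at a configurable neural-to-kinematic lag (positive lag = neural
activity follows the kinematics), a direction-tuning term active during
reaches, and a slow multiplicative drift.  Everything is a pure function of
(config, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from vimreach._utils import (
    STREAM_TASK,
    STREAM_TRAJECTORY,
    STREAM_UNIT,
    stream_rng,
)
from vimreach.kinematics import TrajectorySeries, differentiate

#: Recording time before the first center display (s).
LEAD_IN_S = 2.0

#: Kinematic/error feature names a unit's rate may couple to.
COUPLING_FEATURES = (
    "x_mm", "y_mm", "z_mm", "vx", "vy", "vz", "speed",
    "ax", "ay", "az", "a_mag", "a_signed",
    "ex", "ey", "ez", "e_mag",
)


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and timing of the center-out-and-back task."""

    n_targets: int = 8
    radius_mm: float = 178.0
    target_diameter_mm: float = 30.0
    center_hold_s: float = 3.0
    target_display_s: float = 3.0
    cue_s: float = 0.7
    min_sequences: int = 24
    visible_targets: tuple[int, ...] | None = None  # None -> all targets

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.min_sequences < 1:
            raise ValueError("min_sequences must be >= 1")
        if self.visible_targets is not None and len(self.visible_targets) == 0:
            raise ValueError("visible_targets must not be empty (use None for all)")
        vis = self.visible()
        if not 1 <= len(vis) <= self.n_targets:
            raise ValueError("visible_targets must be a nonempty subset of targets")
        if any(not 1 <= t <= self.n_targets for t in vis):
            raise ValueError("target ids must lie in 1..n_targets")

    def visible(self) -> tuple[int, ...]:
        return self.visible_targets or tuple(range(1, self.n_targets + 1))

    def target_angle(self, target_id: int) -> float:
        """Angle of an outer target in the display plane (radians).

        The convention places target 4 in the upper right and target 8
        diametrically opposite in the lower left, so outward reaches to
        target d share a movement direction with inward reaches from the
        opposite target.
        """
        step = 2.0 * np.pi / self.n_targets
        return step * target_id - 3.0 * step

    def target_position(self, target_id: int) -> np.ndarray:
        """3D position (mm) of a target; id 0 is the central target."""
        if target_id == 0:
            return np.zeros(3)
        th = self.target_angle(target_id)
        return np.array([self.radius_mm * np.cos(th), self.radius_mm * np.sin(th), 0.0])


@dataclass(frozen=True)
class MotorParams:
    """Movement-generation parameters for the synthetic subject."""

    fs: float = 120.0
    reach_duration_median_s: float = 0.8     # lognormal median
    reach_duration_log_sd: float = 0.15
    reaction_time_range_s: tuple[float, float] = (0.15, 0.40)
    tremor_amplitude_mm: float = 2.0
    tremor_freq_hz: float = 5.0                      # sinusoid model only
    tremor_model: str = "narrowband"                 # "narrowband" | "sinusoid"
    tremor_band_hz: tuple[float, float] = (4.0, 12.0)  # characteristic ET band
    tremor_during_movement: bool = False
    noise_sd_mm: float = 0.3
    dropped_frame_prob: float = 0.01
    tail_s: float = 5.0

    def __post_init__(self) -> None:
        if self.tremor_amplitude_mm > 0:
            if self.tremor_freq_hz <= 0:
                raise ValueError("tremor frequency must be positive")
            if self.tremor_freq_hz >= self.fs / 2:
                raise ValueError(
                    f"tremor at {self.tremor_freq_hz} Hz is above Nyquist for fs={self.fs}"
                )
        lo, hi = self.reaction_time_range_s
        if not 0 <= lo <= hi:
            raise ValueError("invalid reaction time range")
        if self.tremor_model not in ("narrowband", "sinusoid"):
            raise ValueError(f"unknown tremor model {self.tremor_model!r}")


@dataclass
class UnitGroundTruth:
    """True generative parameters of one synthetic unit.

    ``coupling`` maps feature names (see :data:`COUPLING_FEATURES`) to
    weights in spikes/s per z-scored feature unit.  ``true_lag_s`` follows
    the analysis convention: positive means neural activity lags the
    kinematics.  ``drift_amplitude`` is the fractional depth of a slow
    (one-cycle-per-session) multiplicative gain.
    """

    unit_id: str
    baseline_rate: float = 20.0
    direction_gain: float = 0.0
    preferred_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    coupling: dict[str, float] = field(default_factory=dict)
    true_lag_s: float = 0.0
    drift_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 <= self.drift_amplitude < 1:
            raise ValueError("drift_amplitude must be in [0, 1)")
        bad = set(self.coupling) - set(COUPLING_FEATURES)
        if bad:
            raise ValueError(f"unknown coupling features: {sorted(bad)}")


@dataclass
class SyntheticSession:
    """A complete generated session plus its ground truth."""

    config: TaskConfig
    motor: MotorParams
    events: pd.DataFrame            # trial, target_id, cue_on_s, target_on_s
    trajectory: TrajectorySeries    # observed (tremor + noise + drops)
    clean: TrajectorySeries         # noiseless ground-truth trajectory
    spikes: dict[str, np.ndarray]
    ground_truth: list[UnitGroundTruth]
    reach_truth: pd.DataFrame       # trial, target_id, outward, t_go_s, t_on_s, t_off_s, ...
    seed: int

    @property
    def duration_s(self) -> float:
        return float(self.trajectory.t[-1])


def generate_task_events(config: TaskConfig, seed: int) -> pd.DataFrame:
    """Load-balanced pseudorandom target sequence with task timing.

    Targets cycle through the visible set, order permuted independently
    within each cycle, until at least ``min_sequences`` out-and-back
    sequences are scheduled; every visible target therefore appears equally
    often.  Times are seconds from recording start.
    """
    visible = config.visible()
    if not visible:
        raise ValueError("no visible targets configured")
    rng = stream_rng(seed, STREAM_TASK)
    n_cycles = int(np.ceil(config.min_sequences / len(visible)))
    order = np.concatenate([rng.permutation(visible) for _ in range(n_cycles)])
    trial_len = config.center_hold_s + config.cue_s + config.target_display_s
    center_on = LEAD_IN_S + np.arange(order.size) * trial_len
    cue_on = center_on + config.center_hold_s
    target_on = cue_on + config.cue_s
    return pd.DataFrame(
        {
            "trial": np.arange(order.size, dtype=int),
            "target_id": order.astype(int),
            "cue_on_s": cue_on,
            "target_on_s": target_on,
        }
    )


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _schedule_reaches(
    events: pd.DataFrame, config: TaskConfig, motor: MotorParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-reach reaction times and durations; return the ground-truth table."""
    rows = []
    rt_lo, rt_hi = motor.reaction_time_range_s
    mu = np.log(motor.reach_duration_median_s)
    for ev in events.itertuples(index=False):
        target = config.target_position(ev.target_id)
        go_out = ev.target_on_s
        go_in = ev.target_on_s + config.target_display_s
        for outward, t_go, src, dst in (
            (True, go_out, np.zeros(3), target),
            (False, go_in, target, np.zeros(3)),
        ):
            rt = rng.uniform(rt_lo, rt_hi)
            dur = float(np.exp(rng.normal(mu, motor.reach_duration_log_sd)))
            dist = float(np.linalg.norm(dst - src))
            rows.append(
                {
                    "trial": ev.trial,
                    "target_id": ev.target_id,
                    "outward": outward,
                    "t_go_s": t_go,
                    "t_on_s": t_go + rt,
                    "t_off_s": t_go + rt + dur,
                    "duration_s": dur,
                    "distance_mm": dist,
                    "peak_speed_mm_s": 1.875 * dist / dur,
                }
            )
    return pd.DataFrame(rows)


def _tremor_waveform(t: np.ndarray, motor: MotorParams, rng: np.random.Generator) -> np.ndarray:
    """Tremor displacement along the tremor axis (mm).

    ``sinusoid``: a pure tone at ``tremor_freq_hz`` with amplitude
    ``tremor_amplitude_mm``.  ``narrowband`` (default): Gaussian noise
    band-passed to ``tremor_band_hz`` (the 4-12 Hz band characteristic of
    essential tremor) — tremor with the wandering amplitude, phase and
    frequency seen in patients — scaled to the same RMS as the sinusoid
    (amplitude/√2).
    """
    if motor.tremor_model == "sinusoid":
        phase = rng.uniform(0, 2 * np.pi)
        return motor.tremor_amplitude_mm * np.sin(2 * np.pi * motor.tremor_freq_hz * t + phase)
    from scipy.signal import butter, sosfiltfilt

    fs = 1.0 / float(t[1] - t[0])
    lo = max(0.5, motor.tremor_band_hz[0])
    hi = min(fs / 2 * 0.95, motor.tremor_band_hz[1])
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.normal(size=t.size))
    rms = x.std()
    target_rms = motor.tremor_amplitude_mm / np.sqrt(2)
    return x * (target_rms / rms if rms > 0 else 0.0)


def _clean_position(
    t: np.ndarray, reach_truth: pd.DataFrame, config: TaskConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless piecewise hold/minimum-jerk position, hold mask and goal."""
    p = np.tile(config.target_position(0), (t.size, 1))
    goal = p.copy()
    moving = np.zeros(t.size, dtype=bool)
    for r in reach_truth.itertuples(index=False):
        src = config.target_position(r.target_id if not r.outward else 0)
        dst = config.target_position(r.target_id if r.outward else 0)
        in_reach = (t >= r.t_on_s) & (t <= r.t_off_s)
        after = t > r.t_off_s
        tau = (t[in_reach] - r.t_on_s) / r.duration_s
        p[in_reach] = src + minimum_jerk(tau)[:, None] * (dst - src)
        p[after] = dst
        goal[in_reach] = dst
        goal[after] = dst
        moving |= in_reach
    return p, ~moving, goal


def generate_trajectory(
    events: pd.DataFrame,
    config: TaskConfig,
    motor: MotorParams,
    seed: int,
) -> tuple[TrajectorySeries, TrajectorySeries, pd.DataFrame]:
    """Generate observed and noise-free trajectories plus the reach truth table.

    Returns ``(observed, clean, reach_truth)``.  ``clean`` is the movement
    the subject actually makes — the hold/minimum-jerk path (continuous
    across boundaries) plus tremor, a sinusoid along a fixed random 3D axis
    applied during holds (and during reaches too when
    ``tremor_during_movement`` models action tremor).  ``observed`` adds
    the measurement layer: white positional noise and dropped frames
    (position NaN, flagged invalid).
    """
    rng = stream_rng(seed, STREAM_TRAJECTORY)
    reach_truth = _schedule_reaches(events, config, motor, rng)
    t_end = float(events["target_on_s"].iloc[-1] + config.target_display_s + motor.tail_s)
    n = int(np.floor(t_end * motor.fs)) + 1
    t = np.arange(n) / motor.fs

    p_move, hold_mask, _ = _clean_position(t, reach_truth, config)

    # tremor is movement the subject actually makes, so it belongs to the
    # clean (noise-free) trajectory that drives spiking, not to the
    # measurement layer
    if motor.tremor_amplitude_mm > 0:
        mask = np.ones(t.size, dtype=bool) if motor.tremor_during_movement else hold_mask
        p_move = p_move.copy()
        if motor.tremor_model == "sinusoid":
            # single oscillation axis, as in a fixed-plane postural tremor
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            p_move[mask] += _tremor_waveform(t, motor, rng)[mask, None] * axis
        else:
            # independent narrowband components per axis (total RMS matched
            # to the sinusoid): tremor direction wanders as in patients
            comp = np.column_stack(
                [_tremor_waveform(t, motor, rng) for _ in range(3)]
            ) / np.sqrt(3)
            p_move[mask] += comp[mask]

    p = p_move.copy()
    if motor.noise_sd_mm > 0:
        p = p + rng.normal(scale=motor.noise_sd_mm, size=p.shape)
    valid = np.ones(t.size, dtype=bool)
    if motor.dropped_frame_prob > 0:
        dropped = rng.random(t.size) < motor.dropped_frame_prob
        valid &= ~dropped
        p[dropped] = np.nan

    observed = TrajectorySeries(t, p, valid)
    clean = TrajectorySeries(t, p_move)
    return observed, clean, reach_truth


def clean_features(
    clean: TrajectorySeries, reach_truth: pd.DataFrame, config: TaskConfig
) -> pd.DataFrame:
    """Ground-truth kinematic + error features of the noiseless trajectory.

    The error vector is instantaneous position minus the goal (the hold
    position at the end of the ongoing reach); it is zero during holds by
    construction.
    """
    df = differentiate(clean)
    _, _, goal = _clean_position(clean.t, reach_truth, config)
    err = clean.p - goal
    df["ex"], df["ey"], df["ez"] = err[:, 0], err[:, 1], err[:, 2]
    df["e_mag"] = np.linalg.norm(err, axis=1)
    return df


def unit_rate(
    features: pd.DataFrame,
    reach_truth: pd.DataFrame,
    gt: UnitGroundTruth,
    config: TaskConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth firing-rate function of a unit on the feature grid.

    rate(t) = drift(t) · max(0, baseline + Σ_f w_f · z_f(t − lag) + direction term)
    where z_f is the session-z-scored feature and the direction term is
    ``direction_gain · (reach direction · preferred direction)`` while a
    reach is in progress.  Returns ``(t, rate)``.
    """
    t = features["t_s"].to_numpy()
    drive = np.full(t.size, gt.baseline_rate)
    for name, w in gt.coupling.items():
        f = features[name].to_numpy(dtype=float)
        sd = f.std()
        z = (f - f.mean()) / sd if sd > 0 else np.zeros_like(f)
        # positive lag: the neural drive at time t reflects kinematics at t - lag
        drive += w * np.interp(t - gt.true_lag_s, t, z)
    if gt.direction_gain != 0.0:
        pref = np.asarray(gt.preferred_direction, dtype=float)
        pref = pref / np.linalg.norm(pref)
        for r in reach_truth.itertuples(index=False):
            src = config.target_position(r.target_id if not r.outward else 0)
            dst = config.target_position(r.target_id if r.outward else 0)
            d = dst - src
            d /= np.linalg.norm(d)
            in_reach = (t >= r.t_on_s + gt.true_lag_s) & (t <= r.t_off_s + gt.true_lag_s)
            drive[in_reach] += gt.direction_gain * float(d @ pref)
    rate = np.maximum(drive, 0.0)
    if gt.drift_amplitude > 0:
        rate = rate * (1.0 + gt.drift_amplitude * np.sin(2 * np.pi * t / t[-1]))
    return t, rate


def generate_spikes(
    t: np.ndarray, rate: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample an inhomogeneous Poisson spike train by thinning.

    Candidate events are drawn homogeneously at the peak rate over the span
    of ``t`` and kept with probability rate(t)/peak, with rate(t) linearly
    interpolated.  The expected count is the integral of the rate.
    """
    if np.any(rate < 0):
        raise ValueError("rate must be nonnegative")
    lam = float(rate.max())
    if lam == 0:
        return np.empty(0)
    span = float(t[-1] - t[0])
    n_cand = rng.poisson(lam * span)
    cand = np.sort(t[0] + rng.random(n_cand) * span)
    keep = rng.random(n_cand) * lam < np.interp(cand, t, rate)
    return cand[keep]


def generate_session(
    config: TaskConfig | None = None,
    motor: MotorParams | None = None,
    units: Sequence[UnitGroundTruth] | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """Generate a full session: events, trajectory and spikes for every unit.

    Per-unit random streams are derived from the master seed by fixed
    offsets, so adding or removing a unit never changes the task, the
    trajectory, or the spike trains of the other units.
    """
    config = config or TaskConfig()
    motor = motor or MotorParams()
    if units is None:
        units = default_unit_set()
    events = generate_task_events(config, seed)
    observed, clean, reach_truth = generate_trajectory(events, config, motor, seed)
    feats = clean_features(clean, reach_truth, config)
    spikes: dict[str, np.ndarray] = {}
    for i, gt in enumerate(units):
        t, rate = unit_rate(feats, reach_truth, gt, config)
        spikes[gt.unit_id] = generate_spikes(t, rate, stream_rng(seed, STREAM_UNIT, i))
    return SyntheticSession(
        config=config,
        motor=motor,
        events=events,
        trajectory=observed,
        clean=clean,
        spikes=spikes,
        ground_truth=list(units),
        reach_truth=reach_truth,
        seed=seed,
    )


def default_unit_set() -> list[UnitGroundTruth]:
    """A small default population spanning the modelled response classes."""
    return [
        UnitGroundTruth("u00_flat", baseline_rate=20.0),
        UnitGroundTruth(
            "u01_vel",
            baseline_rate=20.0,
            coupling={"vx": 5.0, "vy": 3.0, "vz": 1.0},
            true_lag_s=2 / 120,
        ),
        UnitGroundTruth(
            "u02_dir",
            baseline_rate=20.0,
            direction_gain=12.0,
            preferred_direction=(np.sqrt(0.5), np.sqrt(0.5), 0.0),
        ),
        UnitGroundTruth(
            "u03_err",
            baseline_rate=25.0,
            coupling={"ex": 4.0, "ey": 4.0, "e_mag": 4.0},
            true_lag_s=-3 / 120,
        ),
        UnitGroundTruth(
            "u04_speed_drift",
            baseline_rate=15.0,
            coupling={"speed": 6.0},
            drift_amplitude=0.3,
        ),
    ]


__all__ = [
    "COUPLING_FEATURES",
    "MotorParams",
    "SyntheticSession",
    "TaskConfig",
    "UnitGroundTruth",
    "clean_features",
    "default_unit_set",
    "generate_session",
    "generate_spikes",
    "generate_task_events",
    "generate_trajectory",
    "minimum_jerk",
    "unit_rate",
]
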