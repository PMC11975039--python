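"""Reach Start / Reach End detection and reach curation.

Movement onset and offset are defined on the fingertip velocity projected
onto the dominant reach direction.  The speed trace is zero-phase low-pass
filtered at 3 Hz to suppress essential-tremor oscillations (4-12 Hz) before
peak picking, and the same filter is applied to the 3D velocity used for the
projection.  For each trial:

1. find the time of peak filtered speed in a window from 0.5 s before to
   2.5 s after target display;
2. average the velocity in a 0.5 s window around that peak to get the
   dominant reach direction;
3. project velocity from 2 s before to 2 s after the peak onto that
   direction ("reach-aligned velocity");
4. Reach Start is the last time before the peak at which the reach-aligned
   velocity became positive, or showed a local minimum below 5% of its peak;
   Reach End is the first time after the peak at which it became negative,
   or showed such a sub-5% minimum.

Trials where no start or end satisfies these rules are marked invalid.
Curation then discards duration outliers (above Q3 + 1.5·IQR of the
session's durations) and flags sessions with fewer than 25 valid reaches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

REACH_COLUMNS = [
    "trial", "target_id", "outward", "t_target_on_s",
    "t_start_s", "t_peak_s", "t_end_s", "duration_s",
    "dir_x", "dir_y", "dir_z", "valid", "reason",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the event detector, defaults as used in the analyses."""

    lowpass_hz: float = 3.0
    filter_order: int = 4            # applied zero-phase (forward-backward)
    peak_window_s: tuple[float, float] = (-0.5, 2.5)   # around target display
    direction_window_s: float = 0.5  # centered on the speed peak
    projection_window_s: float = 2.0 # each side of the speed peak
    minimum_fraction: float = 0.05   # sub-5%-of-peak minimum fallback
    max_duration_iqr: float = 1.5    # Q3 + 1.5 IQR duration-outlier rule
    min_valid_reaches: int = 25


def _lowpass(x: np.ndarray, fs: float, cfg: DetectionConfig) -> np.ndarray:
    sos = butter(cfg.filter_order, cfg.lowpass_hz, fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=0)


def _crossings_and_minima(r: np.ndarray, thresh: float):
    """Candidate onset/offset samples of the reach-aligned velocity ``r``.

    Returns (up, down, minima): indices where r crosses into positive
    territory (the first positive sample), where it leaves it (the last
    positive sample), and strict local minima below ``thresh``.
    """
    up = np.nonzero((r[:-1] <= 0) & (r[1:] > 0))[0] + 1
    down = np.nonzero((r[:-1] > 0) & (r[1:] <= 0))[0]
    interior = np.nonzero((r[1:-1] < r[:-2]) & (r[1:-1] < r[2:]))[0] + 1
    minima = interior[r[interior] < thresh]
    return up, down, minima


def detect_reach(
    features: pd.DataFrame,
    t_target_on: float,
    cfg: DetectionConfig = DetectionConfig(),
    *,
    _filtered: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Detect one reach around a target-display event.

    ``features`` is a kinematic feature table covering at least
    ``[t_target_on - 2.5 s, t_target_on + 4.5 s]``.  Returns a dict of
    ReachEvent fields (without trial labels).  ``_filtered`` lets a caller
    pass pre-filtered (speed, velocity) arrays to avoid refiltering per
    trial.
    """
    t = features["t_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    if _filtered is None:
        speed_f = _lowpass(features["speed"].to_numpy(), fs, cfg)
        vel_f = _lowpass(features[["vx", "vy", "vz"]].to_numpy(), fs, cfg)
    else:
        speed_f, vel_f = _filtered

    out = {
        "t_target_on_s": t_target_on,
        "t_start_s": np.nan, "t_peak_s": np.nan, "t_end_s": np.nan,
        "duration_s": np.nan, "dir_x": np.nan, "dir_y": np.nan, "dir_z": np.nan,
        "valid": False, "reason": "undetectable",
    }

    lo, hi = cfg.peak_window_s
    win = (t >= t_target_on + lo) & (t <= t_target_on + hi)
    if not np.any(win):
        return out
    ipk = np.nonzero(win)[0][np.argmax(speed_f[win])]
    t_peak = t[ipk]

    half = cfg.direction_window_s / 2
    dwin = (t >= t_peak - half) & (t <= t_peak + half)
    direction = vel_f[dwin].mean(axis=0)
    norm = np.linalg.norm(direction)
    if norm == 0:
        return out
    direction = direction / norm

    pwin = (t >= t_peak - cfg.projection_window_s) & (t <= t_peak + cfg.projection_window_s)
    idx = np.nonzero(pwin)[0]
    r = vel_f[idx] @ direction
    ipk_local = int(np.searchsorted(idx, ipk))
    thresh = cfg.minimum_fraction * float(r[ipk_local])
    up, down, minima = _crossings_and_minima(r, thresh)

    start_cands = np.concatenate([up[up <= ipk_local], minima[minima <= ipk_local]])
    end_cands = np.concatenate([down[down >= ipk_local], minima[minima >= ipk_local]])
    if start_cands.size == 0 or end_cands.size == 0:
        return out
    i_start = idx[int(start_cands.max())]
    i_end = idx[int(end_cands.min())]
    if t[i_start] >= t_peak or t[i_end] <= t_peak:
        return out

    out.update(
        t_start_s=t[i_start], t_peak_s=t_peak, t_end_s=t[i_end],
        duration_s=t[i_end] - t[i_start],
        dir_x=direction[0], dir_y=direction[1], dir_z=direction[2],
        valid=True, reason="",
    )
    return out


def detect_reaches(
    features: pd.DataFrame,
    events: pd.DataFrame,
    config,
    cfg: DetectionConfig = DetectionConfig(),
) -> pd.DataFrame:
    """Detect outward and inward reaches for every trial of a session.

    The outward reach is cued by the outer-target display
    (``target_on_s``); the inward reach by the center re-display,
    ``target_display_s`` later.  Outward reaches to target d and inward
    reaches from the diametrically opposite target share a movement
    direction; direction labels for tuning therefore use the *outward
    equivalent* target id, ``direction_label``.
    """
    t = features["t_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    filtered = (
        _lowpass(features["speed"].to_numpy(), fs, cfg),
        _lowpass(features[["vx", "vy", "vz"]].to_numpy(), fs, cfg),
    )
    n_targets = config.n_targets
    rows = []
    for ev in events.itertuples(index=False):
        for outward in (True, False):
            t_on = ev.target_on_s if outward else ev.target_on_s + config.target_display_s
            rec = detect_reach(features, t_on, cfg, _filtered=filtered)
            rec["trial"] = ev.trial
            rec["target_id"] = ev.target_id
            rec["outward"] = outward
            if outward:
                label = ev.target_id
            else:  # inward from target d moves like outward to the opposite target
                label = (ev.target_id - 1 + n_targets // 2) % n_targets + 1
            rec["direction_label"] = label
            rows.append(rec)
    return pd.DataFrame(rows)[REACH_COLUMNS + ["direction_label"]]


def curate_reaches(
    reaches: pd.DataFrame, cfg: DetectionConfig = DetectionConfig()
) -> tuple[pd.DataFrame, bool]:
    """Apply the duration-outlier rule and the minimum-reach-count rule.

    Durations above Q3 + 1.5·IQR (linear-interpolation quantiles over the
    session's detected durations) are excluded with reason
    ``duration_outlier``.  Returns ``(curated table, session_ok)`` where
    ``session_ok`` is False when fewer than ``min_valid_reaches`` survive.
    """
    if len(reaches) == 0:
        raise ValueError("no reaches to curate")
    out = reaches.copy()
    durations = out.loc[out["valid"], "duration_s"].to_numpy()
    if durations.size:
        q1, q3 = np.percentile(durations, [25, 75])
        threshold = q3 + cfg.max_duration_iqr * (q3 - q1)
        outlier = out["valid"] & (out["duration_s"] > threshold)
        out.loc[outlier, "valid"] = False
        out.loc[outlier, "reason"] = "duration_outlier"
    session_ok = int(out["valid"].sum()) >= cfg.min_valid_reaches
    return out, session_ok


__all__ = [
    "DetectionConfig",
    "REACH_COLUMNS",
    "curate_reaches",
    "detect_reach",
    "detect_reaches",
]
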