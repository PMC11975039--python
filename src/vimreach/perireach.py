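"""Peri-reach firing-rate grids, modulation and directional-tuning tests.

Reaches differ in duration, so peri-reach rates are put on a *stretched*
grid: 150 samples at 10 ms steps over the 1.5 s before Reach Start, 80
evenly spaced samples between Reach Start and Reach End regardless of
duration (inclusive of both endpoints, spacing duration/79), and 150
samples at 10 ms steps over the 1.5 s after Reach End — 380 samples per
reach, aligned sample-to-sample across reaches.

Modulation against baseline is assessed by a Monte-Carlo shuffle: the mean
peri-reach rate at each grid point is compared with the distribution of
means of equally sized samples of the rate taken at uniformly random times
over the entire recording.  A unit is modulated when its empirical
two-sided p-value stays below alpha for at least ``contiguity_min``
consecutive samples, with at least one such run intersecting the analysis
window from 400 ms before Reach Start to 400 ms after Reach End.

Directional tuning applies a tie-corrected Kruskal-Wallis test across
reach-direction groups at every grid point, with the same contiguity and
window rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import distributions, rankdata

from vimreach._utils import contiguous_runs
from vimreach.rates import RateFunction

N_PRE = 150
N_STRETCH = 80
N_POST = 150
N_GRID = N_PRE + N_STRETCH + N_POST
STEP_S = 0.010
MARGIN_S = 1.5
ANALYSIS_WINDOW_S = 0.4

PHASE_PRE, PHASE_FIRST, PHASE_SECOND, PHASE_POST = 0, 1, 2, 3
PHASE_NAMES = {PHASE_PRE: "pre", PHASE_FIRST: "first_half",
               PHASE_SECOND: "second_half", PHASE_POST: "post"}

MODES = ("stretched", "realtime", "cue_aligned", "go_aligned", "peak_aligned")


@dataclass
class PeriReachGrid:
    """Firing rates of one unit on the peri-reach grid.

    ``times`` and ``values`` are (n_reaches, n_grid); ``phase`` labels each
    grid column (pre / first_half / second_half / post) and ``mask`` marks
    the −400 ms…+400 ms analysis window.
    """

    unit_id: str
    mode: str
    times: np.ndarray
    values: np.ndarray
    phase: np.ndarray
    mask: np.ndarray
    reaches: pd.DataFrame
    endpoint_convention: str = "inclusive"

    @property
    def n_reaches(self) -> int:
        return self.values.shape[0]

    @property
    def mean_fr(self) -> np.ndarray:
        return self.values.mean(axis=0)


def _stretched_times(reaches: pd.DataFrame, convention: str = "inclusive") -> np.ndarray:
    """Per-reach grid times: 150 pre, 80 in-reach, 150 post samples."""
    starts = reaches["t_start_s"].to_numpy()[:, None]
    ends = reaches["t_end_s"].to_numpy()[:, None]
    dur = ends - starts
    pre = starts - MARGIN_S + STEP_S * np.arange(N_PRE)         # [-1.5 s, t_start)
    post = ends + STEP_S * (np.arange(N_POST) + 1)              # (t_end, +1.5 s]
    if convention == "inclusive":
        frac = np.arange(N_STRETCH) / (N_STRETCH - 1)           # both endpoints
    elif convention == "midpoint":
        frac = (np.arange(N_STRETCH) + 0.5) / N_STRETCH
    else:
        raise ValueError(f"unknown endpoint convention {convention!r}")
    inreach = starts + dur * frac
    return np.hstack([pre, inreach, post])


def _grid_phase_and_mask() -> tuple[np.ndarray, np.ndarray]:
    phase = np.empty(N_GRID, dtype=int)
    phase[:N_PRE] = PHASE_PRE
    phase[N_PRE : N_PRE + N_STRETCH // 2] = PHASE_FIRST
    phase[N_PRE + N_STRETCH // 2 : N_PRE + N_STRETCH] = PHASE_SECOND
    phase[N_PRE + N_STRETCH :] = PHASE_POST
    n_edge = int(np.round(ANALYSIS_WINDOW_S / STEP_S))
    mask = np.zeros(N_GRID, dtype=bool)
    mask[N_PRE - n_edge : N_PRE + N_STRETCH + n_edge] = True
    return phase, mask


def build_grid(
    rate: RateFunction,
    reaches: pd.DataFrame,
    mode: str = "stretched",
    events: pd.DataFrame | None = None,
    endpoint_convention: str = "inclusive",
) -> PeriReachGrid:
    """Evaluate a unit's (50 ms-smoothed) rate on the peri-reach grid.

    ``mode`` selects the alignment: ``stretched`` (the default analysis),
    ``realtime`` (fixed 10 ms steps from Reach Start, no stretching), or
    ``cue_aligned`` / ``go_aligned`` / ``peak_aligned`` (fixed steps around
    the cue, target display, or speed peak).  Reaches shorter than two
    kinematic samples are skipped with a warning.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    ok = reaches[reaches["valid"]].copy()
    too_short = ok["duration_s"] < 2 / 120
    if too_short.any():
        import warnings

        warnings.warn(f"skipping {int(too_short.sum())} reaches shorter than 2 samples")
        ok = ok[~too_short]
    ok = ok.reset_index(drop=True)

    if mode == "stretched":
        times = _stretched_times(ok, endpoint_convention)
        phase, mask = _grid_phase_and_mask()
    else:
        anchor = {
            "realtime": ok["t_start_s"],
            "peak_aligned": ok["t_peak_s"],
            "go_aligned": ok["t_target_on_s"],
            "cue_aligned": ok["t_target_on_s"] - 0.7 if events is None
            else ok["trial"].map(events.set_index("trial")["cue_on_s"]),
        }[mode].to_numpy()[:, None]
        offsets = STEP_S * np.arange(N_GRID) - MARGIN_S
        times = anchor + offsets
        med_dur = float(np.median(ok["duration_s"]))
        rel = offsets.ravel()
        phase = np.full(N_GRID, PHASE_POST, dtype=int)
        phase[rel < med_dur] = PHASE_SECOND
        phase[rel < med_dur / 2] = PHASE_FIRST
        phase[rel < 0] = PHASE_PRE
        mask = (rel >= -ANALYSIS_WINDOW_S) & (rel <= med_dur + ANALYSIS_WINDOW_S)

    values = rate(times)
    return PeriReachGrid(
        unit_id=rate.unit_id, mode=mode, times=times, values=values,
        phase=phase, mask=mask, reaches=ok, endpoint_convention=endpoint_convention,
    )


def mean_speed_profile(grid: PeriReachGrid, features: pd.DataFrame) -> np.ndarray:
    """Grand-mean fingertip speed on the same grid, by cubic-spline resampling."""
    valid = features["valid"].to_numpy()
    spline = CubicSpline(features["t_s"].to_numpy()[valid], features["speed"].to_numpy()[valid])
    return spline(grid.times).mean(axis=0)


def shuffle_baseline(
    rate: RateFunction,
    n_reaches: int,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | None = None,
    span: tuple[float, float] | None = None,
) -> np.ndarray:
    """Shuffle-derived baseline distribution of mean firing rates.

    Each entry is the mean of ``n_reaches`` rate values sampled at
    uniformly random times over the entire recording (reach epochs
    included).
    """
    rng = rng or np.random.default_rng()
    t0, t1 = span if span is not None else rate.span
    times = rng.uniform(t0, t1, size=(n_shuffles, n_reaches))
    return rate(times).mean(axis=1)


@dataclass
class ModulationResult:
    """Outcome of the peri-reach modulation test for one unit."""

    unit_id: str
    mean_fr: np.ndarray
    p_pos: np.ndarray                 # one-sided, add-one smoothed
    p_neg: np.ndarray
    sign: np.ndarray                  # +1 / -1 / 0 per grid sample
    intervals: list[tuple[int, int, int]]  # (start, stop, sign), half-open, kept runs
    is_modulated: bool
    flags: list[str] = field(default_factory=list)

    @property
    def onset_indices(self) -> np.ndarray:
        return np.array([s for s, _, _ in self.intervals], dtype=int)

    @property
    def end_indices(self) -> np.ndarray:
        return np.array([e - 1 for _, e, _ in self.intervals], dtype=int)


def _significant_runs(
    flags: np.ndarray, contiguity_min: int, mask: np.ndarray
) -> tuple[list[tuple[int, int]], bool]:
    runs = [(a, b) for a, b in contiguous_runs(flags) if b - a >= contiguity_min]
    hits = any(mask[a:b].any() for a, b in runs)
    return runs, hits


def test_modulation(
    grid: PeriReachGrid,
    baseline: np.ndarray,
    alpha: float = 0.01,
    contiguity_min: int = 5,
) -> ModulationResult:
    """Compare the observed mean peri-reach rate with the shuffle baseline.

    A grid sample is significantly positive when the observed mean exceeds
    the (1 − alpha/2) quantile of the baseline (add-one-smoothed empirical
    tail), negative below the alpha/2 quantile.  Runs of same-sign
    significant samples shorter than ``contiguity_min`` are rejected; the
    unit counts as modulated when a surviving run intersects the analysis
    window.
    """
    obs = grid.mean_fr
    n = baseline.size
    flags: list[str] = []
    if np.ptp(baseline) == 0:
        flags.append("degenerate_baseline")
        p_pos = p_neg = np.ones(obs.size)
    else:
        sorted_base = np.sort(baseline)
        n_less = np.searchsorted(sorted_base, obs, side="left")
        n_greater = n - np.searchsorted(sorted_base, obs, side="right")
        p_pos = (n_greater + 1) / (n + 1)  # P(baseline >= obs)
        p_neg = (n_less + 1) / (n + 1)
    sign = np.zeros(obs.size, dtype=int)
    sign[p_pos < alpha / 2] = 1
    sign[p_neg < alpha / 2] = -1

    intervals: list[tuple[int, int, int]] = []
    modulated = False
    for s in (1, -1):
        runs, hit = _significant_runs(sign == s, contiguity_min, grid.mask)
        intervals += [(a, b, s) for a, b in runs]
        modulated |= hit
    intervals.sort()
    kept = np.zeros(obs.size, dtype=bool)
    for a, b, _ in intervals:
        kept[a:b] = True
    sign[~kept] = 0
    return ModulationResult(
        unit_id=grid.unit_id, mean_fr=obs, p_pos=p_pos, p_neg=p_neg,
        sign=sign, intervals=intervals, is_modulated=modulated, flags=flags,
    )


def kruskal_pvalues(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Tie-corrected Kruskal-Wallis p-value at every grid column.

    ``values`` is (n_reaches, n_cols); ``labels`` groups the rows.  Matches
    :func:`scipy.stats.kruskal` column-by-column but ranks all columns at
    once.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n, n_cols = values.shape
    ranks = rankdata(values, axis=0)
    h = np.zeros(n_cols)
    for g in groups:
        sel = labels == g
        h += ranks[sel].sum(axis=0) ** 2 / sel.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction per column
    correction = np.ones(n_cols)
    sorted_vals = np.sort(values, axis=0)
    has_ties = (sorted_vals[1:] == sorted_vals[:-1]).any(axis=0)
    for j in np.nonzero(has_ties)[0]:
        _, counts = np.unique(sorted_vals[:, j], return_counts=True)
        correction[j] = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(correction > 0, h / correction, np.nan)
    return distributions.chi2.sf(h, groups.size - 1)


@dataclass
class TuningResult:
    """Outcome of the directional-tuning test for one unit."""

    unit_id: str
    p: np.ndarray
    severity: np.ndarray              # 0 n.s., 1 "gray" p<0.05, 2 "black" p<0.01
    intervals: list[tuple[int, int]]
    is_tuned: bool
    groups: np.ndarray


def test_directional_tuning(
    grid: PeriReachGrid,
    alpha: float = 0.05,
    contiguity_min: int = 5,
    min_group_size: int = 3,
) -> TuningResult:
    """Kruskal-Wallis test of rate across reach-direction groups per sample.

    Direction groups pool outward reaches to a target with inward reaches
    from the diametrically opposite target (same movement direction, via
    the ``direction_label`` column).  Groups with fewer than
    ``min_group_size`` reaches are dropped; at least two groups must
    remain.
    """
    labels = grid.reaches["direction_label"].to_numpy()
    keep_groups = [g for g in np.unique(labels) if (labels == g).sum() >= min_group_size]
    if len(keep_groups) < 2:
        raise ValueError("need at least 2 direction groups with enough reaches")
    sel = np.isin(labels, keep_groups)
    p = kruskal_pvalues(grid.values[sel], labels[sel])
    severity = (p < 0.05).astype(int) + (p < 0.01).astype(int)
    runs, tuned = _significant_runs(p < alpha, contiguity_min, grid.mask)
    return TuningResult(
        unit_id=grid.unit_id, p=p, severity=severity,
        intervals=runs, is_tuned=tuned, groups=np.asarray(keep_groups),
    )


def spatial_heatmap(
    features: pd.DataFrame,
    rate: RateFunction,
    cell_mm: float = 15.0,
) -> pd.DataFrame:
    """Mean firing rate per 15 mm cell of the top-2-PC movement plane.

    3D fingertip positions are projected onto their top two principal
    components; the plane is tiled with ``cell_mm`` squares and the rate at
    each kinematic timepoint is averaged within the occupied cells.
    """
    from sklearn.decomposition import PCA

    valid = features["valid"].to_numpy()
    pos = features.loc[valid, ["x_mm", "y_mm", "z_mm"]].to_numpy()
    t = features.loc[valid, "t_s"].to_numpy()
    scores = PCA(n_components=2).fit_transform(pos)
    cells = np.floor(scores / cell_mm).astype(int)
    fr = rate(t)
    df = pd.DataFrame({"ix": cells[:, 0], "iy": cells[:, 1], "fr": fr})
    out = df.groupby(["ix", "iy"], as_index=False).agg(
        mean_fr=("fr", "mean"), n_samples=("fr", "size")
    )
    return out


__all__ = [
    "ANALYSIS_WINDOW_S",
    "MODES",
    "ModulationResult",
    "N_GRID",
    "N_PRE",
    "N_POST",
    "N_STRETCH",
    "PHASE_NAMES",
    "PHASE_PRE",
    "PHASE_FIRST",
    "PHASE_SECOND",
    "PHASE_POST",
    "PeriReachGrid",
    "TuningResult",
    "build_grid",
    "kruskal_pvalues",
    "mean_speed_profile",
    "shuffle_baseline",
    "spatial_heatmap",
    "test_directional_tuning",
    "test_modulation",
]
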