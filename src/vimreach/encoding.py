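"""Lagged linear encoding models of firing rate on kinematics and error.

For each unit, the 15 ms-smoothed, sliding-z-scored firing rate is
regressed (ordinary least squares) on normalized kinematic regressors
sampled at native kinematic times within 250 ms before each valid Reach
Start to 250 ms after the subsequent Reach End.  Two regressor sets are
used: *kinematics only* (3D position, 3D velocity, speed, 3D acceleration,
acceleration magnitude, signed acceleration; 12 columns, 6 groups) and
*kinematics + error*, which adds the 3D error vector (instantaneous
position minus the mean hold position 0–1 s after the reach, a proxy for
the goal position) and its magnitude (16 columns, 8 groups).

The regression is repeated over a grid of neural-to-kinematic lags (±1 s in
8.33 ms = one-kinematic-sample steps; positive lag means the rate sample
follows the kinematics).  Significance uses a circular-shift null: the rate
is evaluated at times rotated by a uniform random offset spanning the whole
recording, with wrap-around, preserving autocorrelation while destroying
alignment.  R² is attributed to individual regressors by exact Shapley
decomposition over all 2^p regressor subsets; per-column values sum to the
full-model R² and 3D groups sum their component columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vimreach.rates import RateFunction

KINEMATIC_COLUMNS = [
    "x_mm", "y_mm", "z_mm", "vx", "vy", "vz", "speed",
    "ax", "ay", "az", "a_mag", "a_signed",
]
ERROR_COLUMNS = ["ex", "ey", "ez", "e_mag"]

GROUPS = {
    "3D position": ["x_mm", "y_mm", "z_mm"],
    "3D velocity": ["vx", "vy", "vz"],
    "speed": ["speed"],
    "3D acceleration": ["ax", "ay", "az"],
    "acceleration magnitude": ["a_mag"],
    "signed acceleration": ["a_signed"],
    "3D error": ["ex", "ey", "ez"],
    "error magnitude": ["e_mag"],
}

REGRESSOR_SETS = {
    "kinematics_only": KINEMATIC_COLUMNS,
    "kinematics_plus_error": KINEMATIC_COLUMNS + ERROR_COLUMNS,
}

#: Lag grid: ±1 s in steps of one kinematic sample (1/120 s), 241 lags.
LAG_STEP_S = 1.0 / 120.0
DEFAULT_LAGS_S = np.arange(-120, 121) * LAG_STEP_S

WINDOWS = ("reach", "start_centered", "end_centered")


@dataclass
class Design:
    """Normalized regressor matrix with provenance.

    ``X`` has zero-mean, unit-sd columns; ``times`` are the kinematic
    sample times each row was taken at.  Zero-variance columns are dropped
    before normalization and listed in ``dropped``.
    """

    X: np.ndarray
    columns: list[str]
    times: np.ndarray
    reach_index: np.ndarray
    set_name: str
    window: str
    dropped: list[str] = field(default_factory=list)
    _basis: tuple | None = field(default=None, repr=False, compare=False)

    def basis(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Cached ``(Q, X, columns)`` orthonormal basis of the design."""
        if self._basis is None:
            self._basis = _orthonormal_basis(self.X, list(self.columns))
        return self._basis

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group map restricted to the surviving columns."""
        out = {}
        for name, cols in GROUPS.items():
            kept = [c for c in cols if c in self.columns]
            if kept:
                out[name] = kept
        return out


def build_design(
    features: pd.DataFrame,
    reaches: pd.DataFrame,
    regressor_set: str = "kinematics_only",
    window: str = "reach",
    margin_s: float = 0.25,
    hold_window_s: tuple[float, float] = (0.0, 1.0),
) -> Design:
    """Assemble the normalized regressor matrix from 15 ms-smoothed features.

    ``window`` selects the sampled epochs: ``reach`` takes
    [Reach Start − 250 ms, Reach End + 250 ms] per valid reach;
    ``start_centered`` / ``end_centered`` take 500 ms windows centered on
    Reach Start / Reach End (used for the zero-lag windowed regressions).
    Error columns are computed per reach against the mean position in the
    0–1 s hold after that reach's end; reaches whose hold window extends
    past the recording are dropped from error-set samples with a warning.
    """
    if regressor_set not in REGRESSOR_SETS:
        raise ValueError(f"unknown regressor set {regressor_set!r}")
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    needs_error = regressor_set == "kinematics_plus_error"
    t = features["t_s"].to_numpy()
    valid = features["valid"].to_numpy()
    t_max = t[valid].max()

    blocks, times, reach_idx = [], [], []
    base_cols = KINEMATIC_COLUMNS
    for k, r in enumerate(reaches[reaches["valid"]].itertuples(index=False)):
        if window == "reach":
            lo, hi = r.t_start_s - margin_s, r.t_end_s + margin_s
        elif window == "start_centered":
            lo, hi = r.t_start_s - margin_s, r.t_start_s + margin_s
        else:
            lo, hi = r.t_end_s - margin_s, r.t_end_s + margin_s
        sel = (t >= lo) & (t <= hi) & valid
        if not sel.any():
            continue
        block = features.loc[sel, base_cols].to_numpy(dtype=float)
        if needs_error:
            hold = (t > r.t_end_s + hold_window_s[0]) & (t <= r.t_end_s + hold_window_s[1]) & valid
            if r.t_end_s + hold_window_s[1] > t_max or not hold.any():
                warnings.warn(
                    f"reach at t={r.t_start_s:.2f}s: hold window exceeds recording; "
                    "dropped from error-model samples"
                )
                continue
            goal = features.loc[hold, ["x_mm", "y_mm", "z_mm"]].to_numpy().mean(axis=0)
            err = features.loc[sel, ["x_mm", "y_mm", "z_mm"]].to_numpy() - goal
            block = np.hstack([block, err, np.linalg.norm(err, axis=1)[:, None]])
        blocks.append(block)
        times.append(t[sel])
        reach_idx.append(np.full(sel.sum(), k))
    if not blocks:
        raise ValueError("no samples in the requested windows")
    X = np.vstack(blocks)
    cols = list(REGRESSOR_SETS[regressor_set])

    sd = X.std(axis=0)
    dropped = [c for c, s in zip(cols, sd) if s == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Design(
        X=X,
        columns=[c for c, k in zip(cols, keep) if k],
        times=np.concatenate(times),
        reach_index=np.concatenate(reach_idx),
        set_name=regressor_set,
        window=window,
        dropped=dropped,
    )


def _orthonormal_basis(X: np.ndarray, columns: list[str]):
    """Economic QR of the centered design; drops rank-deficient columns."""
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        lost = [columns[j] for j in piv[rank:]]
        warnings.warn(f"rank-deficient design; dropping columns {lost}")
        keep = np.sort(piv[:rank])
        X = X[:, keep]
        columns = [columns[j] for j in keep]
        q, _ = np.linalg.qr(X)
    return q, X, columns


def _r2_matrix(q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """R² of OLS fits of each (column of) Y on the design with basis ``q``."""
    Yc = Y - Y.mean(axis=0)
    ss_tot = (Yc**2).sum(axis=0)
    ss_fit = (q.T @ Yc) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ss_tot > 0, ss_fit.sum(axis=0) / ss_tot, 0.0)


@dataclass
class EncodingResult:
    """Per-unit, per-regressor-set encoding fit across lags."""

    unit_id: str
    set_name: str
    window: str
    lags_s: np.ndarray
    r2: np.ndarray
    adj_r2: np.ndarray
    n_samples: int
    n_params: int
    columns: list[str]
    optimal_index: int = -1
    null_r2: np.ndarray | None = None
    p_value: float | None = None
    significant: bool | None = None
    shapley: pd.DataFrame | None = None

    @property
    def optimal_lag_s(self) -> float:
        return float(self.lags_s[self.optimal_index])

    @property
    def optimal_r2(self) -> float:
        return float(self.r2[self.optimal_index])

    @property
    def optimal_adj_r2(self) -> float:
        return float(self.adj_r2[self.optimal_index])


def adjusted_r2(r2: np.ndarray, n: int, p: int) -> np.ndarray:
    """Ezekiel small-sample correction: 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    return 1.0 - (1.0 - np.asarray(r2)) * (n - 1) / (n - p - 1)


def lagged_regression(
    design: Design,
    rate: RateFunction,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
) -> EncodingResult:
    """OLS of the unit's rate on the design at every lag.

    The response at lag L is the rate evaluated at ``times + L`` (positive
    lag: neural activity follows the kinematics).  The optimal lag is the
    argmax of R²; adjusted R² is reported for cross-model comparison.
    """
    lags_s = np.asarray(lags_s, dtype=float)
    q, X, columns = design.basis()
    i0, f = _interp_weights(design.times[:, None] + lags_s[None, :], rate)
    Y = rate.rate[i0] * (1.0 - f) + rate.rate[i0 + 1] * f
    r2 = _r2_matrix(q, Y)
    n, p = X.shape
    res = EncodingResult(
        unit_id=rate.unit_id, set_name=design.set_name, window=design.window,
        lags_s=lags_s, r2=r2, adj_r2=adjusted_r2(r2, n, p),
        n_samples=n, n_params=p, columns=columns,
        optimal_index=int(np.argmax(r2)),
    )
    return res


def _interp_weights(times: np.ndarray, rate: RateFunction) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation stencil of ``times`` on the rate's 1 ms grid.

    Returns ``(i0, frac)`` such that evaluating the rate at ``times``
    equals ``r[i0]·(1−frac) + r[i0+1]·frac`` — identical to
    :meth:`RateFunction.__call__` including the clamped extrapolation.
    """
    n = rate.rate.size
    pos = (times - rate.t0) / rate.bin_s - 0.5
    i0 = np.clip(np.floor(pos), 0, n - 2).astype(np.intp)
    frac = np.clip(pos - i0, 0.0, 1.0)
    return i0, frac


def r2_all_circular_shifts(design: Design, rate: RateFunction, at_lag_s: float = 0.0) -> np.ndarray:
    """R² of the regression for *every* circular shift of the rate register.

    Rotating the 1 ms rate array by k bins and re-evaluating at the design
    times is a fixed linear stencil applied at offset positions, so the
    sufficient statistics of the OLS fit (Σy, Σy², Qᵀy) for all n shifts
    are circular cross-correlations of the rate (and its square and
    lag-one product) with scattered stencil weights, computed here by FFT.
    Entry 0 is the unshifted (observed) R².
    """
    from scipy import fft as sfft

    q, _, _ = design.basis()
    r = rate.rate
    n = r.size
    n_samp, n_col = q.shape
    i0, f = _interp_weights(design.times + at_lag_s, rate)
    w0, w1 = 1.0 - f, f

    def scatter(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        np.add.at(out, idx, values)
        return out

    # stencil weight vectors whose circular correlation with the rate (or
    # derived series) yields Σ_j q_j·y, Σ_j y, Σ_j y² at every shift
    specs = [scatter(q[:, c] * w0, i0) + scatter(q[:, c] * w1, i0 + 1) for c in range(n_col)]
    specs.append(scatter(w0, i0) + scatter(w1, i0 + 1))          # -> Σ y
    specs.append(scatter(w0**2, i0) + scatter(w1**2, i0 + 1))    # -> Σ y² (squared terms)
    specs.append(scatter(2.0 * w0 * w1, i0))                     # -> Σ y² (cross term)
    targets = [r] * (n_col + 1) + [r * r, r * np.roll(r, -1)]

    fts = {}
    corr = np.empty((len(specs), n))
    for k, (w, tgt) in enumerate(zip(specs, targets)):
        key = id(tgt)
        if key not in fts:
            fts[key] = sfft.rfft(tgt)
        corr[k] = sfft.irfft(np.conj(sfft.rfft(w)) * fts[key], n)

    qty = corr[:n_col]
    sum_y = corr[n_col]
    sum_y2 = corr[n_col + 1] + corr[n_col + 2]
    ss_tot = sum_y2 - sum_y**2 / n_samp
    ss_fit = (qty**2).sum(axis=0)  # q columns are zero-sum: centering y is free
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 1e-12 * n_samp, ss_fit / ss_tot, 0.0)
    return np.clip(r2, 0.0, 1.0)


def circular_shift_null(
    design: Design,
    rate: RateFunction,
    at_lag_s: float = 0.0,
    n_shifts: int = 10_000,
    rng: np.random.Generator | None = None,
    method: str = "circshift",
) -> tuple[np.ndarray, float]:
    """Chance R² distribution from circularly time-shifted rates.

    Each draw rotates the firing-rate register relative to the kinematic
    sample times by a random offset spanning the entire recording, with
    wrap-around past the end, and refits the regression.  ``circshift``
    (default) draws integer 1 ms-bin rotations and evaluates all of them
    exactly via :func:`r2_all_circular_shifts`; ``continuous`` draws real-
    valued offsets and interpolates (slower, used as a cross-check).
    Returns ``(null_r2, p_value)`` where the p-value is the add-one-
    smoothed exceedance probability of the observed (unshifted) R² at the
    same lag.
    """
    rng = rng or np.random.default_rng()
    q, _, _ = design.basis()
    obs = _r2_matrix(q, rate(design.times + at_lag_s)[:, None])[0]
    if method == "circshift":
        r2_all = r2_all_circular_shifts(design, rate, at_lag_s)
        null_r2 = r2_all[rng.integers(0, r2_all.size, size=n_shifts)]
    elif method == "continuous":
        t0, t1 = rate.span
        span = t1 - t0
        offsets = rng.uniform(0.0, span, size=n_shifts)
        base = design.times + at_lag_s - t0
        null_r2 = np.empty(n_shifts)
        chunk = max(1, int(2e7 // max(base.size, 1)))  # bound the working set
        for a in range(0, n_shifts, chunk):
            shifted = t0 + np.mod(base[:, None] + offsets[None, a : a + chunk], span)
            null_r2[a : a + chunk] = _r2_matrix(q, rate(shifted))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = (np.sum(null_r2 >= obs) + 1) / (n_shifts + 1)
    return null_r2, float(p)


def significance_test(
    design: Design,
    rate: RateFunction,
    result: EncodingResult,
    n_shifts: int = 10_000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.01,
    account_for_lag_selection: bool = True,
) -> EncodingResult:
    """Attach the circular-shift null and the unit-level significance call.

    With ``account_for_lag_selection`` (the default) each null draw mimics
    the full analysis: the rate register is rotated by a random offset and
    the *maximum* R² over the same lag grid is recorded, so the observed
    best-lag R² and the null draws are exchangeable under the null and the
    resulting p-values are uniform for response-independent units.  With
    ``account_for_lag_selection=False`` each draw is a single refit at the
    observed optimal lag (a cheaper, anti-conservative variant that
    ignores the selection of the best lag).  The unit is significant when
    the observed R² exceeds the ``1 − alpha`` quantile of the null.
    """
    rng = rng or np.random.default_rng()
    if account_for_lag_selection:
        r2_all = r2_all_circular_shifts(design, rate)
        n = r2_all.size
        lag_bins = np.round(result.lags_s / rate.bin_s).astype(np.intp)
        obs = float(r2_all[np.mod(lag_bins, n)].max())
        ks = rng.integers(0, n, size=n_shifts)
        null_r2 = r2_all[np.mod(ks[:, None] + lag_bins[None, :], n)].max(axis=1)
        p = (np.sum(null_r2 >= obs) + 1) / (n_shifts + 1)
    else:
        null_r2, p = circular_shift_null(
            design, rate, at_lag_s=result.optimal_lag_s, n_shifts=n_shifts, rng=rng
        )
        obs = result.optimal_r2
    result.null_r2 = null_r2
    result.p_value = float(p)
    result.significant = obs > float(np.quantile(null_r2, 1 - alpha))
    return result


def _subset_r2(corr_xx: np.ndarray, corr_xy: np.ndarray, p: int) -> np.ndarray:
    """R² of every regressor subset from the correlation (Gram) matrix.

    Subsets are indexed by bitmask and solved in batches grouped by subset
    size.  Singular batches (duplicated/collinear columns) fall back to
    least squares, under which R² stays well-defined even when the
    coefficients are not.
    """
    r2 = np.zeros(1 << p)
    by_size: dict[int, list[int]] = {}
    for mask in range(1, 1 << p):
        by_size.setdefault(mask.bit_count(), []).append(mask)
    for s, masks in by_size.items():
        idx = np.array(
            [[j for j in range(p) if mask >> j & 1] for mask in masks]
        )  # (m, s)
        gram = corr_xx[idx[:, :, None], idx[:, None, :]]
        c = corr_xy[idx]
        try:
            beta = np.linalg.solve(gram, c[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.stack(
                [np.linalg.lstsq(g, ci, rcond=None)[0] for g, ci in zip(gram, c)]
            )
        r2[masks] = np.einsum("ms,ms->m", c, beta)
    return r2


def shapley_decompose(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Exact Shapley attribution of the regression R² to each column.

    The Shapley value of column i is the average over all orderings of its
    marginal R² gain, i.e. ``Σ_S |S|!(p−|S|−1)!/p! · (R²(S∪{i}) − R²(S))``
    over subsets S not containing i.  Subset R² values come from the
    correlation matrix of the normalized design, not from refits on raw
    samples.  Per-column values sum to the full-model R²; group values sum
    their member columns.  Refuses p > 20 (exact enumeration only).
    """
    p = X.shape[1]
    if p > 20:
        raise ValueError(f"exact Shapley enumeration limited to 20 columns, got {p}")
    if len(columns) != p:
        raise ValueError("columns must match design width")
    yc = y - y.mean()
    xc = X - X.mean(axis=0)
    xn = xc / np.linalg.norm(xc, axis=0)
    yn = yc / np.linalg.norm(yc)
    corr_xx = xn.T @ xn
    corr_xy = xn.T @ yn
    r2 = _subset_r2(corr_xx, corr_xy, p)

    fact = [math.factorial(k) for k in range(p + 1)]
    weights = np.array([fact[s] * fact[p - s - 1] / fact[p] for s in range(p)])
    all_masks = np.arange(1 << p, dtype=np.uint32)
    sizes = np.bitwise_count(all_masks).astype(int)
    values = np.zeros(p)
    for i in range(p):
        bit = np.uint32(1 << i)
        without = all_masks[(all_masks & bit) == 0]
        w = weights[sizes[without]]
        values[i] = float(np.sum(w * (r2[without | bit] - r2[without])))

    full = r2[-1]
    out = pd.DataFrame({"column": columns, "value": values})
    col_group = {c: g for g, cols in (groups or GROUPS).items() for c in cols}
    out["group"] = out["column"].map(col_group)
    out["proportion"] = out["value"] / full if full > 0 else 0.0
    out.attrs["full_r2"] = float(full)
    return out


def windowed_regression(
    design: Design,
    rate: RateFunction,
    n_shifts: int = 10_000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> EncodingResult:
    """Zero-lag regression on a start- or end-centered windowed design.

    Used with 500 ms windows centered on Reach Starts or Reach Ends to ask
    *when* kinematic/error encoding is present; significance uses the same
    circular-shift null (no lag selection is involved at zero lag).
    """
    res = lagged_regression(design, rate, np.zeros(1))
    null_r2, p = circular_shift_null(design, rate, 0.0, n_shifts=n_shifts, rng=rng)
    res.null_r2 = null_r2
    res.p_value = p
    res.significant = res.optimal_r2 > float(np.quantile(null_r2, 1 - alpha))
    return res


def group_contributions(shapley: pd.DataFrame) -> pd.DataFrame:
    """Sum per-column Shapley values into regressor-group contributions."""
    out = shapley.groupby("group", as_index=False)[["value", "proportion"]].sum()
    return out.sort_values("value", ascending=False).reset_index(drop=True)


def encode_unit(
    design: Design,
    rate: RateFunction,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    n_shifts: int = 10_000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.01,
    run_shapley: bool = True,
    account_for_lag_selection: bool = True,
) -> EncodingResult:
    """Full per-unit encoding analysis: lag sweep, shift null, Shapley."""
    res = lagged_regression(design, rate, lags_s)
    res = significance_test(
        design, rate, res, n_shifts=n_shifts, rng=rng, alpha=alpha,
        account_for_lag_selection=account_for_lag_selection,
    )
    if run_shapley:
        _, X, columns = design.basis()
        y = rate(design.times + res.optimal_lag_s)
        res.shapley = shapley_decompose(X, y, columns, design.groups)
    return res


__all__ = [
    "DEFAULT_LAGS_S",
    "Design",
    "EncodingResult",
    "ERROR_COLUMNS",
    "GROUPS",
    "KINEMATIC_COLUMNS",
    "LAG_STEP_S",
    "REGRESSOR_SETS",
    "adjusted_r2",
    "build_design",
    "circular_shift_null",
    "encode_unit",
    "group_contributions",
    "lagged_regression",
    "r2_all_circular_shifts",
    "shapley_decompose",
    "significance_test",
    "windowed_regression",
]
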