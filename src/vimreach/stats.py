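"""Summary statistics and hypothesis tests over pipeline outputs.

Implements the comparisons reported alongside the analyses: chi-square
goodness-of-fit of significant-sample counts across reach phases (with
expectation proportional to the number of tested samples per phase),
two-proportion z-tests, Wilcoxon rank-sum comparisons, kernel density
estimates of modulation onset/end times, and the session-level report.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from vimreach.perireach import (
    PHASE_FIRST,
    PHASE_NAMES,
    PHASE_POST,
    PHASE_PRE,
    PHASE_SECOND,
    ModulationResult,
    PeriReachGrid,
)


def phase_bias_test(
    counts: Sequence[float], expected_weights: Sequence[float] | None = None
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of observed counts against weighted expectation.

    ``expected_weights`` (default: equal) are proportional to the number of
    tested samples in each category, e.g. phase durations on the peri-reach
    grid.  Returns ``(statistic, p)`` with df = categories − 1.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    w = np.ones(obs.size) if expected_weights is None else np.asarray(expected_weights, float)
    if np.any(w <= 0):
        raise ValueError("expected weights must be positive")
    expected = obs.sum() * w / w.sum()
    stat, p = sps.chisquare(obs, f_exp=expected)
    return float(stat), float(p)


def proportions_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test with pooled variance.

    Returns ``(z, p)`` for H0: the two success probabilities are equal.
    """
    from statsmodels.stats.proportion import proportions_ztest

    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    if k1 + k2 in (0, n1 + n2):  # degenerate pooled proportion
        return 0.0, 1.0
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def ranksum_compare(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    Uses the exact distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (no continuity
    correction, matching the textbook z statistic).  Returns ``(U, p)``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = max(x.size, y.size) <= 20
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def event_time_density(
    times: Sequence[float],
    grid: np.ndarray,
    bandwidth: str | float = "silverman",
) -> np.ndarray:
    """Gaussian KDE of modulation onset/end times evaluated on ``grid``.

    ``bandwidth`` follows :class:`scipy.stats.gaussian_kde` (Silverman's
    rule by default).  A single event yields a Gaussian bump at that time.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros(np.asarray(grid).size)
    if times.size == 1 or np.ptp(times) == 0:
        sd = 1.0 if isinstance(bandwidth, str) else float(bandwidth)
        return sps.norm.pdf(np.asarray(grid), loc=times[0], scale=sd)
    kde = sps.gaussian_kde(times, bw_method=bandwidth)
    return kde(np.asarray(grid))


def phase_sample_counts(
    results: Mapping[str, ModulationResult], phase: np.ndarray
) -> dict[str, dict[str, int]]:
    """Counts of significant samples per reach phase across units.

    Returns per-phase dicts of significant-sample counts, positive counts
    and tested totals (phase length × number of units).
    """
    phases = [PHASE_PRE, PHASE_FIRST, PHASE_SECOND, PHASE_POST]
    sig = {PHASE_NAMES[ph]: 0 for ph in phases}
    pos = dict(sig)
    for res in results.values():
        for ph in phases:
            sel = phase == ph
            sig[PHASE_NAMES[ph]] += int(np.sum(res.sign[sel] != 0))
            pos[PHASE_NAMES[ph]] += int(np.sum(res.sign[sel] > 0))
    totals = {PHASE_NAMES[ph]: int(np.sum(phase == ph)) * len(results) for ph in phases}
    return {"significant": sig, "positive": pos, "tested": totals}


def summarize(
    modulation: Mapping[str, ModulationResult] | None = None,
    tuning: Mapping[str, object] | None = None,
    encoding: Mapping[str, Mapping[str, object]] | None = None,
    grid_phase: np.ndarray | None = None,
) -> dict:
    """Headline quantities of a session analysis as a JSON-ready dict.

    Covers the fraction of modulated units, sign and phase distribution of
    significant samples, fraction of tuned units, per-model encoding
    fractions, optimal-lag summaries, top Shapley group tallies, and median
    adjusted R² per regressor set.  Empty inputs yield an empty report.
    """
    report: dict = {}
    if modulation:
        n = len(modulation)
        mod_units = [u for u, r in modulation.items() if r.is_modulated]
        n_sig = sum(int(np.sum(r.sign != 0)) for r in modulation.values())
        n_pos = sum(int(np.sum(r.sign > 0)) for r in modulation.values())
        report["modulation"] = {
            "n_units": n,
            "n_modulated": len(mod_units),
            "pct_modulated": 100.0 * len(mod_units) / n,
            "n_significant_samples": n_sig,
            "pct_positive_samples": 100.0 * n_pos / n_sig if n_sig else float("nan"),
        }
        if grid_phase is not None:
            counts = phase_sample_counts(modulation, grid_phase)
            report["modulation"]["phase_counts"] = counts
            sig = counts["significant"]
            in_reach = sig["first_half"] + sig["second_half"]
            if in_reach:
                report["modulation"]["pct_second_half_of_reach"] = (
                    100.0 * sig["second_half"] / in_reach
                )
            if n_sig:
                report["modulation"]["pct_in_reach"] = 100.0 * in_reach / n_sig
    if tuning:
        tuned = [u for u, r in tuning.items() if getattr(r, "is_tuned", False)]
        report["tuning"] = {
            "n_units": len(tuning),
            "n_tuned": len(tuned),
            "pct_tuned": 100.0 * len(tuned) / len(tuning),
        }
    if encoding:
        report["encoding"] = {}
        for set_name, per_unit in encoding.items():
            sig_units = {u: r for u, r in per_unit.items() if getattr(r, "significant", False)}
            entry: dict = {
                "n_units": len(per_unit),
                "n_significant": len(sig_units),
                "pct_significant": 100.0 * len(sig_units) / len(per_unit) if per_unit else 0.0,
            }
            if sig_units:
                lags = np.array([r.optimal_lag_s for r in sig_units.values()])
                adj = np.array([r.optimal_adj_r2 for r in sig_units.values()])
                r2s = np.array([r.optimal_r2 for r in sig_units.values()])
                entry["median_adj_r2"] = float(np.median(adj))
                entry["mean_r2"] = float(np.mean(r2s))
                entry["optimal_lag_ms"] = {
                    "median": float(np.median(lags) * 1000),
                    "values": [float(v * 1000) for v in lags],
                }
                tallies: dict[str, int] = {}
                for r in sig_units.values():
                    if r.shapley is not None:
                        top = (
                            r.shapley.groupby("group")["value"].sum().idxmax()
                        )
                        tallies[top] = tallies.get(top, 0) + 1
                entry["top_group_tallies"] = tallies
            report["encoding"][set_name] = entry
    return report


__all__ = [
    "event_time_density",
    "phase_bias_test",
    "phase_sample_counts",
    "proportions_test",
    "ranksum_compare",
    "summarize",
]
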