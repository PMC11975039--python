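"""Lagged encoding regressions, circular-shift nulls, Shapley attribution."""

import itertools
import math

import numpy as np
import pytest

from vimreach.encoding import (
    DEFAULT_LAGS_S,
    Design,
    adjusted_r2,
    build_design,
    circular_shift_null,
    group_contributions,
    lagged_regression,
    r2_all_circular_shifts,
    shapley_decompose,
)
from vimreach.rates import RateFunction


def brute_force_shapley(X, y):
    """Independent oracle: refit-on-raw-samples subset enumeration."""
    n, p = X.shape

    def r2_of(cols):
        if not cols:
            return 0.0
        A = np.column_stack([X[:, list(cols)], np.ones(n)])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        return 1 - resid.var() / y.var()

    values = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for k in range(p):
            for S in itertools.combinations(others, k):
                w = math.factorial(k) * math.factorial(p - k - 1) / math.factorial(p)
                values[i] += w * (r2_of(set(S) | {i}) - r2_of(S))
    return values


def _design_from_matrix(X, times=None, name="kinematics_only"):
    n, p = X.shape
    Xn = (X - X.mean(axis=0)) / X.std(axis=0)
    cols = [f"c{i}" for i in range(p)]
    return Design(
        X=Xn, columns=cols,
        times=np.linspace(1.0, 9.0, n) if times is None else times,
        reach_index=np.zeros(n), set_name=name, window="reach",
    )


class TestShapley:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, p = 200, rng.integers(2, 6)
            X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))  # correlated
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            sh = shapley_decompose(X, y, [f"c{i}" for i in range(p)], {"g": []})
            np.testing.assert_allclose(
                sh["value"].to_numpy(), brute_force_shapley(X, y), atol=1e-10
            )

    def test_orthogonal_columns_get_squared_correlations(self):
        rng = np.random.default_rng(1)
        n, p = 500, 5
        Z = rng.normal(size=(n, p))
        X, _ = np.linalg.qr(Z - Z.mean(axis=0))  # zero-mean orthonormal columns
        y = X @ rng.normal(size=p) + 0.5 * rng.normal(size=n)
        sh = shapley_decompose(X, y, [f"c{i}" for i in range(p)], {"g": []})
        r = np.array([np.corrcoef(X[:, i], y)[0, 1] ** 2 for i in range(p)])
        np.testing.assert_allclose(sh["value"].to_numpy(), r, atol=1e-6)

    def test_duplicated_columns_share_equally(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = 2 * x + 0.1 * rng.normal(size=300)
        X = np.column_stack([x, x])
        sh = shapley_decompose(X, y, ["a", "b"], {"g": []})
        assert sh["value"].iloc[0] == pytest.approx(sh["value"].iloc[1], abs=1e-10)
        assert sh["value"].sum() == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, abs=1e-8
        )

    def test_efficiency_sum_equals_full_r2(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=400)
        sh = shapley_decompose(X, y, [f"c{i}" for i in range(8)], {"g": []})
        assert sh["value"].sum() == pytest.approx(sh.attrs["full_r2"], abs=1e-10)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 4)) @ rng.normal(size=(4, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=300)
        cols = ["a", "b", "c", "d"]
        sh = shapley_decompose(X, y, cols, {"g": []}).set_index("column")["value"]
        perm = [2, 0, 3, 1]
        sh2 = shapley_decompose(
            X[:, perm], y, [cols[i] for i in perm], {"g": []}
        ).set_index("column")["value"]
        for c in cols:
            assert sh[c] == pytest.approx(sh2[c], abs=1e-10)

    def test_refuses_more_than_20_columns(self):
        X = np.random.default_rng(0).normal(size=(50, 21))
        with pytest.raises(ValueError):
            shapley_decompose(X, X[:, 0], [f"c{i}" for i in range(21)], {"g": []})


class TestBuildDesign:
    def test_columns_normalized(self, noisy_features, noisy_reaches):
        d = build_design(noisy_features, noisy_reaches, "kinematics_plus_error")
        assert d.X.shape[1] == 16
        np.testing.assert_allclose(d.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(d.X.std(axis=0), 1.0, rtol=1e-10)

    def test_group_map_sizes(self, noisy_features, noisy_reaches):
        d12 = build_design(noisy_features, noisy_reaches, "kinematics_only")
        assert len(d12.columns) == 12 and len(d12.groups) == 6
        d16 = build_design(noisy_features, noisy_reaches, "kinematics_plus_error")
        assert len(d16.columns) == 16 and len(d16.groups) == 8

    def test_error_magnitude_at_reach_start_matches_geometry(
        self, quiet_session, quiet_features, quiet_reaches
    ):
        """At Reach Start of a straight 178 mm reach the distance to the
        goal hold position is about the full target radius."""
        t = quiet_features["t_s"].to_numpy()
        valid = quiet_reaches[quiet_reaches["valid"]]
        raw = quiet_features[["x_mm", "y_mm", "z_mm"]].to_numpy()
        mags = []
        for r in valid.itertuples(index=False):
            hold = (t > r.t_end_s) & (t <= r.t_end_s + 1.0)
            if not hold.any() or r.t_end_s + 1.0 > t[-1]:
                continue
            goal = raw[hold].mean(axis=0)
            i_start = np.argmin(np.abs(t - r.t_start_s))
            mags.append(np.linalg.norm(raw[i_start] - goal))
        assert np.median(mags) == pytest.approx(178.0, rel=0.05)

    def test_zero_variance_column_dropped(self, quiet_features, quiet_reaches):
        flat = quiet_features.copy()
        flat["z_mm"] = 5.0
        flat["vz"] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            d = build_design(flat, quiet_reaches, "kinematics_only")
        assert "z_mm" not in d.columns and "vz" not in d.columns

    def test_windowed_designs_are_half_second(self, quiet_features, quiet_reaches):
        d = build_design(quiet_features, quiet_reaches, "kinematics_only",
                         window="start_centered")
        starts = quiet_reaches.loc[quiet_reaches["valid"], "t_start_s"].to_numpy()
        for k in np.unique(d.reach_index):
            ts = d.times[d.reach_index == k]
            assert ts.max() - ts.min() <= 0.5 + 1e-9


def _rate_from_series(t_grid, values, unit_id="syn"):
    """RateFunction whose 1 ms bins linearly track a given series."""
    t0 = t_grid[0]
    n = int(np.round((t_grid[-1] - t0) / 0.001))
    centers = t0 + (np.arange(n) + 0.5) * 0.001
    return RateFunction(unit_id, t0, np.interp(centers, t_grid, values))


class TestLaggedRegression:
    def test_noiseless_velocity_function_r2_one_at_zero_lag(
        self, quiet_features, quiet_reaches
    ):
        d = build_design(quiet_features, quiet_reaches, "kinematics_only")
        t = quiet_features["t_s"].to_numpy()
        signal = (
            quiet_features["vx"].to_numpy() * 0.7
            + quiet_features["vy"].to_numpy() * -0.4
        )
        rate = _rate_from_series(t, signal)
        res = lagged_regression(d, rate, np.array([0.0]))
        assert res.r2[0] > 0.999

    def test_recovers_exact_lag_of_noiseless_response(
        self, quiet_features, quiet_reaches
    ):
        true_lag = 3 / 120  # +25 ms: neural follows kinematics by 3 samples
        d = build_design(quiet_features, quiet_reaches, "kinematics_only")
        t = quiet_features["t_s"].to_numpy()
        signal = quiet_features["vx"].to_numpy()
        rate = _rate_from_series(t + true_lag, signal)
        res = lagged_regression(d, rate, DEFAULT_LAGS_S)
        assert res.optimal_lag_s == pytest.approx(true_lag, abs=1e-9)

    def test_adjusted_r2_formula(self):
        assert adjusted_r2(np.array([0.5]), 101, 10)[0] == pytest.approx(
            1 - 0.5 * 100 / 90
        )

    def test_rank_deficient_design_drops_columns(self, noisy_features, noisy_reaches):
        d = build_design(noisy_features, noisy_reaches, "kinematics_only")
        X = np.column_stack([d.X, d.X[:, 0]])
        dd = Design(X=X, columns=d.columns + ["dup"], times=d.times,
                    reach_index=d.reach_index, set_name=d.set_name, window="reach")
        rate = _rate_from_series(noisy_features["t_s"].to_numpy(),
                                 noisy_features["vx"].to_numpy())
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = lagged_regression(dd, rate, np.array([0.0]))
        assert res.n_params == 12


class TestCircularShiftNull:
    def test_zero_shift_reproduces_observed_r2(self, quiet_features, quiet_reaches,
                                               quiet_session, session_span):
        from vimreach.rates import unit_rate_function

        d = build_design(quiet_features, quiet_reaches, "kinematics_only")
        rate = unit_rate_function(quiet_session.spikes["vel"], session_span, 15.0,
                                  zscore_window_s=45.0, unit_id="vel")
        r2_all = r2_all_circular_shifts(d, rate)
        obs = lagged_regression(d, rate, np.array([0.0])).r2[0]
        assert r2_all[0] == pytest.approx(obs, abs=1e-12)

    def test_integer_shifts_match_direct_refit(self, quiet_features, quiet_reaches,
                                               quiet_session, session_span):
        from vimreach.rates import unit_rate_function
        from vimreach.encoding import _r2_matrix

        d = build_design(quiet_features, quiet_reaches, "kinematics_only")
        rate = unit_rate_function(quiet_session.spikes["vel"], session_span, 15.0,
                                  unit_id="vel")
        r2_all = r2_all_circular_shifts(d, rate)
        q, _, _ = d.basis()
        rolled = RateFunction("vel", rate.t0, np.roll(rate.rate, -12345))
        direct = _r2_matrix(q, rolled(d.times)[:, None])[0]
        assert r2_all[12345] == pytest.approx(direct, abs=1e-9)

    def test_same_seed_identical_null(self, quiet_features, quiet_reaches,
                                      quiet_session, session_span):
        from vimreach.rates import unit_rate_function

        d = build_design(quiet_features, quiet_reaches, "kinematics_only")
        rate = unit_rate_function(quiet_session.spikes["vel"], session_span, 15.0,
                                  unit_id="vel")
        a, pa = circular_shift_null(d, rate, 0.0, 200, np.random.default_rng(5))
        b, pb = circular_shift_null(d, rate, 0.0, 200, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        assert pa == pb


class TestNesting:
    def test_error_augmented_model_never_decreases_r2(
        self, quiet_features, quiet_reaches, quiet_session, session_span
    ):
        from vimreach.rates import unit_rate_function

        d12 = build_design(quiet_features, quiet_reaches, "kinematics_only")
        d16 = build_design(quiet_features, quiet_reaches, "kinematics_plus_error")
        for uid in ("flat", "vel", "dir"):
            rate = unit_rate_function(quiet_session.spikes[uid], session_span, 15.0,
                                      zscore_window_s=45.0, unit_id=uid)
            lags = np.array([-0.05, 0.0, 0.05])
            r12 = lagged_regression(d12, rate, lags)
            r16 = lagged_regression(d16, rate, lags)
            # same sample base: reach windows identical across sets here
            assert np.all(r16.r2 >= r12.r2 - 1e-12)


def test_group_contributions_sum_member_columns():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(300, 6))
    y = X[:, 0] + X[:, 1] + rng.normal(size=300)
    groups = {"pair": ["c0", "c1"], "rest": ["c2", "c3", "c4", "c5"]}
    sh = shapley_decompose(X, y, [f"c{i}" for i in range(6)], groups)
    gc = group_contributions(sh).set_index("group")["value"]
    assert gc["pair"] == pytest.approx(sh["value"][:2].sum(), abs=1e-12)
    assert gc.sum() == pytest.approx(sh.attrs["full_r2"], abs=1e-10)
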