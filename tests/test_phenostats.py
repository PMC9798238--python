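import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binqtl.phenostats import (
    VarianceComponents,
    env_correlations,
    fit_blues,
    fit_mixed_model,
    fit_variance_components,
    heritability,
    reml_em,
)


def _dummies(values):
    return pd.get_dummies(pd.Series(values).astype(str)).to_numpy(dtype=float)


class TestREMLAgainstBalancedANOVA:
    def test_one_way_closed_form(self, rng):
        n_g, r = 30, 4
        g = rng.normal(0, 2.0, n_g)
        y = (g[:, None] + rng.normal(0, 1.0, (n_g, r))).ravel()
        groups = np.repeat(np.arange(n_g), r)
        fit = reml_em(y, np.ones((y.size, 1)), {"g": _dummies(groups)}, tol=1e-12)
        msb = r * np.var([y[groups == i].mean() for i in range(n_g)], ddof=1)
        msw = np.mean([np.var(y[groups == i], ddof=1) for i in range(n_g)])
        assert fit.sigma2["g"] == pytest.approx((msb - msw) / r, abs=1e-6)
        assert fit.sigma2_e == pytest.approx(msw, abs=1e-6)

    def test_crossed_two_way_ems_estimators(self, rng):
        L, E, R = 25, 4, 3
        gl = rng.normal(0, 1.2, L)
        en = rng.normal(0, 0.8, E)
        ge = rng.normal(0, 0.6, (L, E))
        ym = gl[:, None, None] + en[None, :, None] + ge[:, :, None] + rng.normal(
            0, 0.5, (L, E, R)
        )
        y = ym.ravel()
        li = np.repeat(np.arange(L), E * R)
        ej = np.tile(np.repeat(np.arange(E), R), L)
        fit = reml_em(
            y,
            np.ones((y.size, 1)),
            {"line": _dummies(li), "env": _dummies(ej), "le": _dummies(li * 10 + ej)},
            tol=1e-12,
            max_iter=5000,
        )
        # expected-mean-square estimators for the balanced random model
        msa = E * R * np.var(ym.mean(axis=(1, 2)), ddof=1)
        msb = L * R * np.var(ym.mean(axis=(0, 2)), ddof=1)
        cell = ym.mean(axis=2)
        msab = (
            R
            * ((cell - cell.mean(1, keepdims=True) - cell.mean(0, keepdims=True) + cell.mean()) ** 2).sum()
            / ((L - 1) * (E - 1))
        )
        mse = ((ym - cell[:, :, None]) ** 2).sum() / (L * E * (R - 1))
        assert fit.sigma2["line"] == pytest.approx((msa - msab) / (E * R), abs=1e-6)
        assert fit.sigma2["env"] == pytest.approx((msb - msab) / (L * R), abs=1e-6)
        assert fit.sigma2["le"] == pytest.approx((msab - mse) / R, abs=1e-6)
        assert fit.sigma2_e == pytest.approx(mse, abs=1e-6)


def _balanced_records(values_by_line, envs=("E1", "E2"), reps=(1, 2)):
    rows = [
        (line, env, rep, v)
        for line, v in values_by_line.items()
        for env in envs
        for rep in reps
    ]
    return pd.DataFrame(rows, columns=["line", "env", "rep", "value"])


class TestBLUEs:
    def test_zero_variance_blue_equals_line_mean(self):
        rec = _balanced_records({f"L{i}": 5.0 + i for i in range(6)})
        blues, _ = fit_blues(rec)
        assert np.allclose(blues["blue"], [5.0 + i for i in range(6)], atol=1e-8)

    def test_two_lines_one_observation_each(self):
        rec = pd.DataFrame(
            {"line": ["a", "b"], "env": ["E1", "E1"], "rep": [1, 1], "value": [10.0, 12.0]}
        )
        blues, _ = fit_blues(rec)
        assert np.allclose(blues["blue"], [10.0, 12.0], atol=1e-10)

    def test_environment_shift_leaves_line_contrasts(self, rng):
        base = {f"L{i}": float(v) for i, v in enumerate(rng.normal(10, 1, 8))}
        rec = _balanced_records(base)
        shifted = rec.copy()
        shifted.loc[shifted["env"] == "E2", "value"] += 3.0
        b0, _ = fit_blues(rec)
        b1, _ = fit_blues(shifted)
        d0 = b0["blue"].to_numpy() - b0["blue"].mean()
        d1 = b1["blue"].to_numpy() - b1["blue"].mean()
        assert np.allclose(d0, d1, atol=1e-6)

    def test_duplicate_records_rejected(self):
        rec = pd.DataFrame(
            {"line": ["a", "a"], "env": ["E1", "E1"], "rep": [1, 1], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            fit_blues(rec)


class TestHeritability:
    def test_pure_genetic(self):
        vc = VarianceComponents(1.0, 0, 0, 0, 0, 1, 1, 1)
        assert heritability(vc) == 1.0

    def test_equal_split(self):
        vc = VarianceComponents(1.0, 0, 0, 0, 1.0, 1, 1, 1)
        assert heritability(vc) == 0.5

    def test_multi_environment_formula(self):
        vc = VarianceComponents(0.5, 0.1, 0.1, 0.2, 0.15, 2, 2, 3)
        assert heritability(vc) == pytest.approx(0.7547, abs=5e-5)

    def test_all_zero_components_undefined(self):
        vc = VarianceComponents(0, 0, 0, 0, 0, 1, 1, 1)
        with pytest.raises(ValueError):
            heritability(vc)

    @settings(max_examples=40, derandomize=True)
    @given(
        var_g=st.floats(0.01, 5.0),
        y=st.integers(1, 5),
        l=st.integers(1, 5),
        r=st.integers(1, 5),
    )
    def test_monotone_in_genetic_variance_and_design(self, var_g, y, l, r):
        base = dict(var_gy=0.2, var_gl=0.2, var_gly=0.3, var_e=0.4)
        h = heritability(VarianceComponents(var_g=var_g, n_years=y, n_locations=l, n_reps=r, **base))
        h_more_g = heritability(
            VarianceComponents(var_g=var_g * 1.5, n_years=y, n_locations=l, n_reps=r, **base)
        )
        h_more_y = heritability(
            VarianceComponents(var_g=var_g, n_years=y + 1, n_locations=l, n_reps=r, **base)
        )
        h_more_r = heritability(
            VarianceComponents(var_g=var_g, n_years=y, n_locations=l, n_reps=r + 1, **base)
        )
        assert h_more_g > h and h_more_y > h and h_more_r > h


class TestVarianceComponents:
    def test_recovery_on_simulated_balanced_data(self, rng):
        """REML recovers generating components on a balanced Y x L x R trial."""
        n, true = 120, dict(g=0.5, gy=0.1, gl=0.1, gly=0.2, e=0.15)
        years, locs, reps = ["y1", "y2"], ["l1", "l2"], [1, 2, 3]
        g = rng.normal(0, np.sqrt(true["g"]), n)
        gy = {yy: rng.normal(0, np.sqrt(true["gy"]), n) for yy in years}
        gl = {ll: rng.normal(0, np.sqrt(true["gl"]), n) for ll in locs}
        gly = {(yy, ll): rng.normal(0, np.sqrt(true["gly"]), n) for yy in years for ll in locs}
        rows = []
        for yy in years:
            for ll in locs:
                for rr in reps:
                    vals = 10 + g + gy[yy] + gl[ll] + gly[(yy, ll)] + rng.normal(
                        0, np.sqrt(true["e"]), n
                    )
                    env = f"{ll}{yy}"
                    rows += [
                        (f"L{i}", env, rr, yy, ll, vals[i]) for i in range(n)
                    ]
        rec = pd.DataFrame(rows, columns=["line", "env", "rep", "year", "location", "value"])
        vc = fit_variance_components(rec, tol=1e-7)
        assert vc.var_g == pytest.approx(true["g"], abs=0.12)
        assert vc.var_e == pytest.approx(true["e"], abs=0.05)
        assert vc.n_years == 2 and vc.n_locations == 2 and vc.n_reps == 3
        assert heritability(vc) == pytest.approx(0.7547, abs=0.08)

    def test_single_environment_interactions_fixed_at_zero(self):
        rec = _balanced_records({f"L{i}": float(i) for i in range(5)}, envs=("only",))
        _, vc = fit_mixed_model(rec)
        assert vc.var_gy == 0.0 and vc.var_gly == 0.0


class TestEnvCorrelations:
    def test_identical_environments(self):
        rec = _balanced_records({f"L{i}": float(i) for i in range(5)})
        corr = env_correlations(rec)
        assert corr.loc["E1", "E2"] == pytest.approx(1.0)

    def test_sign_flip(self):
        rows = [(f"L{i}", "E1", 1, float(i)) for i in range(5)]
        rows += [(f"L{i}", "E2", 1, -float(i)) for i in range(5)]
        rec = pd.DataFrame(rows, columns=["line", "env", "rep", "value"])
        assert env_correlations(rec).loc["E1", "E2"] == pytest.approx(-1.0)

    def test_closed_form_pearson(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 2.0, 3.0, 5.0]
        rows = [(f"L{i}", "E1", 1, x[i]) for i in range(4)]
        rows += [(f"L{i}", "E2", 1, y[i]) for i in range(4)]
        rec = pd.DataFrame(rows, columns=["line", "env", "rep", "value"])
        expected = 6.5 / np.sqrt(5.0 * 8.75)
        assert env_correlations(rec).loc["E1", "E2"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.9827, abs=1e-4)

    def test_insufficient_shared_lines_is_missing(self):
        rows = [("L1", "E1", 1, 1.0), ("L2", "E1", 1, 2.0), ("L3", "E1", 1, 3.0)]
        rows += [("L1", "E2", 1, 1.0), ("L2", "E2", 1, 2.0)]
        rec = pd.DataFrame(rows, columns=["line", "env", "rep", "value"])
        assert np.isnan(env_correlations(rec).loc["E1", "E2"])
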