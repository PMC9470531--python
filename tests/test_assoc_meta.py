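"""Regression battery, BY correction, IVW meta-analysis, leave-one-out."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from famliab.assoc_meta import (
    AssocSpec,
    by_adjust,
    fit_association,
    ivw_meta,
    leave_one_out_dd,
    meta_by_term,
    run_battery,
)


@pytest.fixture(scope="module")
def gaussian_data():
    rng = np.random.default_rng(5)
    n = 10000
    pgs = rng.normal(size=n)
    return pd.DataFrame(
        {
            "pgs": pgs,
            "y": 0.2 * pgs + rng.normal(size=n),
            "fam": np.repeat(np.arange(n // 2), 2),
        }
    )


class TestFitAssociation:
    def test_gaussian_recovery(self, gaussian_data):
        res = fit_association(
            gaussian_data, AssocSpec(outcome="y", predictors=["pgs"])
        ).iloc[0]
        assert abs(res["beta"] - 0.2) < 2 * res["se"]

    def test_cluster_robust_se_runs(self, gaussian_data):
        res = fit_association(
            gaussian_data,
            AssocSpec(outcome="y", predictors=["pgs"], cluster="fam"),
        ).iloc[0]
        assert res["se"] > 0

    def test_null_pvalues_uniform(self):
        """1,000 null refits give uniform p (KS not rejected at 0.01)."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(1000):
            d = pd.DataFrame(
                {"x": rng.normal(size=100), "y": rng.normal(size=100)}
            )
            pvals.append(
                fit_association(d, AssocSpec(outcome="y", predictors=["x"]))[
                    "p"
                ].iloc[0]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_auto_count_picks_negative_binomial_for_quadratic_variance(self):
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.normal(size=n)
        mu = np.exp(0.3 + 0.3 * x)
        r = 1.0  # NB with alpha = 1: variance quadratic in the mean
        cnt = rng.negative_binomial(r, r / (r + mu))
        d = pd.DataFrame({"x": x, "cnt": cnt})
        res = fit_association(
            d,
            AssocSpec(outcome="cnt", predictors=["x"], family="auto_count",
                      standardize=False),
        ).iloc[0]
        assert res["family_used"] == "negative_binomial"
        assert abs(res["beta"] - 0.3) < 3 * res["se"]

    def test_quasipoisson_inflates_se_under_overdispersion(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.normal(size=n)
        mu = np.exp(0.2 + 0.2 * x)
        cnt = rng.negative_binomial(0.5, 0.5 / (0.5 + mu))
        d = pd.DataFrame({"x": x, "cnt": cnt})
        import statsmodels.api as sm

        plain = sm.GLM(
            cnt, sm.add_constant(x), family=sm.families.Poisson()
        ).fit()
        qp = fit_association(
            d,
            AssocSpec(outcome="cnt", predictors=["x"], family="quasipoisson",
                      standardize=False),
        ).iloc[0]
        assert qp["se"] > plain.bse[1]

    def test_too_few_cases_rejected(self, gaussian_data):
        with pytest.raises(ValueError, match="20"):
            fit_association(
                gaussian_data.head(10), AssocSpec(outcome="y", predictors=["pgs"])
            )

    def test_missing_column_rejected(self, gaussian_data):
        with pytest.raises(KeyError):
            fit_association(
                gaussian_data, AssocSpec(outcome="nope", predictors=["pgs"])
            )


class TestBYAdjust:
    def test_hand_worked_example(self):
        q = by_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.055, 0.055, 0.0733333], atol=1e-6)

    def test_single_p_scaled_by_c1(self):
        assert by_adjust([0.03])[0] == pytest.approx(0.03)

    def test_ties_equal(self):
        q = by_adjust([0.02, 0.02, 0.02])
        assert q[0] == q[1] == q[2]

    def test_empty(self):
        assert by_adjust([]).size == 0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_by_dominates_bh_dominates_p(self, pvals):
        q_by = by_adjust(pvals)
        q_bh = multipletests(pvals, method="fdr_bh")[1]
        assert np.all(q_by + 1e-12 >= q_bh)
        assert np.all(q_by + 1e-12 >= np.asarray(pvals))
        assert np.all(q_by <= 1.0)


class TestIVWMeta:
    def test_hand_worked_example(self):
        m = ivw_meta([0.2, 0.4], [0.1, 0.2])
        assert m.beta == pytest.approx(0.24)
        assert m.se == pytest.approx(0.089443, abs=1e-5)
        assert m.q_stat == pytest.approx(0.8)
        assert m.i2 == 0.0

    def test_single_study_identity(self):
        m = ivw_meta([0.31], [0.05])
        assert m.beta == pytest.approx(0.31)
        assert m.se == pytest.approx(0.05)

    def test_two_identical_studies(self):
        m = ivw_meta([0.3, 0.3], [0.04, 0.04])
        assert m.beta == pytest.approx(0.3)
        assert m.se == pytest.approx(0.04 / np.sqrt(2))

    def test_errors(self):
        with pytest.raises(ValueError):
            ivw_meta([], [])
        with pytest.raises(ValueError):
            ivw_meta([0.2], [0.0])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)),
            min_size=1,
            max_size=8,
        )
    )
    def test_pooled_properties(self, studies):
        betas = [b for b, _ in studies]
        ses = [s for _, s in studies]
        m = ivw_meta(betas, ses)
        assert m.se <= min(ses) + 1e-12
        assert min(betas) - 1e-9 <= m.beta <= max(betas) + 1e-9
        assert 0.0 <= m.i2 <= 100.0


def test_meta_by_term_pools_cohorts(gaussian_data):
    res_a = fit_association(
        gaussian_data, AssocSpec(outcome="y", predictors=["pgs"], cohort="A")
    )
    res_b = fit_association(
        gaussian_data.sample(5000, random_state=0),
        AssocSpec(outcome="y", predictors=["pgs"], cohort="B"),
    )
    pooled = meta_by_term(pd.concat([res_a, res_b], ignore_index=True))
    assert len(pooled) == 1
    assert pooled.iloc[0]["k"] == 2


def test_run_battery_adds_q(gaussian_data):
    specs = [AssocSpec(outcome="y", predictors=["pgs"])]
    out = run_battery(gaussian_data, specs)
    assert (out["q"] >= out["p"] - 1e-12).all()


class TestLeaveOneOut:
    @staticmethod
    def _data(signal_in_first: bool, n=4000, seed=9):
        rng = np.random.default_rng(seed)
        carrier = rng.binomial(1, 0.15, size=n)
        cols = {}
        for j in range(7):
            logit = np.full(n, -1.0)
            if j == 0 and signal_in_first:
                logit = logit + 0.8 * carrier
            cols[f"c{j}"] = rng.binomial(1, 1 / (1 + np.exp(-logit)), size=n)
        cols["carrier"] = carrier
        return pd.DataFrame(cols)

    def test_output_shape_and_labels(self):
        data = self._data(signal_in_first=True)
        spec = AssocSpec(outcome="ignored", predictors=["carrier"],
                         family="quasipoisson", standardize=False)
        out = leave_one_out_dd(data, [f"c{j}" for j in range(7)], spec)
        assert len(out) == 7
        assert set(out["excluded"]) == {f"c{j}" for j in range(7)}

    def test_excluding_signal_condition_attenuates(self):
        data = self._data(signal_in_first=True)
        spec = AssocSpec(outcome="ignored", predictors=["carrier"],
                         family="quasipoisson", standardize=False)
        out = leave_one_out_dd(data, [f"c{j}" for j in range(7)], spec)
        out = out.set_index("excluded")
        without_signal = abs(out.loc["c0", "beta"])
        others = out.drop("c0")["beta"].abs()
        assert without_signal < others.min()

    def test_excluding_null_condition_stable(self):
        data = self._data(signal_in_first=True)
        data["_all"] = data[[f"c{j}" for j in range(7)]].sum(axis=1)
        full = fit_association(
            data,
            AssocSpec(outcome="_all", predictors=["carrier"],
                      family="quasipoisson", standardize=False),
        ).iloc[0]
        spec = AssocSpec(outcome="ignored", predictors=["carrier"],
                         family="quasipoisson", standardize=False)
        out = leave_one_out_dd(
            data, [f"c{j}" for j in range(7)], spec
        ).set_index("excluded")
        # dropping no-signal conditions barely moves the estimate
        null_shifts = (out.drop("c0")["beta"] - full["beta"]).abs()
        assert null_shifts.mean() < full["se"]
        assert (null_shifts < 2 * full["se"]).all()

    def test_wrong_column_count_rejected(self):
        data = self._data(signal_in_first=False)
        spec = AssocSpec(outcome="x", predictors=["carrier"])
        with pytest.raises(ValueError, match="7"):
            leave_one_out_dd(data, ["c0", "c1"], spec)
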