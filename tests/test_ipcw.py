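"""Censoring-model fitting, weight arithmetic, and truncation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ccw.clone_censor import ARM_INITIATION, ARM_NON_INITIATION
from ccw.ipcw import (
    CensoringModelSpec,
    compute_ipc_weights,
    fit_censoring_model,
    truncate_weights,
)

from conftest import panel_from_arrays


def two_arm_panel(**kw):
    """One clone per arm, four intervals, censoring controlled by caller."""
    t = np.tile(np.arange(4), 2)
    df = panel_from_arrays(
        t,
        event=np.zeros(8, dtype=int),
        censored=kw.get("censored", np.zeros(8, dtype=int)),
        arm=[ARM_INITIATION] * 4 + [ARM_NON_INITIATION] * 4,
        person=np.ones(8, dtype=int),
    )
    df["x"] = kw.get("x", np.zeros(8))
    return df


class TestCensoringModel:
    def test_no_censoring_gives_probability_one(self):
        panel = two_arm_panel()
        fit = fit_censoring_model(panel, CensoringModelSpec(covariates=()))
        assert (fit.p_uncensored == 1.0).all()
        out = compute_ipc_weights(panel, fit)
        assert np.allclose(out["weight"], 1.0)

    def test_saturated_binary_model_recovers_empirical_proportions(self):
        # one arm, one interval, binary covariate: MLE = stratum proportions
        rng = np.random.default_rng(3)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        p = np.where(x > 0, 0.4, 0.1)
        cens = (rng.random(n) < p).astype(int)
        df = panel_from_arrays(
            np.zeros(n, dtype=int), np.zeros(n, dtype=int), cens,
            arm=[ARM_INITIATION] * n, person=np.arange(n),
        )
        df["x"] = x
        both = pd.concat(
            [df, panel_from_arrays(np.zeros(2, dtype=int), np.zeros(2, dtype=int), np.zeros(2, dtype=int),
                                   arm=[ARM_NON_INITIATION] * 2, person=np.array([9998, 9999])).assign(x=0.0)],
            ignore_index=True,
        )
        fit = fit_censoring_model(both, CensoringModelSpec(covariates=("x",)))
        for level in (0.0, 1.0):
            m = (both["clone_arm"] == ARM_INITIATION) & (both["x"] == level)
            emp = 1.0 - both.loc[m, "censored"].mean()
            assert fit.p_uncensored[m].iloc[0] == pytest.approx(emp, abs=1e-8)

    def test_missing_covariate_raises(self):
        panel = two_arm_panel()
        with pytest.raises(ValueError, match="nope"):
            fit_censoring_model(panel, CensoringModelSpec(covariates=("nope",)))

    def test_empty_arm_raises(self):
        panel = two_arm_panel()
        with pytest.raises(ValueError, match="empty"):
            fit_censoring_model(panel[panel["clone_arm"] == ARM_INITIATION], CensoringModelSpec(covariates=()))


class TestWeights:
    def test_halving_probabilities_double_weights(self):
        panel = two_arm_panel()
        fit = fit_censoring_model(panel, CensoringModelSpec(covariates=()))
        fit.p_uncensored.iloc[:4] = [1.0, 0.5, 0.5, 0.5]
        out = compute_ipc_weights(panel, fit)
        got = out.loc[out["clone_arm"] == ARM_INITIATION, "weight"].to_numpy()
        np.testing.assert_allclose(got, [1.0, 2.0, 4.0, 8.0])

    def test_weights_undefined_on_censored_rows(self):
        cens = np.array([0, 0, 0, 1, 0, 0, 0, 0])
        panel = two_arm_panel(censored=cens)
        fit = fit_censoring_model(panel, CensoringModelSpec(covariates=()))
        out = compute_ipc_weights(panel, fit)
        assert np.isnan(out.loc[out["censored"] == 1, "weight"]).all()

    def test_unstabilized_weights_monotone_within_clone(self):
        rng = np.random.default_rng(8)
        panel = two_arm_panel()
        fit = fit_censoring_model(panel, CensoringModelSpec(covariates=()))
        fit.p_uncensored.iloc[:] = rng.uniform(0.5, 1.0, 8)
        out = compute_ipc_weights(panel, fit)
        for _, grp in out.groupby(["person_id", "clone_arm"]):
            w = grp["weight"].to_numpy()
            assert (np.diff(w) >= -1e-12).all()
            assert (w >= 1.0 - 1e-12).all()


class TestTruncation:
    def test_extreme_weight_is_capped_at_percentile(self):
        n = 1000
        w = np.ones(n)
        w[-1] = 100.0
        panel = panel_from_arrays(
            np.zeros(n, dtype=int), np.zeros(n, dtype=int), np.zeros(n, dtype=int),
            weight=w, arm=[ARM_INITIATION] * n, person=np.arange(n),
        )
        panel["weight_raw"] = panel["weight"]
        out, diags = truncate_weights(panel, 99.5)
        assert out["weight"].max() < 100.0
        assert diags.arm[ARM_INITIATION]["max_before"] == 100.0
        assert diags.arm[ARM_INITIATION]["max_after"] <= diags.arm[ARM_INITIATION]["threshold"]

    def test_equal_weights_unchanged_and_percentile_100_noop(self):
        n = 50
        w = np.full(n, 2.5)
        panel = panel_from_arrays(
            np.zeros(n, dtype=int), np.zeros(n, dtype=int), np.zeros(n, dtype=int),
            weight=w, arm=[ARM_INITIATION] * n, person=np.arange(n),
        )
        panel["weight_raw"] = panel["weight"]
        out, _ = truncate_weights(panel, 99.5)
        np.testing.assert_allclose(out["weight"], 2.5)
        out2, _ = truncate_weights(panel, 100.0)
        np.testing.assert_allclose(out2["weight"], panel["weight_raw"])

    def test_percentile_validation(self):
        panel = panel_from_arrays(np.zeros(2, dtype=int), np.zeros(2, dtype=int), np.zeros(2, dtype=int), weight=np.ones(2))
        panel["weight_raw"] = panel["weight"]
        for bad in (50.0, 0.0, 101.0):
            with pytest.raises(ValueError):
                truncate_weights(panel, bad)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(1.0, 50.0), min_size=5, max_size=60), st.floats(50.1, 100.0))
def test_truncation_never_increases_any_weight(weights, pct):
    w = np.asarray(weights)
    panel = panel_from_arrays(
        np.zeros(w.size, dtype=int), np.zeros(w.size, dtype=int), np.zeros(w.size, dtype=int),
        weight=w, arm=[ARM_INITIATION] * w.size, person=np.arange(w.size),
    )
    panel["weight_raw"] = panel["weight"]
    out, _ = truncate_weights(panel, pct)
    assert (out["weight"].to_numpy() <= w + 1e-12).all()
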