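import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import priorlearn as pl
from priorlearn.models import (
    MODELS,
    SINGLE_PREDICTOR_MODELS,
    DegenerateFitError,
    ModelFit,
    ModelSpec,
    SingularFitError,
    bayesian_weights,
    bic,
    build_predictors,
    compare_models,
    fit_ols,
    modality_weight_contrast,
    stepwise_forward_cv,
    time_resolved_weights,
)
from priorlearn.synthetic import simulate_from_model


def block_table(guess_errors, hint_errors, failed=None, pid=1, block=1):
    n = len(guess_errors)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "block_id": block,
            "trial_index": np.arange(1, n + 1),
            "error": guess_errors,
            "hint_error": hint_errors,
            "failed": failed if failed is not None else [False] * n,
        }
    )


class TestBuildPredictors:
    def test_cumulative_average_arithmetic(self):
        tab = build_predictors(block_table([10.0, 2.0, 6.0], [4.0, -2.0, 6.0]))
        t3 = tab[tab.trial_index == 3].iloc[0]
        assert t3.cumavg_hint == pytest.approx(8.0 / 3.0)  # includes current
        assert t3.cumavg_guess == pytest.approx(6.0)  # excludes current
        assert np.isnan(tab[tab.trial_index == 1].cumavg_guess.iloc[0])

    def test_lags_skip_failed_trials(self):
        tab = build_predictors(
            block_table(
                [10.0, 99.0, 6.0],
                [4.0, 99.0, 6.0],
                failed=[False, True, False],
            )
        )
        t3 = tab[tab.trial_index == 3].iloc[0]
        assert t3.guess_t1 == 10.0  # refers to trial 1, not the failed trial 2
        assert t3.hint_t1 == 4.0
        assert t3.cumavg_guess == pytest.approx(10.0)

    def test_lags_do_not_cross_blocks(self):
        two = pd.concat(
            [
                block_table([1.0, 2.0], [1.0, 2.0], block=1),
                block_table([3.0, 4.0], [3.0, 4.0], block=2),
            ]
        )
        tab = build_predictors(two)
        first_of_b2 = tab[(tab.block_id == 2) & (tab.trial_index == 1)].iloc[0]
        assert np.isnan(first_of_b2.guess_t1)
        assert np.isnan(first_of_b2.cumavg_guess)


class TestFitOls:
    def test_exact_linear_relation(self):
        x = np.arange(1.0, 11.0)
        tab = block_table(2.0 * x, x)
        fit = fit_ols(MODELS[1], build_predictors(tab))
        assert fit.coefs["hint_t"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefs["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_matches_pseudoinverse_oracle(self):
        """Normal-equations contract: lstsq solution equals the pinv
        solution on random small instances."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 30
            tab = pd.DataFrame(
                {
                    "participant_id": 1,
                    "trial_index": np.arange(1, n + 1),
                    "guess": rng.normal(size=n),
                    "hint_t": rng.normal(size=n),
                    "guess_t1": rng.normal(size=n),
                    "guess_t2": rng.normal(size=n),
                }
            )
            spec = ModelSpec(0, "test", ("hint_t", "guess_t1", "guess_t2"))
            fit = fit_ols(spec, tab)
            X = np.column_stack(
                [np.ones(n), tab[["hint_t", "guess_t1", "guess_t2"]].to_numpy()]
            )
            oracle = np.linalg.pinv(X) @ tab["guess"].to_numpy()
            got = [fit.coefs["intercept"]] + [
                fit.coefs[p] for p in spec.predictors
            ]
            assert np.allclose(got, oracle, atol=1e-6)

    def test_hint_follower_identity(self):
        data = simulate_from_model({"hint_t": 1.0}, 0.5, 30.0, 40, seed=0)
        data = data.rename(columns={"guess_error": "error"})
        data["participant_id"], data["failed"] = 1, False
        fit = fit_ols(MODELS[1], build_predictors(data), trial_range=(2, 10))
        assert fit.coefs["hint_t"] == pytest.approx(1.0, abs=0.02)

    def test_rank_deficient_raises(self):
        n = 20
        tab = pd.DataFrame(
            {
                "participant_id": 1,
                "trial_index": np.arange(1, n + 1),
                "guess": np.random.default_rng(1).normal(size=n),
                "hint_t": np.arange(n, dtype=float),
                "guess_t1": 2.0 * np.arange(n, dtype=float),
            }
        )
        with pytest.raises(SingularFitError):
            fit_ols(ModelSpec(0, "dup", ("hint_t", "guess_t1")), tab)

    def test_zero_variance_predictor_dropped_with_warning(self):
        n = 20
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(
            {
                "participant_id": 1,
                "trial_index": np.arange(1, n + 1),
                "guess": rng.normal(size=n),
                "hint_t": rng.normal(size=n),
                "guess_t1": np.zeros(n),
            }
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_ols(ModelSpec(0, "z", ("hint_t", "guess_t1")), tab)
        assert "guess_t1" not in fit.coefs


class TestBic:
    def test_equal_fits_equal_bic(self):
        a = ModelFit(1, 1, rss=50.0, n=100, k=3)
        b = ModelFit(1, 2, rss=50.0, n=100, k=3)
        assert bic(a) == bic(b)

    def test_halved_rss_one_extra_parameter(self):
        # delta BIC = n ln(1/2) + ln(n) ~ -64.7 at n=100
        base = ModelFit(1, 1, rss=100.0, n=100, k=3)
        bigger = ModelFit(1, 2, rss=50.0, n=100, k=4)
        assert bic(bigger) - bic(base) == pytest.approx(
            100 * math.log(0.5) + math.log(100), abs=1e-9
        )

    def test_penalty_grows_by_log_n_per_parameter(self):
        f1 = ModelFit(1, 1, rss=10.0, n=64, k=3)
        f2 = ModelFit(1, 2, rss=10.0, n=64, k=4)
        assert bic(f2) - bic(f1) == pytest.approx(math.log(64))

    def test_zero_rss_degenerate(self):
        with pytest.raises(DegenerateFitError):
            bic(ModelFit(1, 1, rss=0.0, n=10, k=2))


class TestBayesianWeights:
    def test_single_model(self):
        assert bayesian_weights([123.4]) == pytest.approx([1.0])

    def test_two_equal_bics(self):
        assert bayesian_weights([7.0, 7.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two(self):
        w = bayesian_weights([0.0, 2.0])
        assert w == pytest.approx([1 / (1 + math.exp(-1)), math.exp(-1) / (1 + math.exp(-1))], abs=1e-3)
        assert w[0] == pytest.approx(0.731, abs=1e-3)

    @given(
        bics=st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=1,
            max_size=8,
        ),
        shift=st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100)
    def test_normalized_and_shift_invariant(self, bics, shift):
        w = bayesian_weights(bics)
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, bayesian_weights(np.asarray(bics) + shift))

    def test_all_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayesian_weights([np.nan, np.inf])


class TestCompareModels:
    def _cohort_from(self, betas, n_subjects=8, n_blocks=40, noise=3.0, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for pid in range(1, n_subjects + 1):
            d = simulate_from_model(betas, noise, 30.0, n_blocks, seed=rng)
            d = d.rename(columns={"guess_error": "error"})
            d["participant_id"], d["failed"] = pid, False
            frames.append(d)
        return build_predictors(pd.concat(frames, ignore_index=True))

    def test_hint_follower_recovered_as_model_1(self):
        tab = self._cohort_from({"hint_t": 0.95})
        res = compare_models(tab, SINGLE_PREDICTOR_MODELS, trial_range=(2, 10))
        assert res["mean_weights"].idxmax() == 1

    def test_guess_integrator_recovered_as_model_5(self):
        tab = self._cohort_from({"cumavg_guess": 0.9})
        res = compare_models(tab, SINGLE_PREDICTOR_MODELS, trial_range=(2, 10))
        assert res["mean_weights"].idxmax() == 5

    def test_weights_sum_to_one_per_subject(self):
        tab = self._cohort_from({"guess_t1": 0.5, "hint_t": 0.4})
        res = compare_models(tab, trial_range=(4, 10))
        assert np.allclose(res["weights"].sum(axis=1), 1.0)

    def test_split_by_modality_runs_per_level(self, reset_predictors):
        res = compare_models(
            reset_predictors, SINGLE_PREDICTOR_MODELS, (4, 10), "by_modality"
        )
        assert set(res) == {"pro", "anti"}


class TestStepwise:
    def _table(self, effect=0.9, noise=2.0, n_blocks=40, n_subjects=3, seed=3):
        rng = np.random.default_rng(seed)
        rows = []
        for pid in range(n_subjects):
            for b in range(n_blocks):
                h = rng.normal(0, 10, 10)
                g = rng.normal(0, 10, 9)
                y = effect * h[9] + rng.normal(0, noise)
                for t in range(1, 10):
                    rows.append(
                        {
                            "participant_id": pid,
                            "block_id": b,
                            "trial_index": t,
                            "error": g[t - 1],
                            "hint_error": h[t - 1],
                            "failed": False,
                        }
                    )
                rows.append(
                    {
                        "participant_id": pid,
                        "block_id": b,
                        "trial_index": 10,
                        "error": y,
                        "hint_error": h[9],
                        "failed": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_informative_predictor_selected_first(self):
        res = stepwise_forward_cv(self._table(), seed=0)
        for sub in res["per_subject"].values():
            assert sub["selected"][0] == "hint_10"

    def test_null_rmse_matches_noise_sd(self):
        # y is pure zero-mean noise: held-out RMSE of the intercept-only
        # model estimates the noise SD
        res = stepwise_forward_cv(self._table(effect=0.0, noise=5.0), seed=0)
        for sub in res["per_subject"].values():
            assert sub["null_rmse"] == pytest.approx(5.0, rel=0.2)

    def test_selection_terminates_and_improves(self):
        res = stepwise_forward_cv(self._table(), seed=1)
        for sub in res["per_subject"].values():
            path = sub["rmse_path"]
            assert all(a > b for a, b in zip(path, path[1:]))

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            stepwise_forward_cv(self._table(n_blocks=5), folds=10, seed=0)

    def test_deterministic_given_seed(self):
        tab = self._table()
        a = stepwise_forward_cv(tab, seed=42)
        b = stepwise_forward_cv(tab, seed=42)
        assert a["inclusion_histogram"] == b["inclusion_histogram"]


class TestTimeResolved:
    def test_known_relation_recovered_per_trial(self):
        rng = np.random.default_rng(5)
        rows = []
        for pid in range(6):
            for b in range(40):
                prev = 0.0
                for t in range(1, 6):
                    h = rng.normal(0, 10)
                    g = 0.5 * prev + 0.3 * h + rng.normal(0, 1)
                    rows.append(
                        {
                            "participant_id": pid,
                            "block_id": b,
                            "trial_index": t,
                            "error": g,
                            "hint_error": h,
                            "failed": False,
                        }
                    )
                    prev = g
        tab = build_predictors(pd.DataFrame(rows))
        tw = time_resolved_weights(tab, trial_set=range(2, 6))
        gw = tw[tw.predictor == "guess_t1"]
        assert np.allclose(gw.mean_weight, 0.5, atol=0.1)
        assert (gw.p < 0.01).all()


class TestModalityContrast:
    def test_symmetric_agent_shows_no_difference(self, reset_predictors):
        res = modality_weight_contrast(reset_predictors)
        assert res["guess_weight"]["p"] > 0.05
        assert res["hint_weight"]["p"] > 0.05

    def test_asymmetric_hint_weight_detected(self):
        """An agent that doubles its hint reliance under anti responses
        shows a significant hint-weight difference."""
        rng = np.random.default_rng(11)
        rows = []
        for pid in range(20):
            for b in range(40):
                order = ["pro", "anti"] if b % 2 == 0 else ["anti", "pro"]
                prev = [0.0, 0.0, 0.0]
                for t in range(1, 21):
                    rt = order[0] if t <= 10 else order[1]
                    w_h = 0.3 if rt == "pro" else 0.6
                    h = rng.normal(0, 10)
                    g = 0.3 * prev[0] + w_h * h + rng.normal(0, 3)
                    rows.append(
                        {
                            "participant_id": pid,
                            "block_id": b,
                            "trial_index": t,
                            "error": g,
                            "hint_error": h,
                            "response_type": rt,
                            "failed": False,
                        }
                    )
                    prev = [g] + prev[:2]
        tab = build_predictors(pd.DataFrame(rows))
        res = modality_weight_contrast(tab)
        assert res["hint_weight"]["p"] < 0.01
        assert res["guess_weight"]["p"] > 0.05
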