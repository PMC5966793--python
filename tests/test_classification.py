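"""Exclusion filters, mixture classification, behavioral summaries."""

import numpy as np
import pandas as pd
import pytest

import driftmem as dm
from driftmem.classification import MixtureFit, _parse_nontargets, fit_mixture
from driftmem.population import InvalidParameterError


def _trial(**over):
    base = dict(latency=0.5, saccade_amplitude_fraction=1.0,
                correction_deflection=5.0, blink=False)
    base.update(over)
    return base


class TestExclusions:
    @pytest.mark.parametrize("field,value,reason", [
        ("latency", 0.10, "latency-too-early"),
        ("latency", 2.5, "latency-too-late"),
        ("saccade_amplitude_fraction", 1.6, "amplitude"),
        ("saccade_amplitude_fraction", 0.4, "amplitude"),
        ("correction_deflection", 20.0, "deflection"),
        ("blink", True, "blink"),
    ])
    def test_each_rule_fires_with_its_reason(self, field, value, reason):
        excluded, why = dm.apply_exclusions(_trial(**{field: value}))
        assert excluded and why == reason

    def test_clean_trial_retained(self):
        excluded, why = dm.apply_exclusions(_trial())
        assert not excluded and why is None

    def test_boundaries_are_inclusive(self):
        # the stated bounds themselves are acceptable
        for t in (_trial(latency=0.15), _trial(latency=2.0),
                  _trial(saccade_amplitude_fraction=0.5),
                  _trial(saccade_amplitude_fraction=1.5),
                  _trial(correction_deflection=15.0)):
            assert not dm.apply_exclusions(t)[0]

    def test_missing_fields_rejected(self):
        with pytest.raises(InvalidParameterError):
            dm.apply_exclusions({"latency": 0.5})

    def test_filter_is_idempotent_and_order_independent(self, messy_dataset):
        trials, _ = messy_dataset
        once = dm.filter_trials(trials)
        twice = dm.filter_trials(once)
        assert once["valid"].equals(twice["valid"])
        assert once["exclusion_reason"].equals(twice["exclusion_reason"])
        shuffled = dm.filter_trials(trials.sample(frac=1.0, random_state=1))
        merged = shuffled.sort_index()
        assert merged["valid"].equals(once["valid"])

    def test_frame_filter_agrees_with_single_trial_filter(self, messy_dataset):
        trials, _ = messy_dataset
        out = dm.filter_trials(trials)
        for _, row in out.sample(50, random_state=2).iterrows():
            excluded, reason = dm.apply_exclusions(row)
            assert excluded == (not row["valid"])
            if excluded:
                assert reason == row["exclusion_reason"]

    def test_exclusion_rate_arithmetic(self):
        assert dm.exclusion_rate(744, 3840) == 19.4
        assert dm.exclusion_rate(645, 3000) == 21.5

    def test_exclusion_report_counts(self, messy_dataset):
        trials, truth = messy_dataset
        report = dm.exclusion_report(trials)
        assert report["n_total"] == len(trials)
        n_bad = sum(not v for v in truth["true_valid"])
        # injected violations are recovered exactly (they are unambiguous)
        assert report["n_excluded"] == n_bad


def _mixture_data(n, weights=(0.974, 0.022, 0.004), kappa=26.0, seed=0,
                  set_sizes=(2, 4), separation=120.0):
    """Synthetic labelled responses about targets/nontargets/uniform."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n):
        n_items = int(rng.choice(set_sizes))
        target = rng.uniform(0, 360)
        nts = [(target + separation * (j + 1)) % 360 for j in range(n_items - 1)]
        comp = rng.choice(3, p=weights)
        centre = target if comp == 0 else (rng.choice(nts) if comp == 1 and nts
                                           else target)
        if comp == 2:
            resp = rng.uniform(0, 360)
        else:
            resp = (centre + np.rad2deg(rng.vonmises(0, kappa))) % 360
        rows.append({"set_size": n_items, "delay": 1.0, "target_angle": target,
                     "nontarget_angles": nts, "response_angle": resp,
                     "latency": 0.4})
        labels.append(["target", "nontarget", "uniform"][comp])
    return pd.DataFrame(rows), np.array(labels)


class TestFitMixture:
    def test_recovers_generating_weights(self):
        df, _ = _mixture_data(4000, seed=3)
        fit = dm.fit_mixture(df)
        assert fit.p_target == pytest.approx(0.974, abs=0.015)
        assert fit.p_nontarget == pytest.approx(0.022, abs=0.015)
        assert fit.p_uniform == pytest.approx(0.004, abs=0.01)
        assert fit.kappa == pytest.approx(26.0, rel=0.2)
        assert fit.converged

    def test_loglik_non_decreasing_over_iterations(self):
        df, _ = _mixture_data(500, seed=4)
        lls = [fit_mixture(df, max_iter=n, tol=0.0).loglik
               for n in (2, 5, 10, 40)]
        assert np.all(np.diff(lls) >= -1e-9)

    def test_weights_sum_to_one(self):
        df, _ = _mixture_data(800, seed=6)
        fit = dm.fit_mixture(df)
        assert sum(fit.weights) == pytest.approx(1.0, abs=1e-9)

    def test_zero_dispersion_gives_pure_target(self):
        df, _ = _mixture_data(300, weights=(1.0, 0.0, 0.0), kappa=1e5, seed=7)
        fit = dm.fit_mixture(df)
        assert fit.p_target > 0.99

    def test_uniform_only_data_flags_concentration(self):
        df, _ = _mixture_data(400, weights=(0.0, 0.0, 1.0), seed=8)
        fit = dm.fit_mixture(df)
        assert fit.p_uniform > 0.95
        assert not fit.kappa_identifiable

    def test_set_size_one_fixes_nontarget_weight_to_zero(self):
        df, _ = _mixture_data(300, weights=(0.95, 0.0, 0.05), set_sizes=(1,),
                              seed=9)
        fit = dm.fit_mixture(df)
        assert fit.p_nontarget == 0.0

    def test_too_few_trials_rejected(self):
        df, _ = _mixture_data(10, seed=10)
        with pytest.raises(InvalidParameterError):
            dm.fit_mixture(df)


class TestClassifyTrials:
    def test_posterior_near_one_for_clean_target_response(self):
        fit = MixtureFit(p_target=0.8, p_nontarget=0.15, p_uniform=0.05,
                         kappa=40.0, loglik=0.0, n_iter=1, converged=True)
        df = pd.DataFrame([{"set_size": 2, "delay": 1.0, "target_angle": 0.0,
                            "nontarget_angles": [90.0], "response_angle": 1.0,
                            "latency": 0.4}])
        out = dm.classify_trials(df, fit)
        assert out["target_posterior"].iloc[0] > 0.95
        assert out["trial_class"].iloc[0] == "target"

    def test_midpoint_with_equal_weights_is_not_target(self):
        fit = MixtureFit(p_target=0.5, p_nontarget=0.5, p_uniform=0.0,
                         kappa=30.0, loglik=0.0, n_iter=1, converged=True)
        df = pd.DataFrame([{"set_size": 2, "delay": 1.0, "target_angle": 0.0,
                            "nontarget_angles": [90.0], "response_angle": 45.0,
                            "latency": 0.4}])
        out = dm.classify_trials(df, fit)
        assert out["target_posterior"].iloc[0] == pytest.approx(0.5)
        assert out["trial_class"].iloc[0] != "target"

    def test_posterior_exactly_at_threshold_is_not_target(self):
        fit = MixtureFit(p_target=0.9, p_nontarget=0.05, p_uniform=0.05,
                         kappa=30.0, loglik=0.0, n_iter=1, converged=True)
        df = pd.DataFrame([{"set_size": 2, "delay": 1.0, "target_angle": 0.0,
                            "nontarget_angles": [120.0],
                            "response_angle": 20.0, "latency": 0.4}])
        post = dm.classify_trials(df, fit)["target_posterior"].iloc[0]
        out = dm.classify_trials(df, fit, threshold=post)
        assert out["trial_class"].iloc[0] != "target"

    def test_posteriors_near_binary_on_separated_arrays(self):
        """With well-separated items and tight responses, almost all target
        posteriors fall outside (0.05, 0.95)."""
        df, _ = _mixture_data(2000, seed=12)
        fit = dm.fit_mixture(df)
        post = dm.classify_trials(df, fit)["target_posterior"]
        frac_binary = np.mean((post > 0.95) | (post < 0.05))
        assert frac_binary > 0.98

    def test_classification_recovers_generator_labels(self):
        df, labels = _mixture_data(3000, kappa=25.0, separation=90.0, seed=13)
        fit = dm.fit_mixture(df)
        out = dm.classify_trials(df, fit)
        target_true = labels == "target"
        recovered = (out["trial_class"] == "target")[target_true].mean()
        assert recovered >= 0.99


class TestSummaries:
    def test_rmsd_and_median_examples(self):
        df = pd.DataFrame([
            {"set_size": 1, "delay": 0.5, "target_angle": 0.0,
             "nontarget_angles": [], "response_angle": 350.0, "latency": 0.3},
            {"set_size": 1, "delay": 0.5, "target_angle": 0.0,
             "nontarget_angles": [], "response_angle": 10.0, "latency": 0.4},
            {"set_size": 1, "delay": 0.5, "target_angle": 0.0,
             "nontarget_angles": [], "response_angle": 0.0, "latency": 0.5},
        ])
        out = dm.summarize_conditions(df, min_trials=3)
        row = out.iloc[0]
        assert row["precision_deg"] == pytest.approx(np.sqrt((100 + 100) / 3))
        assert row["median_latency"] == pytest.approx(0.4)
        assert not row["flagged"]

    def test_wrapped_deviation(self):
        assert dm.wrap_deg(359.0 - 1.0) == pytest.approx(-2.0)
        df = pd.DataFrame([{"set_size": 1, "delay": 0.5, "target_angle": 1.0,
                            "nontarget_angles": [], "response_angle": 359.0,
                            "latency": 0.3}])
        out = dm.summarize_conditions(df, min_trials=1)
        assert out["precision_deg"].iloc[0] == pytest.approx(2.0)

    def test_small_cells_flagged_not_dropped(self):
        df = pd.DataFrame([{"set_size": 2, "delay": 1.0, "target_angle": 0.0,
                            "nontarget_angles": [90.0], "response_angle": 3.0,
                            "latency": 0.4}] * 2)
        out = dm.summarize_conditions(df)
        assert out["flagged"].iloc[0]
        assert np.isfinite(out["precision_deg"].iloc[0])

    def test_alternative_precision_measures(self):
        df, _ = _mixture_data(500, weights=(1.0, 0.0, 0.0), seed=14)
        for measure in ("rmsd", "csd", "mae"):
            out = dm.summarize_conditions(df, measure=measure, min_trials=1)
            assert np.isfinite(out["precision_deg"]).all()


def test_condition_difference_subtracts_control_baseline():
    mem = pd.DataFrame({"set_size": [1, 2], "delay": [0.5, 0.5],
                        "n_trials": [20, 20], "precision_deg": [6.0, 8.5],
                        "median_latency": [0.35, 0.42],
                        "flagged": [False, False]})
    ctl = mem.copy()
    ctl["precision_deg"] = [4.0, 4.5]
    ctl["median_latency"] = [0.30, 0.33]
    diff = dm.condition_difference(mem, ctl)
    assert np.allclose(diff["precision_deg_diff"], [2.0, 4.0])
    assert np.allclose(diff["median_latency_diff"], [0.05, 0.09])
    assert not diff["flagged"].any()


def test_trials_csv_round_trip(tmp_path, messy_dataset):
    trials, _ = messy_dataset
    path = tmp_path / "trials.csv"
    dm.write_trials_csv(trials, path)
    back = dm.read_trials_csv(path)
    for col in ("set_size", "delay", "target_angle", "response_angle",
                "latency", "saccade_amplitude_fraction"):
        assert np.allclose(back[col], trials[col], atol=1e-6)
    assert back["blink"].equals(trials["blink"].astype(bool))
    for a, b in zip(back["nontarget_angles"], trials["nontarget_angles"]):
        assert np.allclose(_parse_nontargets(a), _parse_nontargets(b),
                           atol=1e-4)
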