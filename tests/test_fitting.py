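"""Grid search, simplex refinement, and variant comparison."""

import numpy as np
import pytest

import driftmem as dm
from driftmem.fitting import (
    DelayRecallModel, InvalidComparisonError, InvalidStartError, ModelConfig,
    ParameterGrid, compare_variants, fit_participant, grid_search, refine_fit,
)
from driftmem.latency import ConfigurationError


def _tiny_grid(variant="setsize_drift"):
    mech = {"setsize_drift": np.array([2048.0, 8192.0, np.inf]),
            "exp_decay": np.array([0.01, 0.1])}[variant]
    return ParameterGrid(variant=variant,
                         gamma=np.array([64.0, 96.0, 128.0]),
                         m=np.array([5.0, 7.0]),
                         kappa=np.array([16.0, 26.0]),
                         tau=np.array([0.1, 0.3]),
                         nu=np.array([7.0, 10.0]),
                         o=np.array([0.18, 0.22]),
                         mech=mech)


class TestParameterGrid:
    def test_default_ranges_match_canonical_table(self):
        g = ParameterGrid.table_default("setsize_drift")
        assert g.gamma[0] == 8.0 and g.gamma[-1] == 512.0 and g.gamma.size == 25
        assert np.allclose(np.diff(np.log(g.gamma)), np.diff(np.log(g.gamma))[0])
        assert g.kappa[0] == 8.0 and g.kappa[-1] == 128.0 and g.kappa.size == 9
        assert g.tau[0] == 2.0 ** -6 and g.tau[-1] == 2.0 and g.tau.size == 8
        assert np.allclose(g.nu, np.linspace(1, 15, 15))
        assert np.allclose(g.o, np.linspace(0.1, 0.3, 11))
        assert g.m[0] == 4 and g.m[-1] == 128
        assert np.all(g.m == np.round(g.m))  # thresholds are integers
        assert np.isinf(g.mech[-1]) and g.mech.size == 16

    def test_decay_sentinels(self):
        lin = ParameterGrid.table_default("linear_decay")
        assert 0.0 in lin.mech and lin.mech.size == 14
        exp = ParameterGrid.table_default("exp_decay")
        assert exp.mech.size == 9 and exp.mech[-1] == pytest.approx(np.log(2))

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            ParameterGrid(variant="setsize_drift", gamma=np.array([95.0]),
                          m=np.array([5.0, 7.0]), kappa=np.array([16.0, 26.0]),
                          tau=np.array([0.1, 0.3]), nu=np.array([7.0, 10.0]),
                          o=np.array([0.18, 0.22]), mech=np.array([4096.0, np.inf]))

    def test_sentinel_only_mechanism_allowed(self):
        g = ParameterGrid(variant="setsize_drift", gamma=np.array([64.0, 96.0]),
                          m=np.array([5.0, 7.0]), kappa=np.array([16.0, 26.0]),
                          tau=np.array([0.1, 0.3]), nu=np.array([7.0, 10.0]),
                          o=np.array([0.18, 0.22]), mech=np.array([np.inf]))
        assert np.isinf(g.mech[0])

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        g = _tiny_grid()
        path = tmp_path / "grid.yaml"
        d = g.to_dict()
        path.write_text(yaml.safe_dump(d))
        g2 = ParameterGrid.from_yaml(path)
        for name in ("gamma", "m", "kappa", "tau", "nu", "o", "mech"):
            assert np.array_equal(getattr(g, name), getattr(g2, name))


class TestGridSearch:
    def test_combined_equals_direct_for_all_ranked(self, clean_trials,
                                                   fast_config):
        for variant in ("setsize_drift", "exp_decay"):
            ranked = grid_search(clean_trials, variant, _tiny_grid(variant),
                                 top_k=5, config=fast_config)
            assert len(ranked) == 5
            lls = [ll for _, ll in ranked]
            assert lls == sorted(lls, reverse=True)
            for ps, ll in ranked:
                direct = dm.dataset_loglik(
                    ps, clean_trials, evaluator=fast_config.evaluator(ps))
                assert abs(ll - direct) < 1e-9

    def test_best_cell_near_generating_parameters(self, clean_trials,
                                                  fast_config):
        ranked = grid_search(clean_trials, "setsize_drift", _tiny_grid(),
                             top_k=1, config=fast_config)
        best = ranked[0][0].to_dict()
        assert best["gamma"] == pytest.approx(96.0)  # truth 95, step to 96
        assert best["m"] == 7

    def test_mismatched_variant_rejected(self, clean_trials):
        with pytest.raises(ConfigurationError):
            grid_search(clean_trials, "exp_decay", _tiny_grid("setsize_drift"))


class TestRefineFit:
    def test_refinement_never_regresses(self, clean_trials, fast_config):
        ranked = grid_search(clean_trials, "setsize_drift", _tiny_grid(),
                             top_k=1, config=fast_config)
        fit = refine_fit(clean_trials, "setsize_drift", ranked[0][0],
                         config=fast_config, maxiter=60)
        assert fit.loglik >= fit.grid_loglik - 1e-9
        assert isinstance(fit.params.lat.threshold, int)

    def test_invalid_start_rejected(self, clean_trials, fast_config):
        bad = dm.ParameterSet.from_values(gamma=95.0, m=7, kappa=26.0, tau=0.2,
                                          nu=9.2, o=0.9,  # above all latencies
                                          variant="setsize_drift",
                                          mech_param=4600.0)
        with pytest.raises(InvalidStartError):
            refine_fit(clean_trials, "setsize_drift", bad, config=fast_config)

    def test_fit_is_deterministic(self, clean_trials, fast_config):
        a = fit_participant(clean_trials, "setsize_drift", grid=_tiny_grid(),
                            config=fast_config, n_starts=1, maxiter=40)
        b = fit_participant(clean_trials, "setsize_drift", grid=_tiny_grid(),
                            config=fast_config, n_starts=1, maxiter=40)
        assert a.params.signature() == b.params.signature()
        assert a.loglik == b.loglik


class TestCompareVariants:
    def _fit(self, trials, fast_config, variant="setsize_drift"):
        return fit_participant(trials, variant, grid=_tiny_grid(variant),
                               config=fast_config, n_starts=1, maxiter=30)

    def test_identical_fits_give_zero_delta(self, clean_trials, fast_config):
        fit = self._fit(clean_trials, fast_config)
        comp = compare_variants({"a_copy": [fit], "b_copy": [fit]})
        assert np.allclose(comp.table["delta_loglik"], 0.0)

    def test_mismatched_trials_rejected(self, clean_trials, fast_config):
        fit_a = self._fit(clean_trials, fast_config)
        other = clean_trials.iloc[: len(clean_trials) - 5].reset_index(drop=True)
        fit_b = self._fit(other, fast_config)
        with pytest.raises(InvalidComparisonError):
            compare_variants({"a": [fit_a], "b": [fit_b]})

    def test_winner_counting(self, clean_trials, fast_config):
        fit_d = self._fit(clean_trials, fast_config, "setsize_drift")
        fit_e = self._fit(clean_trials, fast_config, "exp_decay")
        comp = compare_variants({"setsize_drift": [fit_d], "exp_decay": [fit_e]})
        assert comp.table["n_wins"].sum() == 1
        assert comp.group_winner == comp.winners[0]


class TestModelSurface:
    def test_fit_and_summary(self, clean_trials, fast_config):
        model = DelayRecallModel(clean_trials, variant="setsize_drift",
                                 config=fast_config)
        res = model.fit(grid=_tiny_grid(), n_starts=1, maxiter=40)
        text = res.summary()
        assert "setsize_drift" in text
        assert f"{res.llf:.2f}" in text
        err, lat = res.predict(2, 1.0)
        assert err.integral() == pytest.approx(1.0, abs=1e-6)
        assert res.predicted_median_latency(4) > res.predicted_median_latency(1)
        assert res.predicted_precision_deg(4, 4.0) > \
            res.predicted_precision_deg(1, 0.5)

    def test_plot_fit_renders_all_conditions(self, clean_trials, fast_config):
        import matplotlib
        matplotlib.use("Agg")
        model = DelayRecallModel(clean_trials, variant="setsize_drift",
                                 config=fast_config)
        res = model.fit(grid=_tiny_grid(), n_starts=1, maxiter=20)
        ax = res.plot_fit()
        # one model line and one data overlay per set size
        assert len(ax.lines) == 2 * clean_trials["set_size"].nunique()

    def test_filters_invalid_and_lapse_rows(self, messy_dataset, fast_config):
        trials, _ = messy_dataset
        labelled = dm.filter_trials(trials)
        fit = dm.fit_mixture(labelled[labelled["valid"]])
        labelled = dm.classify_trials(labelled, fit)
        model = DelayRecallModel(labelled, config=fast_config)
        assert len(model.trials) < len(trials)
        assert (model.trials["latency"] <= 2.0).all()
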