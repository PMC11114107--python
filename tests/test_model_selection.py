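"""Candidate enumeration, AICc ranking, quantile residuals, Moran's I."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from symbioclim.glmm import GlmmFit, fit_logistic_glmm
from symbioclim.model_selection import (DEFAULT_PREDICTORS, enumerate_candidates,
                                        morans_i, rank_models,
                                        simulated_quantile_residuals)


def make_fit(predictors, aicc_value, n=500):
    names = ["(Intercept)", *predictors]
    return GlmmFit(names=names, beta=np.zeros(len(names)), se=np.ones(len(names)),
                   tau2=0.1, loglik=0.0, n=n, k=len(names) + 1, aic=aicc_value,
                   aicc=aicc_value, n_groups=10, converged=True,
                   separation_flag=False)


class TestEnumerateCandidates:
    @pytest.mark.parametrize("n_pred,expected", [(6, 22), (2, 4), (0, 1)])
    def test_counts(self, n_pred, expected):
        assert len(enumerate_candidates(DEFAULT_PREDICTORS[:n_pred])) == expected

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(("a", "a", "b"))

    def test_sizes_capped_at_two(self):
        assert max(len(s) for s in enumerate_candidates()) == 2


class TestRankModels:
    def test_informative_rule(self):
        fits = {(): make_fit((), 100.0),
                ("a",): make_fit(("a",), 97.5),
                ("b",): make_fit(("b",), 99.0)}
        df = rank_models(fits).set_index("model")
        assert df.loc["a", "informative"]          # beats null by 2.5
        assert not df.loc["b", "informative"]      # only by 1.0
        assert df.loc["a", "delta_best"] == 0.0

    def test_all_tied_all_top_uninformative(self):
        fits = {(): make_fit((), 50.0),
                ("a",): make_fit(("a",), 50.0),
                ("b",): make_fit(("b",), 50.0)}
        df = rank_models(fits)
        assert df["top_set"].all()
        assert not df["informative"].any()
        # ties break toward fewer parameters: null first
        assert df["model"].iloc[0] == "(null)"

    def test_null_best_by_margin(self):
        fits = {(): make_fit((), 50.0),
                ("a",): make_fit(("a",), 53.0),
                ("b",): make_fit(("b",), 55.0)}
        df = rank_models(fits)
        assert not df["informative"].any()
        assert df["model"].iloc[0] == "(null)"

    def test_differing_n_rejected(self):
        fits = {(): make_fit((), 100.0, n=500), ("a",): make_fit(("a",), 99.0, n=400)}
        with pytest.raises(ValueError, match="differing"):
            rank_models(fits)

    def test_order_invariance(self):
        fits = {("a",): make_fit(("a",), 97.0), (): make_fit((), 100.0),
                ("b",): make_fit(("b",), 98.0)}
        a = rank_models(fits)
        b = rank_models(dict(reversed(list(fits.items()))))
        assert a["model"].tolist() == b["model"].tolist()

    def test_true_predictor_lands_in_top_set(self):
        """Selection consistency on a strongly informative simulation."""
        from symbioclim.colwell import colwell_table
        from symbioclim.data_io import build_model_frame
        from symbioclim.model_selection import fit_candidates
        from symbioclim.synthetic import SimConfig, simulate_study
        hits = 0
        n_reps = 12
        for rep in range(n_reps):
            cfg = SimConfig(n_locations=20, hosts_per_location=40, years=30,
                            amplitude_range=(0.0, 4.0), noise_sd=0.3,
                            beta0=-1.0, beta_pred=3.0, tau=0.3, seed=3 + rep)
            hosts, locations, precip, _ = simulate_study(cfg)
            frame = build_model_frame(hosts, locations,
                                      colwell_table(precip, locations), "hayleyella")
            ranking = rank_models(fit_candidates(frame))
            top = ranking[ranking["top_set"]]
            if all("colwell_long" in preds or "colwell_5yr" in preds
                   for preds in top["predictors"]):
                hits += 1
        assert hits >= int(0.8 * n_reps)


class TestSimulatedQuantileResiduals:
    def _fit_and_frame(self, n_loc=25, n_per=40, seed=9):
        rng = np.random.default_rng(seed)
        x_loc = rng.uniform(-1, 1, n_loc)
        u = rng.normal(0, 0.4, n_loc)
        loc = np.repeat(np.arange(n_loc), n_per)
        y = (rng.random(len(loc)) < special.expit(-0.3 + x_loc[loc] + u[loc])).astype(int)
        frame = pd.DataFrame({"response": y, "x": x_loc[loc],
                              "location_id": loc.astype(str)})
        fit = fit_logistic_glmm(frame, "response", ["x"])
        return fit, frame

    def test_self_consistency_uniform(self):
        fit, frame = self._fit_and_frame(n_loc=25, n_per=40)
        resid = simulated_quantile_residuals(fit, frame, n_sims=250, seed=1)
        ks = stats.kstest(resid["residual"], "uniform").statistic
        assert ks < 0.05

    def test_misfit_pushes_residuals_to_extremes(self):
        fit, frame = self._fit_and_frame()
        flipped = frame.assign(response=1 - frame["response"])
        good = simulated_quantile_residuals(fit, frame, n_sims=250, seed=2)
        bad = simulated_quantile_residuals(fit, flipped, n_sims=250, seed=2)
        spread = lambda r: np.mean(np.abs(r["residual"] - 0.5))
        assert spread(bad) > spread(good)

    def test_fixed_seed_reproducible(self):
        fit, frame = self._fit_and_frame()
        a = simulated_quantile_residuals(fit, frame, n_sims=120, seed=7)
        b = simulated_quantile_residuals(fit, frame, n_sims=120, seed=7)
        assert np.array_equal(a["residual"], b["residual"])

    def test_requires_enough_sims(self):
        fit, frame = self._fit_and_frame()
        with pytest.raises(ValueError):
            simulated_quantile_residuals(fit, frame, n_sims=10)


class TestMoransI:
    def test_matches_double_sum_oracle(self):
        lat = np.array([30.0, 31.0, 33.5, 36.0])
        lon = np.array([-90.0, -85.0, -88.0, -80.0])
        values = np.array([0.2, 0.8, 0.3, 0.9])
        w = np.array([[0, 2.0, 1.0, 0.5],
                      [2.0, 0, 1.5, 0.2],
                      [1.0, 1.5, 0, 3.0],
                      [0.5, 0.2, 3.0, 0]])
        res = morans_i(values, lat, lon, permutations=9, seed=0, weights=w)
        n = 4
        z = values - values.mean()
        num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        oracle = n / w.sum() * num / (z @ z)
        assert res.I == pytest.approx(oracle, abs=1e-12)

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(6)
        n = 12
        lat, lon = rng.uniform(25, 45, n), rng.uniform(-95, -70, n)
        values = rng.normal(size=n)
        sims = [morans_i(rng.permutation(values), lat, lon, permutations=1,
                         seed=0).I for _ in range(800)]
        assert np.mean(sims) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_reproducible_p(self):
        rng = np.random.default_rng(3)
        lat, lon = rng.uniform(25, 45, 8), rng.uniform(-95, -70, 8)
        values = rng.normal(size=8)
        a = morans_i(values, lat, lon, permutations=999, seed=11)
        b = morans_i(values, lat, lon, permutations=999, seed=11)
        assert a.p == b.p

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(5), np.arange(5.0), np.arange(5.0))

    def test_nominal_rejection_rate_without_structure(self):
        """On iid values the permutation test rejects at ~ the nominal 5%."""
        rng = np.random.default_rng(21)
        n_reps, rejects = 300, 0
        lat, lon = rng.uniform(25, 45, 15), rng.uniform(-95, -70, 15)
        for _ in range(n_reps):
            values = rng.normal(size=15)
            res = morans_i(values, lat, lon, permutations=99, seed=int(rng.integers(2**31)))
            rejects += res.p <= 0.05
        assert 0.02 <= rejects / n_reps <= 0.08
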