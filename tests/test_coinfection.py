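"""Coinfection statistics: pair models, Fisher exact, BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from symbioclim.coinfection import (bh_adjust, fisher_by_location,
                                    fisher_exact_2x2, pairwise_coinfection)
from symbioclim.synthetic import SimConfig, simulate_hosts


def fisher_oracle(table):
    """Exhaustive two-sided Fisher p: sum hypergeometric masses of all tables
    with the observed margins whose probability <= the observed table's."""
    t = np.asarray(table)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    p_obs = hypergeom.pmf(t[0, 0], n, r1, c1)
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_a = hypergeom.pmf(a, n, r1, c1)
        if p_a <= p_obs * (1 + 1e-9):
            total += p_a
    return min(total, 1.0)


def bh_oracle(pvals):
    """Step-up adjustment computed by hand."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFisherExact:
    def test_diagonal_2_table(self):
        _, p = fisher_exact_2x2([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_margin_degenerate(self):
        odds, p = fisher_exact_2x2([[5, 0], [5, 0]])
        assert p == 1.0
        assert np.isnan(odds)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        t = [[a, b], [c, d]]
        row = np.array(t).sum(axis=1)
        col = np.array(t).sum(axis=0)
        _, p = fisher_exact_2x2(t)
        if (row == 0).any() or (col == 0).any():
            assert p == 1.0
        else:
            assert p == pytest.approx(fisher_oracle(t), abs=1e-12)

    def test_invariant_to_transpose_and_label_swap(self):
        t = np.array([[7, 3], [2, 9]])
        _, p = fisher_exact_2x2(t)
        _, p_t = fisher_exact_2x2(t.T)
        _, p_s = fisher_exact_2x2(t[::-1, ::-1])
        assert p == pytest.approx(p_t, abs=1e-12)
        assert p == pytest.approx(p_s, abs=1e-12)


class TestBhAdjust:
    def test_three_value_fixture(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_two_element_step_up(self):
        assert np.allclose(bh_adjust([0.005, 0.5]), [0.01, 0.5])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_oracle_monotone_idempotent(self, pvals):
        out = bh_adjust(pvals)
        assert np.allclose(out, bh_oracle(pvals))
        assert (out >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()
        # note: step-up adjustment is NOT idempotent in general
        # (e.g. [0.25, 1.0] -> [0.5, 1.0] -> [1.0, 1.0]); only monotonicity
        # and domination of the raw p-values are invariant


class TestPairwiseCoinfection:
    def test_ten_pair_models(self):
        cfg = SimConfig(n_locations=8, hosts_per_location=40, seed=11)
        hosts, _ = simulate_hosts(cfg, np.full(8, 0.35))
        results = pairwise_coinfection(hosts)
        assert len(results) == 10
        assert len({r.pair for r in results}) == 10
        for r in results:
            lo, hi = r.ci95
            assert lo <= r.log_odds <= hi

    def test_enriched_pair_detected(self):
        """Power check: +2 log-OR pair flagged at ~700 hosts."""
        cfg = SimConfig(seed=11,
                        coinfection_log_or={("amoebophilus", "hayleyella"): 2.0})
        hosts, _ = simulate_hosts(cfg, np.full(22, 0.35))
        results = {r.pair: r for r in pairwise_coinfection(hosts)}
        r = results[("amoebophilus", "hayleyella")]
        assert r.log_odds > 0
        assert r.ci95[0] > 0

    def test_independence_recovers_zero_on_average(self):
        """Mean pair log-odds across replicates ~ 0 under independence."""
        estimates = []
        for rep in range(40):
            cfg = SimConfig(n_locations=10, hosts_per_location=70, seed=500 + rep)
            hosts, _ = simulate_hosts(cfg, np.full(10, 0.35))
            sub = hosts[["amoebophilus", "hayleyella", "location_id"]].dropna()
            frame = pd.DataFrame({
                "response": sub["amoebophilus"].astype(int).to_numpy(),
                "partner": sub["hayleyella"].astype(int).to_numpy(),
                "location_id": sub["location_id"].to_numpy(),
            })
            from symbioclim.glmm import fit_logistic_glmm
            estimates.append(fit_logistic_glmm(frame, "response", ["partner"]).coef("partner"))
        assert abs(np.mean(estimates)) < 0.15


class TestFisherByLocation:
    def _hosts(self):
        rng = np.random.default_rng(2)
        rows = []
        for loc, (pa, pb) in {"L1": (0.4, 0.3), "L2": (0.5, 0.0), "L3": (0.3, 0.4)}.items():
            for i in range(30):
                rows.append({
                    "host_id": f"{loc}-{i}", "location_id": loc, "year": 2000,
                    "agricolaris": int(rng.random() < pa),
                    "hayleyella": int(rng.random() < pb),
                    "bonniea": 0, "amoebophilus": 0, "chlamydiae": 0,
                })
        return pd.DataFrame(rows)

    def test_single_species_location_excluded(self):
        results = fisher_by_location(self._hosts(), ("agricolaris", "hayleyella"))
        assert {r.location_id for r in results} == {"L1", "L3"}

    def test_single_location_adjustment_is_identity(self):
        hosts = self._hosts()
        hosts = hosts[hosts["location_id"] == "L1"]
        results = fisher_by_location(hosts, ("agricolaris", "hayleyella"))
        assert len(results) == 1
        assert results[0].p_adj == pytest.approx(results[0].p)

    def test_rejects_non_paraburkholderia_pair(self):
        with pytest.raises(ValueError):
            fisher_by_location(self._hosts(), ("agricolaris", "chlamydiae"))

    def test_type_one_error_controlled_under_independence(self):
        """Fraction of BH-adjusted rejections stays near/below nominal."""
        rng = np.random.default_rng(7)
        n_reps, rejections, tests = 150, 0, 0
        for _ in range(n_reps):
            rows = []
            for loc in ("A", "B", "C", "D"):
                for i in range(25):
                    rows.append({
                        "host_id": f"{loc}{i}", "location_id": loc, "year": 2000,
                        "agricolaris": int(rng.random() < 0.35),
                        "hayleyella": int(rng.random() < 0.3),
                        "bonniea": 0, "amoebophilus": 0, "chlamydiae": 0,
                    })
            res = fisher_by_location(pd.DataFrame(rows), ("agricolaris", "hayleyella"))
            rejections += sum(r.p_adj < 0.05 for r in res)
            tests += len(res)
        assert rejections / max(tests, 1) <= 0.05
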