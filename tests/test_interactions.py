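"""Cox engine oracle checks, GxG scan, FDR, tertiles, KM estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import carriermod as cm
from carriermod.interactions import (NoEventsError, benjamini_yekutieli,
                                     bh_fdr, cox_fit,
                                     expression_interaction_survival,
                                     gxg_pair, gxg_scan, km_estimate,
                                     tertile_categorize)


def brute_force_cox(times, events, x):
    """Independent oracle: direct maximisation of the hand-written Cox
    partial likelihood (no ties in the inputs used here)."""
    times, events, x = map(np.asarray, (times, events, x))

    def nll(beta):
        total = 0.0
        for i in np.flatnonzero(events):
            risk = times >= times[i]
            total += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -total

    res = optimize.minimize_scalar(nll, bounds=(-8, 8), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


class TestCoxFit:
    def test_six_subject_toy_matches_brute_force(self):
        times = [2.0, 3.0, 5.0, 7.0, 9.0, 11.0]
        events = [1, 0, 1, 0, 1, 0]
        x = [1.0, 0.0, 2.0, 1.0, 0.0, 2.0]
        table = pd.DataFrame({"exit": times, "event": events, "x": x})
        res = cox_fit(table, ["x"], entry_col=None)
        assert res.loc[0, "coef"] == pytest.approx(
            brute_force_cox(times, events, x), abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_tables_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        checked = 0
        while checked < 3:
            n = int(rng.integers(5, 9))
            times = rng.exponential(5, n) + rng.uniform(0, 1, n)  # no ties
            events = rng.integers(0, 2, n)
            if events.sum() < 2:
                continue
            x = rng.normal(size=n)
            bf = brute_force_cox(times, events, x)
            if abs(bf) > 3.0:  # near-separation: no stable finite MLE
                continue
            table = pd.DataFrame({"exit": times, "event": events, "x": x})
            res = cox_fit(table, ["x"], entry_col=None)
            assert res.loc[0, "coef"] == pytest.approx(bf, abs=1e-5)
            checked += 1

    def test_row_duplication_halves_variance(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.4 * x))
        table = pd.DataFrame({"exit": t, "event": 1, "x": x})
        res1 = cox_fit(table, ["x"], entry_col=None)
        res2 = cox_fit(pd.concat([table, table], ignore_index=True), ["x"],
                       entry_col=None)
        # duplication makes every event a tie, so Efron's correction shifts
        # the estimate slightly; invariance is only approximate
        assert res2.loc[0, "coef"] == pytest.approx(res1.loc[0, "coef"],
                                                    abs=5e-3)
        assert (res2.loc[0, "se"] ** 2 / res1.loc[0, "se"] ** 2
                == pytest.approx(0.5, abs=0.02))

    def test_null_p_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(150):
            n = 120
            x = rng.normal(size=n)
            table = pd.DataFrame({"exit": rng.exponential(1, n), "event": 1,
                                  "x": x})
            pvals.append(cox_fit(table, ["x"], entry_col=None).loc[0, "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_covariate_dropped(self):
        table = pd.DataFrame({"exit": [1.0, 2.0, 3.0], "event": [1, 1, 0],
                              "x": [1.0, 1.0, 1.0], "y": [0.0, 1.0, 2.0]})
        res = cox_fit(table, ["x", "y"], entry_col=None)
        assert list(res["term"]) == ["y"]

    def test_no_events_raises(self):
        table = pd.DataFrame({"exit": [1.0, 2.0], "event": [0, 0],
                              "x": [0.0, 1.0]})
        with pytest.raises(NoEventsError):
            cox_fit(table, ["x"], entry_col=None)


class TestGxG:
    def _cohort(self, seed=5, beta_ab=0.0, n_fam=2_500):
        c = cm.SimulationConfig(n_families=n_fam,
                                family_structure={"singleton": 1.0},
                                haplotypes=("00", "01", "10", "11"),
                                haplotype_freqs=(0.36, 0.24, 0.24, 0.16),
                                true_log_hr_breast=(0.1, 0.1),
                                true_log_hr_ovarian=(0.0, 0.0), seed=seed)
        g = cm.simulate_genotypes(c)
        rec = cm.simulate_phenotypes(g, c)
        if beta_ab != 0.0:
            # add a product-term effect by re-simulating survival with the
            # interaction in the linear predictor
            from carriermod.synthetic import (_in_sample_baseline,
                                              _invert_hazard, stream)
            inc = c.incidence("breast")
            risk = (0.1 * g.dose[:, 0] + 0.1 * g.dose[:, 1]
                    + beta_ab * g.dose[:, 0] * g.dose[:, 1]).astype(float)
            lam0 = _in_sample_baseline(inc, risk, c.min_age)
            onset = _invert_hazard(lam0, inc.edges, np.exp(risk), c.min_age,
                                   stream(c.seed, "gxg-onset"))
            fup = rec["age_last_followup"].to_numpy(float)
            rec = rec.copy()
            rec["age_breast"] = np.where(onset < fup, np.round(onset, 4),
                                         np.nan)
            rec["age_ovarian"] = np.nan
        return rec, g

    def test_self_pair_rejected(self):
        rec, g = self._cohort(n_fam=200)
        with pytest.raises(ValueError, match="itself"):
            gxg_scan(rec, g, ["snp1"], ["snp1"])

    def test_identical_genotype_vectors_rejected(self):
        rec, g = self._cohort(n_fam=200)
        with pytest.raises(ValueError, match="itself"):
            gxg_pair(rec, g.dose[:, 0], g.dose[:, 0])

    def test_sparse_pair_skipped(self):
        rec, g = self._cohort(n_fam=200)
        out = gxg_scan(rec, g, ["snp1"], ["snp2"], min_double_carriers=10 ** 6)
        assert len(out) == 0

    def test_interaction_recovery(self):
        truth = np.log(1.33)
        rec, g = self._cohort(seed=6, beta_ab=truth, n_fam=6_000)
        res = gxg_pair(rec, g.dose[:, 0], g.dose[:, 1])
        assert 1.05 < res.interaction_hr < 1.70  # truth 1.33, ~3 sigma band
        assert res.p_interaction < 0.05

    def test_null_scan_fdr_control(self):
        # scaled-down null FDR check: scans of independent null pairs,
        # empirical FDR at q=0.05 stays near zero
        false_disc, n_scans = 0, 40
        for s in range(n_scans):
            rec, g = self._cohort(seed=700 + s, n_fam=400)
            out = gxg_scan(rec, g, ["snp1"], ["snp2"], cluster=False)
            false_disc += int((out["fdr"] < 0.05).sum() > 0)
        assert false_disc / n_scans <= 0.075 + 2.5 * np.sqrt(
            0.05 * 0.95 / n_scans)

    def test_category_coding(self):
        rec, g = self._cohort(seed=8, n_fam=2_000)
        res = gxg_pair(rec, g.dose[:, 0], g.dose[:, 1], coding="category",
                       categories=("het", "carrier"))
        assert set(res.term_names) == {"a", "b", "ab"}
        assert res.interaction_hr > 0


class TestFDR:
    def test_single_p_identity(self):
        assert bh_fdr([0.02], m=1)[0] == pytest.approx(0.02)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.001, 0.02, 0.03], m=3),
                                   [0.003, 0.03, 0.03])

    def test_constant_vector_family_41(self):
        np.testing.assert_allclose(bh_fdr([0.05] * 41, m=41), [0.05] * 41)

    def test_family_larger_than_vector(self):
        # testing 3 SNPs of a declared family of 41
        np.testing.assert_allclose(bh_fdr([0.001, 0.02, 0.03], m=41),
                                   [0.041, 0.41, 0.41])

    def test_matches_statsmodels_when_family_equals_length(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-5, 1, 40)
        np.testing.assert_allclose(bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_rank_transform(self, pvals):
        adj = bh_fdr(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in ranks
        assert np.all(adj <= 1.0)
        # re-adjusting can only move values up (step-up with inflated input)
        assert np.all(bh_fdr(adj) >= adj - 1e-12)

    def test_by_variant_more_conservative(self):
        p = [0.001, 0.02, 0.03]
        assert np.all(benjamini_yekutieli(p) >= bh_fdr(p) - 1e-12)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.2], m=1)


class TestTertiles:
    def test_balanced_one_to_nine(self):
        cats = tertile_categorize(range(1, 10))
        assert list(cats) == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3

    def test_boundary_ties_go_low(self):
        cats = tertile_categorize([1, 1, 1, 2, 3, 3])
        assert list(cats) == ["low", "low", "low", "medium", "high", "high"]

    @given(st.lists(st.integers(-10 ** 6, 10 ** 6), min_size=5, max_size=40,
                    unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, ints):
        values = np.asarray(ints, float) / 1000.0
        base = tertile_categorize(values)
        transformed = tertile_categorize(np.exp(values / 2000.0))
        assert list(base) == list(transformed)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            tertile_categorize([1.0, 1.0, 1.0, 2.0])


class TestKM:
    def test_no_events_flat_at_one(self):
        km = km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_computed_product_limit(self):
        km = km_estimate([1, 2, 3, 5], [1, 0, 1, 0]).set_index("time")
        assert km.loc[0.0, "survival"] == 1.0
        assert km.loc[1.0, "survival"] == pytest.approx(0.75)
        assert km.loc[3.0, "survival"] == pytest.approx(0.375)

    def test_order_permutation_invariant(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(1, 50)
        e = rng.integers(0, 2, 50)
        km1 = km_estimate(t, e)
        perm = rng.permutation(50)
        km2 = km_estimate(t[perm], e[perm])
        pd.testing.assert_frame_equal(km1, km2)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(1, 60)
        km = km_estimate(t, np.ones(60, int))
        ts = np.sort(t)
        for i, u in enumerate(ts):
            emp = (t > u).mean()
            row = km[km["time"] == u]
            assert row["survival"].iloc[0] == pytest.approx(emp, abs=1e-12)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(12)
        km = km_estimate(rng.exponential(1, 80), rng.integers(0, 2, 80))
        assert np.all(np.diff(km["survival"]) <= 1e-12)


class TestExpressionInteraction:
    def test_km_groups_start_at_one(self):
        tab = cm.simulate_expression_cohort(600, beta_a=0.3, seed=13)
        res, km = expression_interaction_survival(tab, "geneA", "geneB")
        for _, grp in km.groupby("group"):
            assert grp.sort_values("time")["survival"].iloc[0] == 1.0
            assert np.all(np.diff(grp.sort_values("time")["survival"])
                          <= 1e-12)

    def test_scale_invariance_of_interaction_hr(self):
        tab = cm.simulate_expression_cohort(1_500, beta_a=0.2, beta_b=0.2,
                                            beta_ab=0.3, seed=14)
        res1, _ = expression_interaction_survival(tab, "geneA", "geneB")
        tab2 = tab.copy()
        tab2["geneA"] = tab2["geneA"] * 37.0 + 5.0
        res2, _ = expression_interaction_survival(tab2, "geneA", "geneB")
        assert res2.interaction_hr == pytest.approx(res1.interaction_hr,
                                                    rel=1e-9)

    def test_empty_tertile_combinations_reported(self):
        # perfectly rank-correlated expressions leave off-diagonal tertile
        # combinations empty; they must be reported, not dropped
        rng = np.random.default_rng(15)
        x = np.sort(rng.normal(size=300))
        tab = pd.DataFrame({"time": rng.exponential(1, 300),
                            "event": 1, "geneA": x,
                            "geneB": x + 0.01 * rng.normal(size=300)})
        res, km = expression_interaction_survival(tab, "geneA", "geneB")
        assert "geneA_low|geneB_high" in res.empty_groups
        assert "geneA_high|geneB_low" in res.empty_groups
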