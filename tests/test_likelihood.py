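"""Retrospective-likelihood core: phenotype rules, baseline constraint,
likelihood oracles, score test, estimation, competing risks, stratified and
heterogeneity tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import carriermod as cm
from carriermod.incidence import IncidenceModel
from carriermod.likelihood import (AssociationResult, Baseline, EffectModel,
                                   GenotypePrior, build_cohort,
                                   constrain_baseline, er_subtype_analysis,
                                   genotype_posteriors, loglik_terms,
                                   mixture_incidence, phenotype_likelihood,
                                   retrospective_loglik)


def sim_cohort(n_fam=400, beta=0.0, seed=1, structure=None, asc=None, **kw):
    c = cm.SimulationConfig(
        n_families=n_fam,
        family_structure=structure or {"singleton": 1.0},
        haplotypes=("0", "1"), haplotype_freqs=(0.75, 0.25),
        true_log_hr_breast=(beta,), true_log_hr_ovarian=(0.0,),
        ascertainment=asc, seed=seed, **kw)
    return cm.simulate_ascertained_cohort(c)


class TestBuildPhenotype:
    def test_ovarian_before_breast(self, make_records):
        # ovarian at 40 censors the breast analysis (unaffected at 40) but
        # is the ovarian-analysis event
        rec = make_records([dict(breast=45.0, ovarian=40.0, followup=70.0)])
        b, _ = build_cohort(rec, "breast")
        assert b.loc[0, "affected"] == 0 and b.loc[0, "exit"] == 40.0
        o, _ = build_cohort(rec, "ovarian")
        assert o.loc[0, "affected"] == 1 and o.loc[0, "exit"] == 40.0

    def test_ovarian_after_breast_still_affected(self, make_records):
        # breast cancer is not a censoring event in the ovarian analysis
        rec = make_records([dict(breast=45.0, ovarian=50.0, followup=70.0)])
        b, _ = build_cohort(rec, "breast")
        assert b.loc[0, "affected"] == 1 and b.loc[0, "exit"] == 45.0
        o, _ = build_cohort(rec, "ovarian")
        assert o.loc[0, "affected"] == 1 and o.loc[0, "exit"] == 50.0

    def test_censored_only(self, make_records):
        rec = make_records([dict(followup=60.0)])
        for disease in ("breast", "ovarian"):
            coh, _ = build_cohort(rec, disease)
            assert coh.loc[0, "affected"] == 0 and coh.loc[0, "exit"] == 60.0

    def test_mastectomy_censors_breast_only(self, make_records):
        rec = make_records([dict(breast=55.0, mastectomy=50.0, followup=70.0)])
        b, _ = build_cohort(rec, "breast")
        assert b.loc[0, "affected"] == 0 and b.loc[0, "exit"] == 50.0

    def test_oophorectomy_censors_ovarian(self, make_records):
        rec = make_records([dict(ovarian=55.0, oophorectomy=50.0, followup=70.0)])
        o, _ = build_cohort(rec, "ovarian")
        assert o.loc[0, "affected"] == 0 and o.loc[0, "exit"] == 50.0

    def test_er_subtype_censors_other_subtype_case(self, make_records):
        rec = make_records([dict(breast=45.0, followup=70.0, er="pos"),
                            dict(iid="I2", fam="F2", breast=47.0,
                                 followup=70.0, er="neg")])
        pos, _ = build_cohort(rec, "breast", er_subtype="pos")
        assert list(pos["affected"]) == [1, 0]
        assert list(pos["exit"]) == [45.0, 47.0]

    def test_unusable_exit_excluded_with_reason(self, make_records):
        rec = make_records([dict(followup=10.0), dict(iid="I2", followup=60.0)])
        coh, excl = build_cohort(rec, "breast")
        assert len(coh) == 1
        assert excl[0][0] == "I1" and "exit age" in excl[0][1]


class TestConstrainBaseline:
    def test_null_effect_identity(self, stepped_incidence):
        b = constrain_baseline(stepped_incidence, EffectModel("per_allele", 0.0),
                               GenotypePrior(0.3))
        np.testing.assert_allclose(b.lam0, stepped_incidence.rates)

    def test_single_interval_closed_form(self):
        # E[exp(beta g)] at q=0.5, HR 2: 0.25 + 0.5*2 + 0.25*4 = 2.25
        inc = IncidenceModel("x", np.array([18.0]), np.array([0.02]))
        b = constrain_baseline(inc, EffectModel("per_allele", np.log(2.0)),
                               GenotypePrior(0.5))
        assert b.lam0[0] == pytest.approx(0.02 / 2.25, rel=1e-12)

    @pytest.mark.parametrize("beta,q", [(0.5, 0.25), (-1.2, 0.4), (2.0, 0.1)])
    def test_mixture_reproduces_input(self, stepped_incidence, beta, q):
        prior = GenotypePrior(q)
        b = constrain_baseline(stepped_incidence, EffectModel("per_allele", beta),
                               prior)
        mix = mixture_incidence(b, prior)
        np.testing.assert_allclose(mix, stepped_incidence.rates, rtol=1e-10)

    @given(beta=st.floats(-2, 2), q=st.floats(0.05, 0.5),
           scale=st.floats(0.1, 3.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mixture_roundtrip_property(self, beta, q, scale):
        inc = IncidenceModel("x", np.array([18.0, 30.0, 50.0]),
                             scale * np.array([0.002, 0.01, 0.02]))
        prior = GenotypePrior(q)
        b = constrain_baseline(inc, EffectModel("per_allele", beta), prior)
        np.testing.assert_allclose(mixture_incidence(b, prior), inc.rates,
                                   rtol=1e-10)


class TestPhenotypeLikelihood:
    def test_null_effect_equal_across_genotypes(self, stepped_incidence):
        b = constrain_baseline(stepped_incidence, EffectModel("per_allele", 0.0),
                               GenotypePrior(0.3))
        vals = [phenotype_likelihood(20.0, 45.0, False, g, b) for g in range(3)]
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_exponential_closed_form(self):
        # constant hazard 0.01/yr, 50 unaffected years: exp(-0.5)
        inc = IncidenceModel("x", np.array([0.0]), np.array([0.01]))
        b = constrain_baseline(inc, EffectModel("per_allele", 0.0),
                               GenotypePrior(0.3))
        val = phenotype_likelihood(0.0, 50.0, False, 0, b)
        assert val == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_affected_density_matches_cdf_derivative(self, stepped_incidence):
        # f(t) = -dS/dt, checked by central finite difference
        b = constrain_baseline(stepped_incidence,
                               EffectModel("per_allele", 0.4),
                               GenotypePrior(0.25))
        g, t, h = 1, 44.0, 1e-5
        surv = lambda u: phenotype_likelihood(18.0, u, False, g, b)
        density = phenotype_likelihood(18.0, t, True, g, b)
        fd = -(surv(t + h) - surv(t - h)) / (2 * h)
        assert density == pytest.approx(fd, rel=1e-6)

    def test_exit_outside_grid_rejected(self, stepped_incidence):
        b = constrain_baseline(stepped_incidence, EffectModel("per_allele", 0.0),
                               GenotypePrior(0.3))
        with pytest.raises(ValueError, match="outside"):
            phenotype_likelihood(18.0, 150.0, False, 0, b)


def brute_force_loglik(cohort, g, beta, q, incidence):
    """Independent oracle: explicit per-individual enumeration of the
    3-genotype denominator using phenotype_likelihood."""
    prior = GenotypePrior(q)
    baseline = constrain_baseline(incidence, EffectModel("per_allele", beta),
                                  prior)
    p = prior.probs()
    total = 0.0
    for i in range(len(cohort)):
        row = cohort.iloc[i]
        probs = [phenotype_likelihood(row["entry"], row["exit"],
                                      bool(row["affected"]), gg, baseline)
                 for gg in range(3)]
        total += np.log(probs[g[i]] * p[g[i]]
                        / sum(pr * pg for pr, pg in zip(probs, p)))
    return total


class TestRetrospectiveLoglik:
    def test_null_reduces_to_prior(self, stepped_incidence, make_records):
        rec = make_records([dict(breast=45.0), dict(iid="I2", fam="F2")])
        cohort, _ = build_cohort(rec, "breast")
        g = np.array([1, 0])
        prior = GenotypePrior(0.3)
        terms = loglik_terms(cohort, g, EffectModel("per_allele", 0.0), prior,
                             stepped_incidence)
        np.testing.assert_allclose(terms, np.log(prior.probs())[g], rtol=1e-12)

    def test_two_individual_enumeration_oracle(self, stepped_incidence,
                                               make_records):
        rec = make_records([dict(breast=42.0, followup=60.0),
                            dict(iid="I2", fam="F2", followup=55.0)])
        cohort, _ = build_cohort(rec, "breast")
        g = np.array([2, 0])
        for beta in (-0.5, 0.0, 0.8):
            ll = retrospective_loglik(cohort, g, EffectModel("per_allele", beta),
                                      GenotypePrior(0.3), stepped_incidence)
            assert ll == pytest.approx(
                brute_force_loglik(cohort, g, beta, 0.3, stepped_incidence),
                rel=1e-10)

    def test_posteriors_sum_to_one(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=200, beta=0.3, seed=5)
        cohort, _ = build_cohort(rec, "breast")
        post = genotype_posteriors(cohort, EffectModel("per_allele", 0.3),
                                   GenotypePrior(0.25), stepped_incidence)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_mle_beats_null(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=500, beta=0.4, seed=6)
        cohort, _ = build_cohort(rec, "breast")
        g = gm.dose[cohort["row"].to_numpy(), 0].astype(int)
        est = cm.estimate_hr(rec, gm.dose[:, 0], stepped_incidence, "breast")
        q = g.mean() / 2
        ll_hat = retrospective_loglik(cohort, g,
                                      EffectModel("per_allele", est.beta_hat),
                                      GenotypePrior(q), stepped_incidence)
        ll_0 = retrospective_loglik(cohort, g, EffectModel("per_allele", 0.0),
                                    GenotypePrior(q), stepped_incidence)
        assert ll_hat >= ll_0

    def test_empty_cohort_rejected(self, stepped_incidence):
        with pytest.raises(ValueError, match="empty"):
            retrospective_loglik(pd.DataFrame(columns=["entry", "exit",
                                                       "affected"]),
                                 np.array([], int),
                                 EffectModel("per_allele", 0.0),
                                 GenotypePrior(0.3), stepped_incidence)


class TestScoreTest:
    def test_analytic_score_matches_finite_difference(self, stepped_incidence):
        rng = np.random.default_rng(7)
        h = 1e-6
        for _ in range(10):
            rec, gm = sim_cohort(n_fam=rng.integers(30, 80), beta=0.0,
                                 seed=int(rng.integers(1 << 30)))
            res = cm.score_test(rec, gm.dose[:, 0], stepped_incidence, "breast")
            cohort, _ = build_cohort(rec, "breast")
            g = gm.dose[cohort["row"].to_numpy(), 0].astype(int)
            q = g.mean() / 2
            ll = lambda b: retrospective_loglik(
                cohort, g, EffectModel("per_allele", b), GenotypePrior(q),
                stepped_incidence)
            fd = (ll(h) - ll(-h)) / (2 * h)
            assert res.score_U == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_singleton_families_reduce_to_naive(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=300, seed=8)
        res = cm.score_test(rec, gm.dose[:, 0], stepped_incidence, "breast")
        assert res.variance_V == pytest.approx(res.naive_V, rel=1e-12)

    def test_monomorphic_marker_untestable(self, stepped_incidence, make_records):
        rec = make_records([dict(breast=45.0), dict(iid="I2", fam="F2")])
        res = cm.score_test(rec, np.array([1, 1]), stepped_incidence, "breast")
        assert not res.testable
        assert np.isnan(res.p)

    def test_null_type1_error_ascertained(self, stepped_incidence):
        # 300 quick null replicates; binomial 99% band around 0.05
        rej = 0
        nrep = 300
        for r in range(nrep):
            rec, gm = sim_cohort(n_fam=260, seed=90_000 + r,
                                 asc={"affected": 1.0, "unaffected": 0.3})
            res = cm.score_test(rec, gm.dose[:, 0], stepped_incidence, "breast")
            rej += res.p < 0.05
        lo, hi = stats.binom.interval(0.99, nrep, 0.05)
        assert lo <= rej <= hi


class TestEstimateHR:
    def test_allele_flip_negates_beta(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=600, beta=0.3, seed=9)
        a = cm.estimate_hr(rec, gm.dose[:, 0], stepped_incidence, "breast")
        b = cm.estimate_hr(rec, 2 - gm.dose[:, 0], stepped_incidence, "breast")
        assert a.beta_hat == pytest.approx(-b.beta_hat, abs=2e-5)

    def test_null_cohort_hr_near_one(self):
        inc = cm.default_incidence("BRCA1", "breast")
        rec, gm = sim_cohort(n_fam=8_000, beta=0.0, seed=10)
        res = cm.estimate_hr(rec, gm.dose[:, 0], inc, "breast")
        assert 0.95 <= res.hr <= 1.05
        assert res.ci95[0] < 1.0 < res.ci95[1]

    def test_genotype_coding_two_parameters(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=2_000, beta=0.35, seed=11)
        res = cm.estimate_hr(rec, gm.dose[:, 0], stepped_incidence, "breast",
                             coding="genotype")
        assert res.beta_hat.shape == (2,)
        # per-allele truth: hom log-HR ~ 2x het log-HR
        assert res.hr[1] > res.hr[0] > 0.9

    def test_result_invariants(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=500, beta=0.2, seed=12)
        st_res = cm.score_test(rec, gm.dose[:, 0], stepped_incidence, "breast")
        est = cm.estimate_hr(rec, gm.dose[:, 0], stepped_incidence, "breast")
        assert st_res.chi2 == pytest.approx(
            st_res.score_U ** 2 / st_res.variance_V)
        assert est.ci95[0] < est.ci95[1]
        assert est.hr == pytest.approx(np.exp(est.beta_hat))


class TestCompetingRisks:
    def _cohort_no_ovarian(self, seed=13, n_fam=800):
        zero = IncidenceModel("ovarian", np.array([18.0]), np.array([0.0]))
        return sim_cohort(n_fam=n_fam, beta=0.25, seed=seed,
                          incidence_ovarian=zero,
                          censor_model=cm.CensorModel(p_oophorectomy=0.0))

    def test_reduction_to_single_disease(self):
        incb = cm.default_incidence("BRCA1", "breast")
        inco = cm.default_incidence("BRCA1", "ovarian")
        rec, gm = self._cohort_no_ovarian()
        assert rec["age_ovarian"].isna().all()
        joint = cm.competing_risks_fit(rec, gm.dose[:, 0], incb, inco,
                                       fix_ovarian=0.0)
        single = cm.estimate_hr(rec, gm.dose[:, 0], incb, "breast")
        assert abs(joint["breast"].beta_hat - single.beta_hat) < 1e-8

    def test_cause_probabilities_conserve_total(self):
        # integral of both cause densities plus final survivor equals 1
        incb = cm.default_incidence("BRCA1", "breast")
        inco = cm.default_incidence("BRCA1", "ovarian")
        prior = GenotypePrior(0.25)
        bb = constrain_baseline(incb, EffectModel("per_allele", 0.3), prior)
        bo = constrain_baseline(inco, EffectModel("per_allele", -0.2), prior)
        tgrid = np.linspace(18.0, 119.99, 200_000)
        dt = tgrid[1] - tgrid[0]
        for g in range(3):
            Sb = np.exp(-bb.multipliers[g] * (bb.cum0(tgrid) - bb.cum0(18.0)))
            So = np.exp(-bo.multipliers[g] * (bo.cum0(tgrid) - bo.cum0(18.0)))
            fb = bb.hazard0(tgrid) * bb.multipliers[g] * Sb * So
            fo = bo.hazard0(tgrid) * bo.multipliers[g] * Sb * So
            total = (fb + fo).sum() * dt + Sb[-1] * So[-1]
            assert total == pytest.approx(1.0, abs=5e-4)

    def test_missing_incidence_rejected(self):
        rec, gm = self._cohort_no_ovarian(n_fam=50)
        with pytest.raises(ValueError, match="incidence"):
            cm.competing_risks_fit(rec, gm.dose[:, 0],
                                   cm.default_incidence("BRCA1", "breast"),
                                   None)


class TestStratifiedAndHeterogeneity:
    def test_single_stratum_matches_unstratified(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=600, beta=0.3, seed=14)
        per, pooled = cm.stratified_test(rec, gm.dose[:, 0], stepped_incidence,
                                         "breast")
        flat = cm.estimate_hr(rec, gm.dose[:, 0], stepped_incidence, "breast")
        assert len(per) == 1
        only = next(iter(per.values()))
        assert only.beta_hat == pytest.approx(flat.beta_hat, abs=1e-6)
        assert pooled.beta_hat == pytest.approx(flat.beta_hat, abs=1e-5)

    def test_pooled_between_stratum_estimates(self, stepped_incidence):
        rec, gm = sim_cohort(n_fam=1_500, beta=0.25, seed=15, n_strata=2)
        per, pooled = cm.stratified_test(rec, gm.dose[:, 0], stepped_incidence,
                                         "breast")
        betas = sorted(r.beta_hat for r in per.values())
        assert betas[0] - 1e-9 <= pooled.beta_hat <= betas[-1] + 1e-9

    def test_effect_difference_examples(self):
        a = AssociationResult("breast", beta_hat=0.2, var_beta=0.01)
        b = AssociationResult("breast", beta_hat=0.2, var_beta=0.01)
        assert cm.effect_difference_test(a, b) == pytest.approx(1.0)
        c = AssociationResult("breast",
                              beta_hat=0.2 + 1.96 * np.sqrt(0.02),
                              var_beta=0.01)
        assert cm.effect_difference_test(a, c) == pytest.approx(0.05, rel=1e-3)
        assert cm.effect_difference_test(c, a) == pytest.approx(
            cm.effect_difference_test(a, c))

    def test_heterogeneity_closed_forms(self):
        r1 = AssociationResult("breast", beta_hat=0.3, var_beta=0.02)
        r2 = AssociationResult("breast", beta_hat=0.3, var_beta=0.02)
        Q, p = cm.heterogeneity_test([r1, r2])
        assert Q == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
        # two strata, equal variances v, betas differing by d: Q = d^2 / 2v
        r3 = AssociationResult("breast", beta_hat=0.5, var_beta=0.02)
        Q, _ = cm.heterogeneity_test([r1, r3])
        assert Q == pytest.approx(0.2 ** 2 / (2 * 0.02), rel=1e-9)

    def test_heterogeneity_null_p_uniform(self):
        # homogeneous strata: Q is chi-square, p uniform (KS over 400 draws)
        rng = np.random.default_rng(16)
        pvals = []
        for _ in range(400):
            results = [AssociationResult("breast",
                                         beta_hat=rng.normal(0.1, np.sqrt(v)),
                                         var_beta=v)
                       for v in (0.01, 0.02, 0.015)]
            pvals.append(cm.heterogeneity_test(results)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_heterogeneity_needs_two_strata(self):
        with pytest.raises(ValueError, match=">= 2"):
            cm.heterogeneity_test([AssociationResult("breast", beta_hat=0.1,
                                                     var_beta=0.01)])

    def test_er_subtype_analysis_runs(self):
        inc = cm.default_incidence("BRCA1", "breast")
        rec, gm = sim_cohort(n_fam=2_000, beta=0.2, seed=17,
                             er_unknown_fraction=0.0)
        out = er_subtype_analysis(rec, gm.dose[:, 0], inc)
        assert 0.0 < out["p_difference"] <= 1.0
        assert out["pos"].n_individuals == out["neg"].n_individuals
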