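"""Retrospective-likelihood association analysis for mutation carriers.

Carriers recruited through cancer genetics clinics are sampled non-randomly
with respect to disease status, so a prospective cohort likelihood of
phenotypes given genotypes is biased.  The machinery here instead models the
*retrospective* likelihood of the observed genotypes conditional on the
disease phenotypes,

    L = prod_i  P(pheno_i | g_i) p(g_i) / sum_g' P(pheno_i | g') p(g'),

which is valid under any phenotype-dependent sampling.  P(pheno | g) is a
survival likelihood with genotype-specific hazard lam0(t) * exp(beta * g),
where the baseline lam0 is *constrained* so that the population-average
incidence over the genotype distribution among survivors reproduces a
supplied carrier incidence curve (see :func:`constrain_baseline`).

Association is assessed with a 1-df score test whose variance is clustered
over families (the kinship adjustment appropriate for the shallow family
structures handled here), and hazard ratios are estimated by maximising the
retrospective likelihood with per-allele or genotype-level effect codings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .incidence import IncidenceModel

logger = logging.getLogger("carriermod.likelihood")

DEFAULT_MIN_AGE = 18.0
BETA_BOUNDS = (-5.0, 5.0)
BETA_XATOL = 1e-6


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class GenotypePrior:
    """HWE genotype distribution for the dose-counted allele (frequency f):
    P(g) = ((1-f)^2, 2 f (1-f), f^2) for g = 0, 1, 2."""
    allele_freq: float
    mode: str = "HWE"

    def __post_init__(self):
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must lie strictly in (0, 1)")
        if self.mode != "HWE":
            raise ValueError("only HWE priors are supported")

    def probs(self) -> np.ndarray:
        f = self.allele_freq
        return np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])


@dataclass(frozen=True)
class EffectModel:
    """Log-hazard-ratio coding.

    ``per_allele``: hazard multiplied by exp(beta) per copy of the dose
    allele.  ``genotype``: separate log-HRs for heterozygotes and rare
    homozygotes versus common homozygotes.
    """
    coding: str = "per_allele"
    beta: np.ndarray | float = 0.0

    def multipliers(self) -> np.ndarray:
        b = np.atleast_1d(np.asarray(self.beta, float))
        if not np.all(np.isfinite(b)):
            raise ValueError("beta must be finite")
        if self.coding == "per_allele":
            return np.exp(np.array([0.0, b[0], 2 * b[0]]))
        if self.coding == "genotype":
            if b.size != 2:
                raise ValueError("genotype coding needs (het, hom) betas")
            return np.exp(np.array([0.0, b[0], b[1]]))
        raise ValueError(f"unknown coding {self.coding!r}")


@dataclass
class AssociationResult:
    """Score statistic, kinship-adjusted variance and (optionally) the
    maximum-retrospective-likelihood hazard ratio with Wald CI."""
    disease: str
    score_U: float = np.nan
    variance_V: float = np.nan
    naive_V: float = np.nan
    chi2: float = np.nan
    p: float = np.nan
    beta_hat: float | np.ndarray = np.nan
    var_beta: float | np.ndarray = np.nan
    hr: float | np.ndarray = np.nan
    ci95: tuple = (np.nan, np.nan)
    n_individuals: int = 0
    n_families: int = 0
    coding: str = "per_allele"
    testable: bool = True
    converged: bool = True
    label: str = ""


# ---------------------------------------------------------------------------
# phenotype construction

_BREAST_EXIT = ["age_breast", "age_ovarian", "age_mastectomy", "age_last_followup"]
_OVARIAN_EXIT = ["age_ovarian", "age_oophorectomy", "age_last_followup"]


def build_cohort(records: pd.DataFrame, disease: str,
                 min_age: float = DEFAULT_MIN_AGE, er_subtype: str | None = None):
    """Construct analysis phenotypes for every record.

    Breast analysis: follow-up ends at the first of breast diagnosis,
    ovarian diagnosis, bilateral prophylactic mastectomy or last follow-up;
    carriers censored at ovarian diagnosis count as unaffected.  Ovarian
    analysis: follow-up ends at the first of ovarian diagnosis,
    risk-reducing oophorectomy or last follow-up; breast cancer is not a
    censoring event, so ovarian cancer after breast cancer still counts as
    affected.

    With ``er_subtype`` ("pos"/"neg"), breast cases of any other (or
    unknown) tumour subtype are treated as unaffected, censored at their
    diagnosis age.

    Returns ``(cohort, exclusions)`` where ``cohort`` has columns
    individual_id, family_id, row (position in ``records``), entry, exit,
    affected; ``exclusions`` lists (individual_id, reason).
    """
    if disease not in ("breast", "ovarian"):
        raise ValueError("disease must be 'breast' or 'ovarian'")
    cols = _BREAST_EXIT if disease == "breast" else _OVARIAN_EXIT
    ages = np.column_stack([
        pd.to_numeric(records[c], errors="coerce").to_numpy(float) for c in cols])
    with np.errstate(invalid="ignore"):
        exit_age = np.nanmin(ages, axis=1)
    event_age = ages[:, 0]  # diagnosis age of the target disease
    affected = np.isfinite(event_age) & (event_age <= exit_age)
    if er_subtype is not None:
        if disease != "breast":
            raise ValueError("ER subtypes apply to the breast analysis only")
        er = records["er_status"].fillna("").to_numpy(str)
        affected &= (er == er_subtype)

    usable = np.isfinite(exit_age) & (exit_age > min_age)
    exclusions = []
    for i in np.flatnonzero(~usable):
        reason = ("no usable exit age" if not np.isfinite(exit_age[i])
                  else f"exit age {exit_age[i]:.1f} <= entry age {min_age:.1f}")
        exclusions.append((records["individual_id"].iloc[i], reason))
        logger.info("excluded %s: %s", records["individual_id"].iloc[i], reason)

    cohort = pd.DataFrame({
        "individual_id": records["individual_id"].to_numpy()[usable],
        "family_id": records["family_id"].to_numpy()[usable],
        "row": np.flatnonzero(usable),
        "entry": min_age,
        "exit": exit_age[usable],
        "affected": affected[usable].astype(int),
    })
    return cohort, exclusions


def build_competing_cohort(records: pd.DataFrame,
                           min_age: float = DEFAULT_MIN_AGE):
    """First-event phenotype for the competing-risks analysis: exit at the
    first of breast/ovarian diagnosis, either surgery, or last follow-up;
    the cause labels the affected status."""
    cols = ["age_breast", "age_ovarian", "age_mastectomy",
            "age_oophorectomy", "age_last_followup"]
    ages = np.column_stack([
        pd.to_numeric(records[c], errors="coerce").to_numpy(float) for c in cols])
    with np.errstate(invalid="ignore"):
        exit_age = np.nanmin(ages, axis=1)
    breast = np.isfinite(ages[:, 0]) & (ages[:, 0] <= exit_age)
    ovarian = np.isfinite(ages[:, 1]) & (ages[:, 1] <= exit_age) & ~breast
    usable = np.isfinite(exit_age) & (exit_age > min_age)
    cohort = pd.DataFrame({
        "individual_id": records["individual_id"].to_numpy()[usable],
        "family_id": records["family_id"].to_numpy()[usable],
        "row": np.flatnonzero(usable),
        "entry": min_age,
        "exit": exit_age[usable],
        "affected_breast": breast[usable].astype(int),
        "affected_ovarian": ovarian[usable].astype(int),
    })
    return cohort


# ---------------------------------------------------------------------------
# constrained baseline and likelihood

@dataclass(frozen=True)
class Baseline:
    """Genotype-specific baseline on the incidence age grid."""
    edges: np.ndarray      # K + 1 interval edges
    lam0: np.ndarray       # K baseline hazards
    multipliers: np.ndarray  # exp(beta * g) for g = 0, 1, 2

    @property
    def cum_edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.lam0 * np.diff(self.edges))])

    def cum0(self, age):
        """Baseline cumulative hazard (genotype multiplier not applied)."""
        return np.interp(np.clip(age, self.edges[0], self.edges[-1]),
                         self.edges, self.cum_edges)

    def hazard0(self, age):
        idx = np.clip(np.searchsorted(self.edges, age, side="right") - 1,
                      0, len(self.lam0) - 1)
        return self.lam0[idx]


def constrain_baseline(incidence: IncidenceModel, effect: EffectModel,
                       prior: GenotypePrior) -> Baseline:
    """Solve for the baseline hazard lam0 such that the mixture of the
    genotype-specific hazards lam0(t) exp(beta g) over the genotype
    distribution *among survivors* reproduces the carrier incidence at
    every grid point.

    Processed interval by interval:
        lam0(k) = lam(k) * [sum_g p(g) S_g(k)] / [sum_g p(g) S_g(k) e^{beta g}]
    with S_g the genotype-specific survivor function accumulated over the
    preceding intervals (from the start of the age grid).
    """
    p = prior.probs()
    if p.sum() <= 0:
        raise ValueError("degenerate genotype prior")
    mult = effect.multipliers()
    edges = incidence.edges
    widths = np.diff(edges)
    lam0 = np.empty_like(incidence.rates)
    logS = np.zeros(3)
    for k in range(len(lam0)):
        S = np.exp(logS)
        lam0[k] = incidence.rates[k] * (p @ S) / (p @ (S * mult))
        logS = logS - lam0[k] * mult * widths[k]
    return Baseline(edges, lam0, mult)


def mixture_incidence(baseline: Baseline, prior: GenotypePrior) -> np.ndarray:
    """Population-average incidence implied by a constrained baseline,
    evaluated at the interval start points (for round-trip checks)."""
    p = prior.probs()
    widths = np.diff(baseline.edges)
    out = np.empty_like(baseline.lam0)
    logS = np.zeros(3)
    for k in range(len(out)):
        S = np.exp(logS)
        out[k] = baseline.lam0[k] * (p @ (S * baseline.multipliers)) / (p @ S)
        logS = logS - baseline.lam0[k] * baseline.multipliers * widths[k]
    return out


def phenotype_likelihood(entry: float, exit: float, affected: bool,
                         g: int, baseline: Baseline) -> float:
    """P(phenotype | genotype): survivor ratio over the at-risk window,
    times the genotype-specific hazard at exit for affected carriers."""
    if not (baseline.edges[0] <= exit <= baseline.edges[-1]):
        raise ValueError(f"exit age {exit} outside the baseline grid")
    m = baseline.multipliers[g]
    val = np.exp(-m * (baseline.cum0(exit) - baseline.cum0(entry)))
    if affected:
        val *= baseline.hazard0(exit) * m
    return float(val)


def _log_pheno_matrix(cohort: pd.DataFrame, baseline: Baseline) -> np.ndarray:
    """(n, 3) matrix of log P(pheno_i | g) for g = 0, 1, 2."""
    entry = cohort["entry"].to_numpy(float)
    exit_ = cohort["exit"].to_numpy(float)
    delta = cohort["affected"].to_numpy(float)
    dC = baseline.cum0(exit_) - baseline.cum0(entry)
    with np.errstate(divide="ignore"):
        log_h = np.log(baseline.hazard0(exit_))
    logm = np.log(baseline.multipliers)
    return (-np.outer(dC, baseline.multipliers)
            + delta[:, None] * (log_h[:, None] + logm[None, :]))


def loglik_terms(cohort: pd.DataFrame, g: np.ndarray, effect: EffectModel,
                 prior: GenotypePrior, incidence: IncidenceModel) -> np.ndarray:
    """Per-individual retrospective log-likelihood contributions
    log [ P(pheno|g_i) p(g_i) / sum_g' P(pheno|g') p(g') ]."""
    baseline = constrain_baseline(incidence, effect, prior)
    logP = _log_pheno_matrix(cohort, baseline)
    logprior = np.log(prior.probs())
    num = logP[np.arange(len(cohort)), g] + logprior[g]
    den = logsumexp(logP + logprior[None, :], axis=1)
    return num - den


def genotype_posteriors(cohort: pd.DataFrame, effect: EffectModel,
                        prior: GenotypePrior,
                        incidence: IncidenceModel) -> np.ndarray:
    """Conditional genotype probabilities P(g | pheno_i); rows sum to 1."""
    baseline = constrain_baseline(incidence, effect, prior)
    logP = _log_pheno_matrix(cohort, baseline) + np.log(prior.probs())[None, :]
    return np.exp(logP - logsumexp(logP, axis=1, keepdims=True))


def retrospective_loglik(cohort: pd.DataFrame, g: np.ndarray,
                         effect: EffectModel, prior: GenotypePrior,
                         incidence: IncidenceModel) -> float:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    return float(loglik_terms(cohort, g, effect, prior, incidence).sum())


# ---------------------------------------------------------------------------
# score test

def _family_sums(values: np.ndarray, family_ids: np.ndarray) -> np.ndarray:
    _, codes = np.unique(family_ids, return_inverse=True)
    if values.ndim == 1:
        return np.bincount(codes, weights=values)
    return np.column_stack([np.bincount(codes, weights=values[:, j])
                            for j in range(values.shape[1])])


def score_test(records: pd.DataFrame, genotype: np.ndarray,
               incidence: IncidenceModel, disease: str,
               min_age: float = DEFAULT_MIN_AGE,
               prior: GenotypePrior | None = None,
               er_subtype: str | None = None,
               dose: np.ndarray | None = None) -> AssociationResult:
    """Kinship-adjusted 1-df score test of the retrospective likelihood
    at beta = 0.

    The per-individual score contribution is u_i = (g_i - 2q)(d_i - H_i),
    with d_i the affected indicator and H_i the cumulative carrier hazard
    over the at-risk window; the variance is computed family-robustly as
    the sum of squared within-family score sums, which reduces to the
    unadjusted sum of squares when every family is a singleton.  When the
    allele frequency is the plug-in estimate, the residuals d_i - H_i are
    recentred so the variance accounts for the estimated frequency.

    ``dose`` (posterior-expected doses) replaces the hard calls in the
    score when given; this is the imputed-marker variant.
    """
    cohort, _ = build_cohort(records, disease, min_age, er_subtype)
    idx = cohort["row"].to_numpy()
    gvals = (np.asarray(dose, float) if dose is not None
             else np.asarray(genotype, float))[idx]
    n_fam = cohort["family_id"].nunique()
    result = AssociationResult(disease=disease, n_individuals=len(cohort),
                               n_families=n_fam)
    if len(cohort) == 0 or np.var(gvals) == 0:
        result.testable = False
        logger.warning("score_test: untestable marker (monomorphic or empty)")
        return result

    plug_in = prior is None
    q = gvals.mean() / 2.0 if plug_in else prior.allele_freq
    H = incidence.cumulative_hazard(cohort["exit"].to_numpy()) \
        - incidence.cumulative_hazard(cohort["entry"].to_numpy())
    resid = cohort["affected"].to_numpy(float) - H
    centre = resid.mean() if plug_in else 0.0
    u = (gvals - 2.0 * q) * (resid - centre)
    U = float(((gvals - 2.0 * q) * resid).sum())
    fam = _family_sums(u, cohort["family_id"].to_numpy())
    V = float((fam ** 2).sum())
    result.score_U = U
    result.variance_V = V
    result.naive_V = float((u ** 2).sum())
    if V <= 0:
        result.testable = False
        return result
    result.chi2 = U ** 2 / V
    result.p = float(stats.chi2.sf(result.chi2, df=1))
    return result


# ---------------------------------------------------------------------------
# maximum retrospective-likelihood estimation

def _profile_loglik_factory(cohort, g, incidence, coding, q_fixed):
    def loglik(beta, q):
        effect = EffectModel(coding, beta)
        prior = GenotypePrior(q)
        return retrospective_loglik(cohort, g, effect, prior, incidence)
    return loglik


def _sandwich(cohort, g, incidence, coding, beta_hat, q_hat, profile_freq,
              h=1e-5):
    """Family-clustered sandwich covariance of the free parameters.

    Parameters are the effect coefficients plus, when ``profile_freq``,
    the allele frequency.  A = -Hessian of the total log-likelihood
    (central differences), B = sum over families of outer products of
    within-family score sums.
    """
    beta_hat = np.atleast_1d(np.asarray(beta_hat, float))
    theta = np.concatenate([beta_hat, [q_hat]]) if profile_freq else beta_hat
    p = len(theta)

    def terms(th):
        b = th[:len(beta_hat)]
        q = th[len(beta_hat)] if profile_freq else q_hat
        return loglik_terms(cohort, g, EffectModel(coding, b if len(b) > 1
                                                   else float(b[0])),
                            GenotypePrior(q), incidence)

    scores = np.empty((len(cohort), p))
    for j in range(p):
        e = np.zeros(p); e[j] = h
        scores[:, j] = (terms(theta + e) - terms(theta - e)) / (2 * h)
    fam = _family_sums(scores, cohort["family_id"].to_numpy())
    fam = np.atleast_2d(fam)
    B = fam.T @ fam

    A = np.empty((p, p))
    h2 = 1e-4
    f0 = terms(theta).sum()
    for j in range(p):
        for k in range(j, p):
            ej = np.zeros(p); ej[j] = h2
            ek = np.zeros(p); ek[k] = h2
            if j == k:
                val = (terms(theta + ej).sum() - 2 * f0
                       + terms(theta - ej).sum()) / h2 ** 2
            else:
                val = (terms(theta + ej + ek).sum() - terms(theta + ej - ek).sum()
                       - terms(theta - ej + ek).sum()
                       + terms(theta - ej - ek).sum()) / (4 * h2 ** 2)
            A[j, k] = A[k, j] = -val
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)
    return Ainv @ B @ Ainv


def estimate_hr(records: pd.DataFrame, genotype: np.ndarray,
                incidence: IncidenceModel, disease: str,
                coding: str = "per_allele",
                min_age: float = DEFAULT_MIN_AGE,
                prior: GenotypePrior | None = None,
                profile_freq: bool = False,
                er_subtype: str | None = None) -> AssociationResult:
    """Maximise the retrospective likelihood over the effect coefficients.

    The baseline is re-constrained at every trial beta (profile
    consistency).  By default the allele frequency is the plug-in sample
    estimate; with ``profile_freq`` it is profiled jointly with beta, which
    is preferable under strong ascertainment because the crude sample
    frequency is enriched for the risk allele.  Wald CIs use the
    family-clustered sandwich variance on the log-HR scale.
    """
    cohort, _ = build_cohort(records, disease, min_age, er_subtype)
    g = np.asarray(genotype)[cohort["row"].to_numpy()].astype(int)
    result = AssociationResult(disease=disease, coding=coding,
                               n_individuals=len(cohort),
                               n_families=cohort["family_id"].nunique())
    if len(cohort) == 0 or np.var(g) == 0:
        result.testable = False
        return result

    loglik = _profile_loglik_factory(cohort, g, incidence, coding, None)
    q0 = prior.allele_freq if prior is not None else g.mean() / 2.0
    converged = True

    if coding == "per_allele":
        if profile_freq:
            beta, q = 0.0, q0
            for _ in range(60):
                rb = optimize.minimize_scalar(
                    lambda b: -loglik(b, q), bounds=BETA_BOUNDS,
                    method="bounded", options={"xatol": BETA_XATOL})
                rq = optimize.minimize_scalar(
                    lambda qq: -loglik(rb.x, qq), bounds=(1e-4, 1 - 1e-4),
                    method="bounded", options={"xatol": 1e-8})
                delta = abs(rb.x - beta)
                beta, q = float(rb.x), float(rq.x)
                if delta < BETA_XATOL:
                    break
            else:
                converged = False
        else:
            q = q0
            rb = optimize.minimize_scalar(
                lambda b: -loglik(b, q), bounds=BETA_BOUNDS, method="bounded",
                options={"xatol": BETA_XATOL})
            beta = float(rb.x)
            converged = bool(rb.success)
        beta_hat = beta
    elif coding == "genotype":
        q = q0
        if profile_freq:
            def nll(th):
                return -loglik(th[:2], 1 / (1 + np.exp(-th[2])))
            x0 = np.array([0.0, 0.0, np.log(q0 / (1 - q0))])
        else:
            def nll(th):
                return -loglik(th, q)
            x0 = np.zeros(2)
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": BETA_XATOL, "fatol": 1e-9,
                                         "maxiter": 4000})
        converged = bool(res.success)
        if profile_freq:
            beta_hat = res.x[:2]
            q = float(1 / (1 + np.exp(-res.x[2])))
        else:
            beta_hat = res.x
    else:
        raise ValueError(f"unknown coding {coding!r}")

    cov = _sandwich(cohort, g, incidence, coding, beta_hat, q, profile_freq)
    nb = 1 if coding == "per_allele" else 2
    var_beta = np.diag(cov)[:nb]
    se = np.sqrt(var_beta)
    b = np.atleast_1d(np.asarray(beta_hat, float))
    lo, hi = np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
    if coding == "per_allele":
        result.beta_hat = float(b[0])
        result.var_beta = float(var_beta[0])
        result.hr = float(np.exp(b[0]))
        result.ci95 = (float(lo[0]), float(hi[0]))
    else:
        result.beta_hat = b
        result.var_beta = var_beta
        result.hr = np.exp(b)
        result.ci95 = (lo, hi)
    result.converged = converged
    if not converged:
        logger.warning("estimate_hr: optimisation did not converge")
    return result


# ---------------------------------------------------------------------------
# competing risks

def competing_loglik(cohort: pd.DataFrame, g: np.ndarray, beta_breast: float,
                     beta_ovarian: float, prior: GenotypePrior,
                     inc_breast: IncidenceModel,
                     inc_ovarian: IncidenceModel) -> float:
    """Joint retrospective log-likelihood with cause-specific hazards
    lam_d(t) exp(beta_d g), conditioning on the first-event phenotype."""
    bb = constrain_baseline(inc_breast, EffectModel("per_allele", beta_breast),
                            prior)
    bo = constrain_baseline(inc_ovarian, EffectModel("per_allele", beta_ovarian),
                            prior)
    entry = cohort["entry"].to_numpy(float)
    exit_ = cohort["exit"].to_numpy(float)
    db = cohort["affected_breast"].to_numpy(float)
    do = cohort["affected_ovarian"].to_numpy(float)
    dCb = bb.cum0(exit_) - bb.cum0(entry)
    dCo = bo.cum0(exit_) - bo.cum0(entry)
    with np.errstate(divide="ignore"):
        log_hb = np.log(bb.hazard0(exit_))
        log_ho = np.log(bo.hazard0(exit_))
    logP = (-np.outer(dCb, bb.multipliers) - np.outer(dCo, bo.multipliers)
            + db[:, None] * (log_hb[:, None] + np.log(bb.multipliers)[None, :])
            + do[:, None] * (log_ho[:, None] + np.log(bo.multipliers)[None, :]))
    logprior = np.log(prior.probs())
    num = logP[np.arange(len(cohort)), g] + logprior[g]
    den = logsumexp(logP + logprior[None, :], axis=1)
    return float((num - den).sum())


def competing_risks_fit(records: pd.DataFrame, genotype: np.ndarray,
                        inc_breast: IncidenceModel,
                        inc_ovarian: IncidenceModel,
                        min_age: float = DEFAULT_MIN_AGE,
                        prior: GenotypePrior | None = None,
                        fix_breast: float | None = None,
                        fix_ovarian: float | None = None,
                        profile_freq: bool = False) -> dict:
    """Simultaneous estimation of (beta_breast, beta_ovarian) under the
    cause-specific competing-risks retrospective likelihood.

    Either coefficient can be fixed (e.g. ``fix_ovarian=0`` reproduces the
    single-disease breast analysis when the data contain no ovarian
    events).  With ``profile_freq`` the allele frequency is profiled
    jointly with the two coefficients, which matters under ascertainment:
    enrichment of cases of either disease inflates the crude sample
    frequency and leaks into *both* cause-specific estimates.  Returns
    ``{"breast": AssociationResult, "ovarian": ...}``.
    """
    if inc_breast is None or inc_ovarian is None:
        raise ValueError("incidence models required for both diseases")
    cohort = build_competing_cohort(records, min_age)
    g = np.asarray(genotype)[cohort["row"].to_numpy()].astype(int)
    q0 = prior.allele_freq if prior is not None else g.mean() / 2.0

    free = [d for d, fx in (("breast", fix_breast), ("ovarian", fix_ovarian))
            if fx is None]
    if not free:
        raise ValueError("at least one coefficient must be free")
    n_eff = len(free)

    def unpack(x):
        x = np.atleast_1d(x)
        vals = {"breast": fix_breast, "ovarian": fix_ovarian}
        for name, v in zip(free, x):
            vals[name] = float(v)
        q = (1.0 / (1.0 + np.exp(-x[n_eff]))) if profile_freq else q0
        return vals["breast"], vals["ovarian"], q

    def nll(x):
        b_b, b_o, q = unpack(x)
        return -competing_loglik(cohort, g, b_b, b_o, GenotypePrior(q),
                                 inc_breast, inc_ovarian)

    x0 = np.zeros(n_eff + (1 if profile_freq else 0))
    if profile_freq:
        x0[n_eff] = np.log(q0 / (1.0 - q0))
    if len(x0) == 1:
        r = optimize.minimize_scalar(nll, bounds=BETA_BOUNDS, method="bounded",
                                     options={"xatol": BETA_XATOL})
        x_hat, converged = np.array([r.x]), bool(r.success)
    else:
        r = optimize.minimize(nll, x0, method="Nelder-Mead",
                              options={"xatol": BETA_XATOL, "fatol": 1e-9,
                                       "maxiter": 6000})
        x_hat, converged = r.x, bool(r.success)
    b_b, b_o, q_hat = unpack(x_hat)

    # family-clustered sandwich over the free parameters
    h = 1e-5

    def terms(x):
        bb_, bo_, q_ = unpack(x)
        pr = GenotypePrior(q_)
        bl_b = constrain_baseline(inc_breast, EffectModel("per_allele", bb_), pr)
        bl_o = constrain_baseline(inc_ovarian, EffectModel("per_allele", bo_), pr)
        entry = cohort["entry"].to_numpy(float)
        exit_ = cohort["exit"].to_numpy(float)
        db = cohort["affected_breast"].to_numpy(float)
        do = cohort["affected_ovarian"].to_numpy(float)
        logP = (-np.outer(bl_b.cum0(exit_) - bl_b.cum0(entry), bl_b.multipliers)
                - np.outer(bl_o.cum0(exit_) - bl_o.cum0(entry), bl_o.multipliers))
        with np.errstate(divide="ignore"):
            logP += db[:, None] * (np.log(bl_b.hazard0(exit_))[:, None]
                                   + np.log(bl_b.multipliers)[None, :])
            logP += do[:, None] * (np.log(bl_o.hazard0(exit_))[:, None]
                                   + np.log(bl_o.multipliers)[None, :])
        logprior = np.log(pr.probs())
        return (logP[np.arange(len(cohort)), g] + logprior[g]
                - logsumexp(logP + logprior[None, :], axis=1))

    p = len(x_hat)
    scores = np.empty((len(cohort), p))
    for j in range(p):
        e = np.zeros(p); e[j] = h
        scores[:, j] = (terms(x_hat + e) - terms(x_hat - e)) / (2 * h)
    fam = np.atleast_2d(_family_sums(scores, cohort["family_id"].to_numpy()))
    B = fam.T @ fam
    h2 = 1e-4
    A = np.empty((p, p))
    f0 = terms(x_hat).sum()
    for j in range(p):
        for k in range(j, p):
            ej = np.zeros(p); ej[j] = h2
            ek = np.zeros(p); ek[k] = h2
            if j == k:
                val = (terms(x_hat + ej).sum() - 2 * f0
                       + terms(x_hat - ej).sum()) / h2 ** 2
            else:
                val = (terms(x_hat + ej + ek).sum()
                       - terms(x_hat + ej - ek).sum()
                       - terms(x_hat - ej + ek).sum()
                       + terms(x_hat - ej - ek).sum()) / (4 * h2 ** 2)
            A[j, k] = A[k, j] = -val
    cov = np.linalg.inv(A) @ B @ np.linalg.inv(A)

    out = {}
    betas = {"breast": b_b, "ovarian": b_o}
    for d in ("breast", "ovarian"):
        res = AssociationResult(disease=d, n_individuals=len(cohort),
                                n_families=cohort["family_id"].nunique(),
                                converged=converged)
        res.beta_hat = betas[d]
        res.hr = float(np.exp(betas[d]))
        if d in free:
            j = free.index(d)
            res.var_beta = float(cov[j, j])
            se = np.sqrt(cov[j, j])
            res.ci95 = (float(np.exp(betas[d] - 1.96 * se)),
                        float(np.exp(betas[d] + 1.96 * se)))
            # 1-df Wald chi-square for the free coefficient
            res.chi2 = betas[d] ** 2 / cov[j, j] if cov[j, j] > 0 else np.nan
            res.p = float(stats.chi2.sf(res.chi2, 1)) if cov[j, j] > 0 else np.nan
        else:
            res.label = "fixed"
        out[d] = res
    return out


# ---------------------------------------------------------------------------
# stratified analyses, heterogeneity, effect differences

def stratified_test(records: pd.DataFrame, genotype: np.ndarray,
                    incidence: IncidenceModel, disease: str,
                    stratum_field: str = "stratum",
                    min_age: float = DEFAULT_MIN_AGE,
                    estimate: bool = True) -> tuple[dict, AssociationResult]:
    """Per-stratum association results plus a pooled analysis in which the
    genotype prior and constrained baseline are stratum-specific but the
    log-HR is shared."""
    genotype = np.asarray(genotype)
    strata = records[stratum_field].fillna("").to_numpy(str)
    per_stratum: dict[str, AssociationResult] = {}
    pieces = []
    for s in sorted(set(strata)):
        mask = strata == s
        sub = records[mask].reset_index(drop=True)
        gsub = genotype[mask]
        cohort, _ = build_cohort(sub, disease, min_age)
        if cohort["affected"].sum() == 0:
            logger.warning("stratum %s excluded: no affected individuals", s)
            continue
        res = (estimate_hr(sub, gsub, incidence, disease, min_age=min_age)
               if estimate else
               score_test(sub, gsub, incidence, disease, min_age=min_age))
        res.label = s
        per_stratum[s] = res
        pieces.append((cohort, gsub[cohort["row"].to_numpy()].astype(int)))

    if not pieces:
        raise ValueError("no usable strata")

    def pooled_loglik(beta):
        total = 0.0
        for cohort, g in pieces:
            q = g.mean() / 2.0
            total += retrospective_loglik(cohort, g,
                                          EffectModel("per_allele", beta),
                                          GenotypePrior(q), incidence)
        return total

    r = optimize.minimize_scalar(lambda b: -pooled_loglik(b),
                                 bounds=BETA_BOUNDS, method="bounded",
                                 options={"xatol": BETA_XATOL})
    beta = float(r.x)
    # pooled sandwich: per-stratum scores, family clustering within strata
    h = 1e-5
    A = 0.0
    B = 0.0
    for cohort, g in pieces:
        q = g.mean() / 2.0
        pr = GenotypePrior(q)

        def t(b):
            return loglik_terms(cohort, g, EffectModel("per_allele", b),
                                pr, incidence)
        s_i = (t(beta + h) - t(beta - h)) / (2 * h)
        fam = _family_sums(s_i, cohort["family_id"].to_numpy())
        B += float((fam ** 2).sum())
        h2 = 1e-4
        A += -(t(beta + h2).sum() - 2 * t(beta).sum()
               + t(beta - h2).sum()) / h2 ** 2
    var = B / A ** 2 if A > 0 else np.nan
    pooled = AssociationResult(
        disease=disease, coding="per_allele",
        n_individuals=sum(len(c) for c, _ in pieces),
        n_families=sum(c["family_id"].nunique() for c, _ in pieces),
        beta_hat=beta, var_beta=var, hr=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * np.sqrt(var))),
              float(np.exp(beta + 1.96 * np.sqrt(var)))),
        converged=bool(r.success), label="pooled")
    return per_stratum, pooled


def effect_difference_test(result_a: AssociationResult,
                           result_b: AssociationResult) -> float:
    """Wald test of equality of two log-HRs estimated on disjoint case
    groups: z = (betaA - betaB) / sqrt(varA + varB)."""
    for r in (result_a, result_b):
        if not np.isfinite(r.var_beta):
            raise ValueError("both results need finite variances")
    z = (result_a.beta_hat - result_b.beta_hat) / np.sqrt(
        result_a.var_beta + result_b.var_beta)
    return float(2.0 * stats.norm.sf(abs(z)))


def heterogeneity_test(results) -> tuple[float, float]:
    """Cochran's Q across strata: Q = sum w_k (beta_k - beta_w)^2 with
    w_k = 1/var_k, referred to chi-square with K - 1 df."""
    usable = [r for r in results
              if np.isfinite(r.beta_hat) and np.isfinite(r.var_beta)
              and r.var_beta > 0]
    if len(usable) < 2:
        raise ValueError("heterogeneity test needs >= 2 usable strata")
    beta = np.array([r.beta_hat for r in usable])
    w = np.array([1.0 / r.var_beta for r in usable])
    beta_w = (w * beta).sum() / w.sum()
    Q = float((w * (beta - beta_w) ** 2).sum())
    p = float(stats.chi2.sf(Q, df=len(usable) - 1))
    return Q, p


def er_subtype_analysis(records: pd.DataFrame, genotype: np.ndarray,
                        incidence: IncidenceModel,
                        min_age: float = DEFAULT_MIN_AGE) -> dict:
    """ER-positive and ER-negative breast cancer analyses (cases of the
    other or unknown subtype censored at diagnosis) plus the Wald p for the
    difference of the two per-allele effects."""
    out = {}
    for subtype in ("pos", "neg"):
        out[subtype] = estimate_hr(records, genotype, incidence, "breast",
                                   min_age=min_age, er_subtype=subtype)
    out["p_difference"] = effect_difference_test(out["pos"], out["neg"])
    return out
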