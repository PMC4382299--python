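"""Cox proportional-hazards engine, pairwise SNP x SNP interaction scans,
FDR control and expression-interaction survival analysis.

The Cox fits (partial likelihood, Efron tie handling, left truncation,
family-clustered robust variance) are delegated to lifelines behind
:func:`cox_fit`; everything layered on top - the interaction scan with its
genotype codings, the step-up FDR with a declared family size, tertile
categorisation and the Kaplan-Meier outputs - is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

logger = logging.getLogger("carriermod.interactions")

TERTILE_LABELS = ("low", "medium", "high")


@dataclass
class InteractionResult:
    """Main-effect and interaction hazard ratios from one Cox model."""
    term_names: list
    hr: np.ndarray
    p: np.ndarray
    interaction_hr: float
    p_interaction: float
    empty_groups: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.hr <= 0):
            raise ValueError("hazard ratios must be positive")


class NoEventsError(ValueError):
    """Raised when a survival table contains no observed events."""


def _efron_nll_grad(beta, X, exit_, event, entry=None):
    """Efron-tie negative log partial likelihood and gradient.

    Used only to polish the lifelines estimate to a tighter optimum than
    its relative-log-likelihood stopping rule reaches.  Supports a common
    entry age (risk sets unchanged) or fully general entries.
    """
    beta = np.atleast_1d(beta)
    eta = X @ beta
    w = np.exp(eta)
    ev = np.flatnonzero(event == 1)
    if entry is None:
        # common entry: risk sets are suffix sets of the exit order, and
        # only tied event-time groups need Efron's inner loop
        order = np.argsort(exit_, kind="stable")
        t_sorted = exit_[order]
        w_suffix = np.cumsum(w[order][::-1])[::-1]
        wx_suffix = np.cumsum((w[order, None] * X[order])[::-1], axis=0)[::-1]
        times, inverse, counts = np.unique(exit_[ev], return_inverse=True,
                                           return_counts=True)
        pos = np.searchsorted(t_sorted, times, side="left")
        S_r, G_r = w_suffix[pos], wx_suffix[pos]
        S_d = np.bincount(inverse, weights=w[ev])
        G_d = np.column_stack([np.bincount(inverse, weights=w[ev] * X[ev, j])
                               for j in range(X.shape[1])])
        nll = float(-eta[ev].sum())
        grad = -X[ev].sum(axis=0)
        single = counts == 1
        nll += float(np.log(S_r[single]).sum())
        grad += (G_r[single] / S_r[single, None]).sum(axis=0)
        for k in np.flatnonzero(~single):
            d = counts[k]
            for el in range(d):
                denom = S_r[k] - (el / d) * S_d[k]
                nll += np.log(denom)
                grad += (G_r[k] - (el / d) * G_d[k]) / denom
        return nll, grad
    nll, grad = 0.0, np.zeros_like(beta)
    for t in np.unique(exit_[ev]):
        risk_idx = np.flatnonzero((entry < t) & (exit_ >= t))
        dead = risk_idx[(exit_[risk_idx] == t) & (event[risk_idx] == 1)]
        d = len(dead)
        s_r, g_r = w[risk_idx].sum(), (w[risk_idx][:, None]
                                       * X[risk_idx]).sum(axis=0)
        s_d, g_d = w[dead].sum(), (w[dead][:, None] * X[dead]).sum(axis=0)
        nll -= eta[dead].sum()
        grad -= X[dead].sum(axis=0)
        for el in range(d):
            denom = s_r - (el / d) * s_d
            nll += np.log(denom)
            grad += (g_r - (el / d) * g_d) / denom
    return nll, grad


def _polish_coefs(beta0, table, covariates, duration_col, event_col,
                  entry_col):
    from scipy import optimize

    X = table[covariates].to_numpy(float)
    exit_ = table[duration_col].to_numpy(float)
    event = table[event_col].to_numpy(int)
    entry = table[entry_col].to_numpy(float) if entry_col is not None else None
    res = optimize.minimize(
        lambda b: _efron_nll_grad(b, X, exit_, event, entry),
        np.asarray(beta0, float), jac=True, method="BFGS",
        options={"gtol": 1e-10, "maxiter": 200})
    return res.x if np.isfinite(res.fun) else np.asarray(beta0, float)


def cox_fit(table: pd.DataFrame, covariates,
            duration_col: str = "exit", event_col: str = "event",
            entry_col: str | None = "entry",
            cluster_col: str | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, left truncation honoured
    via the entry column, optional cluster-robust variance).

    Constant covariates are dropped with a warning; a table with no events
    raises :class:`NoEventsError`; non-convergence propagates as
    lifelines' ConvergenceError (never silently swallowed).

    Returns one row per term: coef, se, hr, z, p.
    """
    covariates = list(covariates)
    if table[event_col].sum() == 0:
        raise NoEventsError("no observed events in the survival table")
    usable = []
    for c in covariates:
        if np.var(table[c].to_numpy(float)) == 0:
            logger.warning("constant covariate %s dropped", c)
        else:
            usable.append(c)
    if not usable:
        raise ValueError("no non-constant covariates to fit")
    # a common entry age before every exit leaves risk sets unchanged, and
    # lifelines' truncation-free path is much faster
    if entry_col is not None:
        e = table[entry_col].to_numpy(float)
        if np.all(e == e[0]) and e[0] <= table[duration_col].min():
            entry_col = None
    cols = usable + [duration_col, event_col]
    if entry_col is not None:
        cols.append(entry_col)
    if cluster_col is not None:
        cols.append(cluster_col)
    cph = CoxPHFitter()
    cph.fit(table[cols], duration_col=duration_col, event_col=event_col,
            entry_col=entry_col, cluster_col=cluster_col,
            robust=cluster_col is not None, show_progress=False,
            fit_options={"precision": 1e-9, "max_steps": 500})
    s = cph.summary
    # polish the point estimate beyond lifelines' relative-log-likelihood
    # stopping rule; the standard errors are insensitive at this scale
    coef = _polish_coefs(s["coef"].to_numpy()[: len(usable)],
                         table, usable, duration_col, event_col, entry_col)
    se = s["se(coef)"].to_numpy()
    z = coef / se
    return pd.DataFrame({
        "term": s.index,
        "coef": coef,
        "se": se,
        "hr": np.exp(coef),
        "z": z,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP x SNP interaction scan

_CATEGORY_CODES = {
    "het": lambda g: (g == 1).astype(float),
    "hom": lambda g: (g == 2).astype(float),
    "carrier": lambda g: (g >= 1).astype(float),
}


def _survival_table(records, disease, min_age):
    from .likelihood import DEFAULT_MIN_AGE, build_cohort

    cohort, _ = build_cohort(records, disease,
                             DEFAULT_MIN_AGE if min_age is None else min_age)
    return pd.DataFrame({
        "entry": cohort["entry"].to_numpy(),
        "exit": cohort["exit"].to_numpy(),
        "event": cohort["affected"].to_numpy(),
        "family_id": cohort["family_id"].to_numpy(),
    }), cohort["row"].to_numpy()


def gxg_pair(records: pd.DataFrame, g_a: np.ndarray, g_b: np.ndarray,
             disease: str = "breast", coding: str = "dose",
             categories: tuple = ("het", "het"), min_age=None,
             cluster: bool = True) -> InteractionResult:
    """Cox model with both main effects and the product term for one SNP
    pair.  ``coding="dose"`` uses per-allele doses (1-df product term);
    ``coding="category"`` uses genotype-category indicators (e.g. het x
    homozygote cells)."""
    table, rows = _survival_table(records, disease, min_age)
    if coding == "dose":
        xa, xb = np.asarray(g_a, float)[rows], np.asarray(g_b, float)[rows]
    elif coding == "category":
        xa = _CATEGORY_CODES[categories[0]](np.asarray(g_a)[rows])
        xb = _CATEGORY_CODES[categories[1]](np.asarray(g_b)[rows])
    else:
        raise ValueError(f"unknown coding {coding!r}")
    if np.array_equal(np.asarray(g_a), np.asarray(g_b)):
        raise ValueError("cannot scan a SNP against itself "
                         "(perfect collinearity)")
    table["a"] = xa
    table["b"] = xb
    table["ab"] = xa * xb
    res = cox_fit(table, ["a", "b", "ab"],
                  cluster_col="family_id" if cluster else None)
    row = res.set_index("term")
    return InteractionResult(
        term_names=list(res["term"]),
        hr=res["hr"].to_numpy(), p=res["p"].to_numpy(),
        interaction_hr=float(row.loc["ab", "hr"]),
        p_interaction=float(row.loc["ab", "p"]))


def gxg_scan(records: pd.DataFrame, genotypes, index_snps, partner_snps,
             disease: str = "breast", coding: str = "dose",
             categories: tuple = ("het", "het"),
             min_double_carriers: int = 10, min_age=None,
             cluster: bool = True, fdr_m: int | None = None) -> pd.DataFrame:
    """All (index, partner) pairwise interaction Cox fits.

    Pairs with fewer than ``min_double_carriers`` individuals carrying
    both minor alleles are skipped with a log entry; a per-scan BH-FDR
    column is appended over the tested pairs.
    """
    rows = []
    for snp_a in index_snps:
        for snp_b in partner_snps:
            if snp_a == snp_b:
                raise ValueError(
                    f"pair ({snp_a}, {snp_b}): cannot scan a SNP against "
                    "itself (perfect collinearity)")
            ga, gb = genotypes.column(snp_a), genotypes.column(snp_b)
            n_double = int(((ga > 0) & (gb > 0)).sum())
            if n_double < min_double_carriers:
                logger.warning("pair (%s, %s) skipped: %d double carriers "
                               "< %d", snp_a, snp_b, n_double,
                               min_double_carriers)
                continue
            r = gxg_pair(records, ga, gb, disease, coding, categories,
                         min_age, cluster)
            idx = {t: k for k, t in enumerate(r.term_names)}
            rows.append({
                "snp_a": snp_a, "snp_b": snp_b, "disease": disease,
                "coding": coding, "n_double_carriers": n_double,
                "hr_a": r.hr[idx["a"]], "p_a": r.p[idx["a"]],
                "hr_b": r.hr[idx["b"]], "p_b": r.p[idx["b"]],
                "interaction_hr": r.interaction_hr,
                "p_interaction": r.p_interaction,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p_interaction", kind="stable").reset_index(drop=True)
        out["fdr"] = bh_fdr(out["p_interaction"].to_numpy(), m=fdr_m)
    else:
        out = pd.DataFrame(columns=["snp_a", "snp_b", "disease", "coding",
                                    "n_double_carriers", "hr_a", "p_a",
                                    "hr_b", "p_b", "interaction_hr",
                                    "p_interaction", "fdr"])
    return out


# ---------------------------------------------------------------------------
# FDR

def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` declares the size of the test family and may exceed the number
    of p-values supplied (testing a subset of a declared family of, say,
    41 SNPs); it defaults to ``len(p_values)``.  Output is monotone in the
    input ranks, capped at 1, and idempotent when ``m == len(p_values)``.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def benjamini_yekutieli(p_values, m: int | None = None) -> np.ndarray:
    """BY variant (arbitrary-dependence correction factor)."""
    p = np.asarray(p_values, float)
    m_eff = int(m) if m is not None else p.size
    c = np.sum(1.0 / np.arange(1, m_eff + 1))
    return np.minimum(bh_fdr(p, m=m_eff) * c, 1.0)


# ---------------------------------------------------------------------------
# expression tertiles, KM, interaction survival

def tertile_categorize(values) -> np.ndarray:
    """Categorise values as low/medium/high at the empirical 1/3 and 2/3
    quantiles; values tied with a boundary go to the lower category, so
    group sizes differ only by the number of boundary ties.  Rank-based:
    invariant under monotone transformation."""
    v = np.asarray(values, float)
    if v.size < 3 or np.unique(v[np.isfinite(v)]).size < 3:
        raise ValueError("tertile categorisation needs >= 3 distinct "
                         "finite values")
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    out = np.where(v <= q1, TERTILE_LABELS[0],
                   np.where(v <= q2, TERTILE_LABELS[1], TERTILE_LABELS[2]))
    return out.astype(object)


def km_estimate(times, events, groups=None) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimates per group.

    Returns long-format step-function data (group, time, survival,
    at_risk) including the time-0 row where survival is 1; curves are
    monotone non-increasing and jump exactly at event times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = (np.asarray(groups) if groups is not None
              else np.full(times.shape, "all"))
    out = []
    for grp in pd.unique(groups):
        mask = groups == grp
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        for t, s, n in zip(sf.index, sf.iloc[:, 0], at_risk):
            out.append({"group": grp, "time": float(t), "survival": float(s),
                        "at_risk": int(n)})
    return pd.DataFrame(out)


def expression_interaction_survival(table: pd.DataFrame, gene_a: str,
                                    gene_b: str, time_col: str = "time",
                                    event_col: str = "event"):
    """Continuous Cox interaction between two expression profiles, plus
    tertile-stratified Kaplan-Meier output.

    Expression values are standardised (zero mean, unit variance) before
    fitting, making the interaction HR invariant to probe scale.  Returns
    ``(InteractionResult, km_data)``; tertile-combination groups with no
    members are reported on the result, not silently dropped.
    """
    for col in (gene_a, gene_b, time_col, event_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    xa = table[gene_a].to_numpy(float)
    xb = table[gene_b].to_numpy(float)
    za = (xa - xa.mean()) / xa.std()
    zb = (xb - xb.mean()) / xb.std()
    surv = pd.DataFrame({
        "exit": table[time_col].to_numpy(float),
        "event": table[event_col].to_numpy(int),
        "a": za, "b": zb, "ab": za * zb,
    })
    res = cox_fit(surv, ["a", "b", "ab"], entry_col=None)
    row = res.set_index("term")
    ta = tertile_categorize(xa)
    tb = tertile_categorize(xb)
    labels = np.array([f"{gene_a}_{u}|{gene_b}_{v}" for u, v in zip(ta, tb)],
                      dtype=object)
    empty = [f"{gene_a}_{u}|{gene_b}_{v}"
             for u in TERTILE_LABELS for v in TERTILE_LABELS
             if not np.any(labels == f"{gene_a}_{u}|{gene_b}_{v}")]
    km = km_estimate(surv["exit"], surv["event"], labels)
    result = InteractionResult(
        term_names=list(res["term"]),
        hr=res["hr"].to_numpy(), p=res["p"].to_numpy(),
        interaction_hr=float(row.loc["ab", "hr"]),
        p_interaction=float(row.loc["ab", "p"]),
        empty_groups=empty)
    return result, km
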