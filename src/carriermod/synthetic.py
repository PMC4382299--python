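"""Synthetic carrier-family cohorts.

Generates data with the statistical structure the carrier analyses assume:

* founder haplotypes drawn i.i.d. from a supplied frequency vector (HWE,
  with LD between SNPs induced by the haplotype structure),
* shallow families (singletons, sib-pairs, mother-daughter pairs) with
  Mendelian transmission, inducing within-family genotype correlation,
* two competing cancers (breast, ovarian) with genotype-dependent
  proportional cause-specific hazards on a piecewise-constant age grid,
* censoring by prophylactic mastectomy / oophorectomy and end of follow-up,
* family-level affected-enriched ascertainment emulating recruitment
  through cancer genetics clinics.

All randomness flows through named streams keyed on ``config.seed`` so a
fixed seed gives byte-identical output and individual components can be
varied in isolation.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .incidence import IncidenceModel, default_incidence

logger = logging.getLogger("carriermod.synthetic")

PHENOTYPE_COLUMNS = [
    "individual_id", "family_id", "gene", "stratum",
    "age_breast", "age_ovarian", "age_mastectomy", "age_oophorectomy",
    "age_last_followup", "er_status", "mutation_class",
]

FAMILY_TEMPLATES = ("singleton", "sib_pair", "mother_daughter")


@dataclass(frozen=True)
class CensorModel:
    """Ages/rates of the non-disease exits from follow-up.

    Probabilities are lifetime uptake probabilities; ages are drawn
    uniformly on the given ranges, independently of genotype.
    """
    p_mastectomy: float = 0.05
    mastectomy_ages: tuple = (30.0, 60.0)
    p_oophorectomy: float = 0.10
    oophorectomy_ages: tuple = (35.0, 60.0)
    followup_ages: tuple = (20.0, 80.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative counterpart of the study design (female carriers >= 18 y)."""

    n_families: int = 500
    family_structure: dict = field(default_factory=lambda: {
        "singleton": 0.4, "sib_pair": 0.4, "mother_daughter": 0.2})
    haplotypes: tuple = ("00", "01", "10", "11")
    haplotype_freqs: tuple = (0.4, 0.3, 0.2, 0.1)
    true_log_hr_breast: tuple = (0.0, 0.0)
    true_log_hr_ovarian: tuple = (0.0, 0.0)
    gene: str = "BRCA1"
    incidence_breast: IncidenceModel | None = None
    incidence_ovarian: IncidenceModel | None = None
    censor_model: CensorModel = field(default_factory=CensorModel)
    # family-level retention probabilities; None disables ascertainment
    ascertainment: dict | None = None
    # SD of the shared family-level log-normal frailty multiplying both
    # cancer hazards (residual familial aggregation: shared modifier loci
    # and environment).  0 disables it.
    frailty_sd: float = 0.0
    n_strata: int = 1
    er_neg_fraction: float = 0.7
    er_unknown_fraction: float = 0.1
    class1_fraction: float = 0.7
    min_age: float = 18.0
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.haplotypes[0])

    def incidence(self, disease: str) -> IncidenceModel:
        model = {"breast": self.incidence_breast,
                 "ovarian": self.incidence_ovarian}[disease]
        return model if model is not None else default_incidence(self.gene, disease)

    def validate(self) -> None:
        freqs = np.asarray(self.haplotype_freqs, float)
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype_freqs must sum to 1 within 1e-12")
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ValueError("haplotype_freqs must lie in [0,1]")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError("all haplotypes must have equal length")
        if len(self.haplotype_freqs) != len(self.haplotypes):
            raise ValueError("haplotype_freqs length must match haplotypes")
        if any(set(h) - {"0", "1"} for h in self.haplotypes):
            raise ValueError("haplotypes must be strings over {0,1}")
        for name, beta in (("true_log_hr_breast", self.true_log_hr_breast),
                           ("true_log_hr_ovarian", self.true_log_hr_ovarian)):
            if len(beta) != self.n_snps:
                raise ValueError(f"{name} must have one entry per SNP")
            if not np.all(np.isfinite(beta)):
                raise ValueError(f"{name} must be finite")
        total = sum(self.family_structure.get(t, 0.0) for t in FAMILY_TEMPLATES)
        if total <= 0 or set(self.family_structure) - set(FAMILY_TEMPLATES):
            raise ValueError(f"family_structure keys must be in {FAMILY_TEMPLATES}")
        if self.ascertainment is not None:
            keys = set(self.ascertainment)
            if keys == {"affected", "unaffected"}:
                pass
            elif keys == {"0", "1", "2"}:
                pass
            else:
                raise ValueError("ascertainment keys must be "
                                 "{'affected','unaffected'} or {'0','1','2'}")
            if any(not 0.0 <= p <= 1.0 for p in self.ascertainment.values()):
                raise ValueError("retention probabilities must lie in [0,1]")
        if np.count_nonzero(freqs) == 1:
            logger.warning("degenerate haplotype distribution: one haplotype "
                           "carries all mass; every genotype will be identical")


@dataclass
class GenotypeMatrix:
    """Hard-call genotype doses (count of the '1' allele per SNP)."""

    individual_ids: np.ndarray
    family_ids: np.ndarray
    dose: np.ndarray          # (n, S) int8 in {0,1,2}
    snp_ids: list

    def __post_init__(self):
        if not np.isin(self.dose, (0, 1, 2)).all():
            raise ValueError("doses must lie in {0,1,2}")

    @property
    def n(self) -> int:
        return self.dose.shape[0]

    @property
    def allele1_freq(self) -> np.ndarray:
        return self.dose.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.allele1_freq
        return np.minimum(f, 1.0 - f)

    def subset(self, individual_ids) -> "GenotypeMatrix":
        order = {iid: k for k, iid in enumerate(self.individual_ids)}
        idx = np.array([order[i] for i in individual_ids], dtype=int)
        return GenotypeMatrix(self.individual_ids[idx], self.family_ids[idx],
                              self.dose[idx], list(self.snp_ids))

    def column(self, snp_id) -> np.ndarray:
        return self.dose[:, self.snp_ids.index(snp_id)]


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(config: SimulationConfig,
                       batch: int = 0) -> GenotypeMatrix:
    """Draw family genotypes: founders i.i.d. from the haplotype frequencies,
    offspring by Mendelian (haplotype-level) transmission.

    ``batch`` offsets the random streams so independent cohorts can be drawn
    from one config (used when topping up after ascertainment).
    """
    config.validate()
    rng = stream(config.seed, f"genotypes/{batch}")
    haps = np.array([[int(c) for c in h] for h in config.haplotypes], dtype=np.int8)
    freqs = np.asarray(config.haplotype_freqs, float)

    templates = [t for t in FAMILY_TEMPLATES if config.family_structure.get(t, 0) > 0]
    weights = np.array([config.family_structure[t] for t in templates], float)
    weights /= weights.sum()
    nf = config.n_families
    fam_types = rng.choice(len(templates), size=nf, p=weights)
    sizes = np.where(fam_types == templates.index("singleton"), 1, 2) \
        if "singleton" in templates else np.full(nf, 2)
    n_ind = int(sizes.sum())

    # founder haplotypes are drawn i.i.d.; transmissions are fair coin flips
    hap_a = np.empty(n_ind, dtype=int)
    hap_b = np.empty(n_ind, dtype=int)
    starts = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    for t_idx, template in enumerate(templates):
        fmask = fam_types == t_idx
        k = int(fmask.sum())
        if k == 0:
            continue
        pos = starts[fmask]
        if template == "singleton":
            draws = rng.choice(len(haps), size=(k, 2), p=freqs)
            hap_a[pos], hap_b[pos] = draws[:, 0], draws[:, 1]
        elif template == "sib_pair":
            # latent parental haplotypes; only the sibs enter the cohort
            parents = rng.choice(len(haps), size=(k, 4), p=freqs)
            pick = rng.integers(2, size=(k, 4))
            for c in (0, 1):
                hap_a[pos + c] = parents[np.arange(k), pick[:, 2 * c]]
                hap_b[pos + c] = parents[np.arange(k), 2 + pick[:, 2 * c + 1]]
        else:  # mother_daughter
            mother = rng.choice(len(haps), size=(k, 2), p=freqs)
            hap_a[pos], hap_b[pos] = mother[:, 0], mother[:, 1]
            transmit = rng.integers(2, size=k)
            hap_a[pos + 1] = mother[np.arange(k), transmit]
            hap_b[pos + 1] = rng.choice(len(haps), size=k, p=freqs)

    fam_of_ind = np.repeat(np.arange(nf), sizes)
    member = np.arange(n_ind) - np.repeat(starts, sizes) + 1
    fams = np.array([f"F{batch}_{f}" for f in fam_of_ind])
    ids = np.array([f"F{batch}_{f}_{m}" for f, m in zip(fam_of_ind, member)])
    dose = (haps[hap_a] + haps[hap_b]).astype(np.int8)
    return GenotypeMatrix(ids, fams, dose,
                          [f"snp{j + 1}" for j in range(config.n_snps)])


# ---------------------------------------------------------------------------
# phenotypes

def _in_sample_baseline(incidence: IncidenceModel, risk: np.ndarray,
                        min_age: float) -> np.ndarray:
    """Baseline hazard per interval such that the *sample* mixture of
    genotype-specific hazards reproduces the carrier incidence.

    Interval by interval: lam0_k = lam_k * sum(S_i) / sum(S_i * exp(r_i)),
    where S_i is individual i's survivor accumulated over earlier intervals.
    """
    edges = incidence.edges
    widths = np.diff(edges)
    mult = np.exp(risk)
    lam0 = np.zeros_like(incidence.rates)
    logS = np.zeros_like(risk)
    start = np.searchsorted(edges, min_age, side="right") - 1
    for k in range(max(start, 0), len(lam0)):
        S = np.exp(logS)
        denom = float(S @ mult)
        lam0[k] = incidence.rates[k] * S.sum() / denom if denom > 0 else 0.0
        logS = logS - lam0[k] * mult * widths[k]
    return lam0


def _invert_hazard(lam0: np.ndarray, edges: np.ndarray, mult: np.ndarray,
                   min_age: float, rng: np.random.Generator) -> np.ndarray:
    """Sample event ages by inversion of the piecewise-constant cumulative
    hazard, exact (no discretisation); returns +inf when no event occurs
    before the end of the grid."""
    cum = np.concatenate([[0.0], np.cumsum(lam0 * np.diff(edges))])
    e = rng.exponential(size=mult.shape[0])
    start = np.interp(min_age, edges, cum)
    target = start + e / mult
    # locate interval; side='left' so targets landing exactly on an edge of a
    # zero-rate interval resolve to the preceding positive-rate interval
    idx = np.clip(np.searchsorted(cum, target, side="left") - 1, 0, len(lam0) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ages = edges[idx] + (target - cum[idx]) / lam0[idx]
    ages = np.where(target >= cum[-1], np.inf, ages)
    return ages


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig,
                        batch: int = 0) -> pd.DataFrame:
    """Simulate competing-cancer histories and censoring for each carrier.

    Latent breast and ovarian onset ages are drawn independently from their
    cause-specific hazards ``lam0_d(t) * exp(beta_d . g)`` starting at
    ``min_age``; the observed record keeps every age that would have been
    observable (events before surgery/follow-up truncation), so both the
    breast-analysis and ovarian-analysis phenotypes can be rebuilt downstream.
    """
    config.validate()
    n = genotypes.n
    cm = config.censor_model
    rng_ev = stream(config.seed, f"events/{batch}")
    rng_cn = stream(config.seed, f"censoring/{batch}")
    rng_an = stream(config.seed, f"annotations/{batch}")

    _, fam_idx = np.unique(genotypes.family_ids, return_inverse=True)
    if config.frailty_sd > 0:
        rng_fr = stream(config.seed, f"frailty/{batch}")
        frailty = config.frailty_sd * rng_fr.standard_normal(fam_idx.max() + 1)
        frailty = frailty[fam_idx]
    else:
        frailty = np.zeros(n)

    latent = {}
    for disease, betas in (("breast", config.true_log_hr_breast),
                           ("ovarian", config.true_log_hr_ovarian)):
        beta = np.asarray(betas, float)
        if np.any(~np.isfinite(beta)):
            raise ValueError("hazard log-HRs must be finite")
        inc = config.incidence(disease)
        risk = genotypes.dose @ beta + frailty
        lam0 = _in_sample_baseline(inc, risk, config.min_age)
        latent[disease] = _invert_hazard(lam0, inc.edges, np.exp(risk),
                                         config.min_age, rng_ev)

    followup = rng_cn.uniform(*cm.followup_ages, size=n)
    followup = np.maximum(followup, config.min_age + 0.5)
    mast = np.where(rng_cn.random(n) < cm.p_mastectomy,
                    rng_cn.uniform(*cm.mastectomy_ages, size=n), np.inf)
    ooph = np.where(rng_cn.random(n) < cm.p_oophorectomy,
                    rng_cn.uniform(*cm.oophorectomy_ages, size=n), np.inf)
    mast = np.where(mast < followup, mast, np.inf)
    ooph = np.where(ooph < followup, ooph, np.inf)

    breast = latent["breast"]
    ovarian = latent["ovarian"]
    breast_obs = np.where(breast < np.minimum(mast, followup), breast, np.inf)
    ovarian_obs = np.where(ovarian < np.minimum(ooph, followup), ovarian, np.inf)

    # family-level annotations
    fam_ids, fam_index = np.unique(genotypes.family_ids, return_inverse=True)
    strata = rng_an.integers(config.n_strata, size=len(fam_ids))
    mclass = rng_an.random(len(fam_ids)) < config.class1_fraction

    er = np.full(n, "", dtype=object)
    has_bc = np.isfinite(breast_obs)
    u = rng_an.random(n)
    er[has_bc] = np.where(u[has_bc] < config.er_unknown_fraction, "unknown",
                          np.where(rng_an.random(n)[has_bc] < config.er_neg_fraction,
                                   "neg", "pos"))

    def col(x):
        return [round(float(v), 4) if np.isfinite(v) else None for v in x]

    df = pd.DataFrame({
        "individual_id": genotypes.individual_ids,
        "family_id": genotypes.family_ids,
        "gene": config.gene,
        "stratum": [f"S{strata[i]}" for i in fam_index],
        "age_breast": col(breast_obs),
        "age_ovarian": col(ovarian_obs),
        "age_mastectomy": col(mast),
        "age_oophorectomy": col(ooph),
        "age_last_followup": col(followup),
        "er_status": er,
        "mutation_class": ([("1" if mclass[i] else "2") for i in fam_index]
                           if config.gene == "BRCA1" else ""),
    })
    return df


def family_affected(records: pd.DataFrame) -> pd.Series:
    """Per-family count of members with a recorded cancer diagnosis."""
    affected = records["age_breast"].notna() | records["age_ovarian"].notna()
    return affected.groupby(records["family_id"]).sum()


def apply_ascertainment(records: pd.DataFrame, config: SimulationConfig,
                        batch: int = 0) -> pd.DataFrame:
    """Retain families independently with probability depending on the
    family's affection status (clinic-based recruitment).

    Two retention models are supported: ``{"affected": p1, "unaffected":
    p0}`` keyed on whether any member is affected, and ``{"0": p0, "1":
    p1, "2": p2}`` keyed on the number of affected members ("2" meaning
    two or more), which emulates the preferential referral of multiplex
    families and induces *positive* within-family phenotype correlation in
    the retained sample.
    """
    if config.ascertainment is None:
        return records
    config.validate()
    rng = stream(config.seed, f"ascertainment/{batch}")
    counts = family_affected(records)
    asc = config.ascertainment
    if "affected" in asc:
        p = np.where(counts.to_numpy() > 0, asc["affected"], asc["unaffected"])
    else:
        key = np.minimum(counts.to_numpy(int), 2).astype(str)
        p = np.array([asc[k] for k in key])
    keep_fam = counts.index[rng.random(len(counts)) < p]
    return records[records["family_id"].isin(set(keep_fam))].reset_index(drop=True)


def simulate_ascertained_cohort(config: SimulationConfig,
                                target_families: int | None = None,
                                max_batches: int = 40):
    """Simulate genotypes + phenotypes + ascertainment, topping up in
    batches until ``target_families`` retained families are available.

    Returns ``(records, genotypes)`` aligned on individual_id.
    """
    recs, genos = [], []
    kept = 0
    target = target_families if target_families is not None else config.n_families
    for b in range(max_batches):
        g = simulate_genotypes(config, batch=b)
        r = simulate_phenotypes(g, config, batch=b)
        r = apply_ascertainment(r, config, batch=b)
        recs.append(r)
        genos.append(g.subset(r["individual_id"].to_numpy()))
        kept += r["family_id"].nunique()
        if target_families is None or kept >= target:
            break
    records = pd.concat(recs, ignore_index=True)
    dose = np.vstack([g.dose for g in genos])
    geno = GenotypeMatrix(records["individual_id"].to_numpy(),
                          records["family_id"].to_numpy(), dose,
                          genos[0].snp_ids)
    if target_families is not None:
        keep = records["family_id"].unique()[:target]
        records = records[records["family_id"].isin(set(keep))].reset_index(drop=True)
        geno = geno.subset(records["individual_id"].to_numpy())
    return records, geno


# ---------------------------------------------------------------------------
# imputed dosages

def simulate_dosages(genotypes: GenotypeMatrix, target_info: float, seed: int):
    """Posterior genotype probabilities emulating imputation at a target
    info (r^2) level.

    With probability ``target_info`` an individual's posterior is a point
    mass on the true genotype; otherwise it collapses to the HWE prior at
    the sample allele frequency.  The expected dose is then an unbiased,
    noisy version of the truth and the realised info statistic
    var(dose) / (2 f (1 - f)) concentrates on ``target_info``.
    """
    from .dosage import DosageSet  # local import to keep modules acyclic

    if not 0.0 < target_info <= 1.0:
        raise ValueError("target_info must lie in (0, 1]")
    rng = stream(seed, "dosage")
    n, s = genotypes.dose.shape
    f = genotypes.allele1_freq
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)  # (S,3)
    onehot = np.eye(3)[genotypes.dose]                                   # (n,S,3)
    keep = (rng.random((n, s)) < target_info)[..., None]
    probs = np.where(keep, onehot, prior[None, :, :])
    return DosageSet.from_probs(genotypes.individual_ids, genotypes.family_ids,
                                list(genotypes.snp_ids), probs)


# ---------------------------------------------------------------------------
# expression-survival cohort

def simulate_expression_cohort(n: int, beta_a: float = 0.0, beta_b: float = 0.0,
                               beta_ab: float = 0.0, corr: float = 0.3,
                               censor_frac: float = 0.3,
                               baseline_rate: float = 0.1, seed: int = 0,
                               gene_a: str = "geneA",
                               gene_b: str = "geneB") -> pd.DataFrame:
    """Sporadic-tumour style expression/survival table.

    Two correlated standard-normal expression values per case; survival times
    from an exponential proportional-hazards model with main effects and a
    product term; independent exponential censoring tuned so that roughly
    ``censor_frac`` of subjects are censored under the null (``censor_frac
    = 1`` censors everyone at baseline, leaving zero observed events).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= censor_frac <= 1.0:
        raise ValueError("censor_frac must lie in [0,1]")
    rng = stream(seed, "expression")
    cov = np.array([[1.0, corr], [corr, 1.0]])
    x = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    lp = beta_a * x[:, 0] + beta_b * x[:, 1] + beta_ab * x[:, 0] * x[:, 1]
    t_event = rng.exponential(1.0 / (baseline_rate * np.exp(lp)))
    if censor_frac >= 1.0:
        time, event = np.zeros(n), np.zeros(n, dtype=int)
    elif censor_frac == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        rate_c = baseline_rate * censor_frac / (1.0 - censor_frac)
        t_cens = rng.exponential(1.0 / rate_c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "sample_id": [f"T{i + 1}" for i in range(n)],
        "time": time, "event": event,
        gene_a: x[:, 0], gene_b: x[:, 1],
    })


# ---------------------------------------------------------------------------
# file output

def write_phenotype_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=PHENOTYPE_COLUMNS)


def read_phenotype_csv(path) -> pd.DataFrame:
    """Read and validate a phenotype table; schema violations are reported
    with the offending row."""
    df = pd.read_csv(path, dtype={"er_status": str, "mutation_class": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    age_cols = [c for c in PHENOTYPE_COLUMNS if c.startswith("age_")]
    for i, row in df.iterrows():
        ages = [row[c] for c in age_cols if pd.notna(row[c])]
        if not ages:
            raise ValueError(f"{path} row {i} ({row['individual_id']}): "
                             "no age field present")
        if any(a < 0 for a in ages):
            raise ValueError(f"{path} row {i} ({row['individual_id']}): "
                             "negative age")
        fup = row["age_last_followup"]
        if pd.notna(fup):
            for c in ("age_breast", "age_ovarian", "age_mastectomy",
                      "age_oophorectomy"):
                if pd.notna(row[c]) and row[c] > fup:
                    raise ValueError(
                        f"{path} row {i} ({row['individual_id']}): {c}="
                        f"{row[c]} exceeds age_last_followup={fup}")
    df["er_status"] = df["er_status"].fillna("")
    df["mutation_class"] = df["mutation_class"].fillna("")
    return df


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Rows = individuals, columns = SNPs."""
    pd.DataFrame(genotypes.dose, index=genotypes.individual_ids,
                 columns=genotypes.snp_ids).to_csv(path, sep="\t",
                                                   index_label="individual_id")


def read_genotype_tsv(path, phenotypes: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    ids = df.index.to_numpy(str)
    if phenotypes is not None:
        fam = phenotypes.set_index("individual_id").loc[ids, "family_id"].to_numpy()
    else:
        fam = ids.copy()
    return GenotypeMatrix(ids, fam, df.to_numpy(np.int8), list(df.columns))


def write_vcf(genotypes: GenotypeMatrix, path, dosages=None) -> None:
    """Write hard calls (GT), and when a DosageSet is supplied also DS and GP."""
    fmt = "GT" if dosages is None else "GT:DS:GP"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosages is not None:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Expected alternate allele dose">\n')
            fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,'
                     'Description="Genotype posterior probabilities">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.individual_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in enumerate(genotypes.snp_ids):
            cells = []
            for i in range(genotypes.n):
                cell = gt_str[int(genotypes.dose[i, j])]
                if dosages is not None:
                    p = dosages.probs[i, j]
                    cell += f":{p[1] + 2 * p[2]:.4f}:" + ",".join(
                        f"{v:.4f}" for v in p)
                cells.append(cell)
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\t{fmt}\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# config serialisation (flat key=value sections)

def config_to_ini(config: SimulationConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["simulation"] = {
        "n_families": str(config.n_families),
        "gene": config.gene,
        "n_strata": str(config.n_strata),
        "min_age": str(config.min_age),
        "seed": str(config.seed),
        "er_neg_fraction": str(config.er_neg_fraction),
        "er_unknown_fraction": str(config.er_unknown_fraction),
        "class1_fraction": str(config.class1_fraction),
        "frailty_sd": str(config.frailty_sd),
    }
    cp["family_structure"] = {k: str(v) for k, v in config.family_structure.items()}
    cp["haplotypes"] = {h: str(f) for h, f in
                        zip(config.haplotypes, config.haplotype_freqs)}
    cp["effects"] = {
        "log_hr_breast": ",".join(str(b) for b in config.true_log_hr_breast),
        "log_hr_ovarian": ",".join(str(b) for b in config.true_log_hr_ovarian),
    }
    cm = config.censor_model
    cp["censoring"] = {
        "p_mastectomy": str(cm.p_mastectomy),
        "mastectomy_ages": f"{cm.mastectomy_ages[0]},{cm.mastectomy_ages[1]}",
        "p_oophorectomy": str(cm.p_oophorectomy),
        "oophorectomy_ages": f"{cm.oophorectomy_ages[0]},{cm.oophorectomy_ages[1]}",
        "followup_ages": f"{cm.followup_ages[0]},{cm.followup_ages[1]}",
    }
    if config.ascertainment is not None:
        cp["ascertainment"] = {k: str(v) for k, v in config.ascertainment.items()}
    with open(path, "w") as fh:
        cp.write(fh)


def config_from_ini(path) -> SimulationConfig:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FileNotFoundError(path)
    sim = cp["simulation"]
    if "seed" not in sim:
        raise ValueError(f"{path}: seed is mandatory")
    pair = lambda s: tuple(float(v) for v in s.split(","))
    cm = CensorModel(
        p_mastectomy=cp.getfloat("censoring", "p_mastectomy", fallback=0.05),
        mastectomy_ages=pair(cp.get("censoring", "mastectomy_ages",
                                    fallback="30,60")),
        p_oophorectomy=cp.getfloat("censoring", "p_oophorectomy", fallback=0.10),
        oophorectomy_ages=pair(cp.get("censoring", "oophorectomy_ages",
                                      fallback="35,60")),
        followup_ages=pair(cp.get("censoring", "followup_ages", fallback="20,80")),
    ) if cp.has_section("censoring") else CensorModel()
    asc = ({k: float(v) for k, v in cp["ascertainment"].items()}
           if cp.has_section("ascertainment") else None)
    cfg = SimulationConfig(
        n_families=sim.getint("n_families"),
        family_structure={k: float(v) for k, v in cp["family_structure"].items()},
        haplotypes=tuple(cp["haplotypes"].keys()),
        haplotype_freqs=tuple(float(v) for v in cp["haplotypes"].values()),
        true_log_hr_breast=pair(cp.get("effects", "log_hr_breast")),
        true_log_hr_ovarian=pair(cp.get("effects", "log_hr_ovarian")),
        gene=sim.get("gene", "BRCA1"),
        censor_model=cm,
        ascertainment=asc,
        n_strata=sim.getint("n_strata", fallback=1),
        er_neg_fraction=sim.getfloat("er_neg_fraction", fallback=0.7),
        er_unknown_fraction=sim.getfloat("er_unknown_fraction", fallback=0.1),
        class1_fraction=sim.getfloat("class1_fraction", fallback=0.7),
        min_age=sim.getfloat("min_age", fallback=18.0),
        frailty_sd=sim.getfloat("frailty_sd", fallback=0.0),
        seed=sim.getint("seed"),
    )
    cfg.validate()
    return cfg
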