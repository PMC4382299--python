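"""Configuration-driven orchestration of the carrier analyses.

A run is described by a flat INI config (paths, analysis selections,
thresholds, seed) and executes the stages in dependency order: phenotype
construction -> per-SNP retrospective score tests and HR estimates -> FDR
-> haplotype EM + haplotype Cox -> SNP x SNP interaction scan ->
expression-interaction survival.  Every run writes a manifest with config
hash, package version, seed and per-file checksums; re-running an
identical config reproduces identical checksums.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dosage import dosage_score_test, filter_imputed, read_vcf_dosages
from .haplotypes import (diplotype_doses, em_haplotype_frequencies, group_rare,
                         haplotype_cox)
from .incidence import IncidenceModel, default_incidence
from .interactions import bh_fdr, expression_interaction_survival, gxg_scan
from .likelihood import estimate_hr, score_test, stratified_test
from .synthetic import read_genotype_tsv, read_phenotype_csv

logger = logging.getLogger("carriermod.pipeline")

RESULT_COLUMNS = ["snp", "gene", "disease", "n", "n_families", "U", "V",
                  "chi2", "p", "hr", "ci_low", "ci_high", "coding", "fdr"]


@dataclass
class RunConfig:
    phenotypes: Path
    genotypes_tsv: Path | None = None
    genotypes_vcf: Path | None = None
    incidence: dict = field(default_factory=dict)  # (gene, disease) -> model
    expression: Path | None = None
    diseases: tuple = ("breast",)
    snps: tuple | None = None          # None = all; () = none
    haplotype_window: tuple = ()
    gxg_index: tuple = ()
    gxg_partners: tuple = ()
    expression_pairs: tuple = ()
    info_min: float = 0.30
    maf_min: float = 0.3
    fdr_q: float = 0.05
    fdr_family_size: int | None = None
    keep_haplotypes: int = 4
    min_double_carriers: int = 10
    profile_freq: bool = False
    seed: int = 0
    output_dir: Path = Path("carriermod_out")

    def validate(self) -> None:
        if not Path(self.phenotypes).exists():
            raise FileNotFoundError(f"phenotype table not found: {self.phenotypes}")
        for p in (self.genotypes_tsv, self.genotypes_vcf, self.expression):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        if self.genotypes_tsv is None and self.genotypes_vcf is None:
            raise ValueError("genotypes_tsv or genotypes_vcf required")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_ini(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        base = Path(path).parent

        def p(section, key):
            v = cp.get(section, key, fallback=None)
            return (base / v) if v else None

        def tup(section, key, default=None):
            v = cp.get(section, key, fallback=None)
            if v is None:
                return default
            v = v.strip()
            return tuple(x.strip() for x in v.split(",") if x.strip())

        inc = {}
        if cp.has_section("incidence"):
            for key, v in cp["incidence"].items():
                gene, disease = key.upper().split("_", 1)
                inc[(gene, disease.lower())] = IncidenceModel.from_csv(
                    base / v, disease=disease.lower())
        if not cp.has_option("run", "seed"):
            raise ValueError(f"{path}: [run] seed is mandatory")
        return cls(
            phenotypes=p("inputs", "phenotypes"),
            genotypes_tsv=p("inputs", "genotypes_tsv"),
            genotypes_vcf=p("inputs", "genotypes_vcf"),
            expression=p("inputs", "expression"),
            incidence=inc,
            diseases=tup("analysis", "diseases", ("breast",)),
            snps=tup("analysis", "snps", None),
            haplotype_window=tup("analysis", "haplotype_window", ()),
            gxg_index=tup("analysis", "gxg_index", ()),
            gxg_partners=tup("analysis", "gxg_partners", ()),
            expression_pairs=tup("analysis", "expression_pairs", ()),
            info_min=cp.getfloat("thresholds", "info_min", fallback=0.30),
            maf_min=cp.getfloat("thresholds", "maf_min", fallback=0.3),
            fdr_q=cp.getfloat("thresholds", "fdr_q", fallback=0.05),
            fdr_family_size=(cp.getint("thresholds", "fdr_family_size")
                             if cp.has_option("thresholds", "fdr_family_size")
                             else None),
            keep_haplotypes=cp.getint("thresholds", "keep_haplotypes", fallback=4),
            min_double_carriers=cp.getint("thresholds", "min_double_carriers",
                                          fallback=10),
            profile_freq=cp.getboolean("analysis", "profile_freq", fallback=False),
            seed=cp.getint("run", "seed"),
            output_dir=Path(cp.get("run", "output_dir", fallback="carriermod_out")),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _incidence_for(config: RunConfig, gene: str, disease: str) -> IncidenceModel:
    return config.incidence.get((gene, disease)) or default_incidence(gene, disease)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    exclusions: list[dict] = []
    outputs: list[Path] = []

    records = read_phenotype_csv(config.phenotypes)
    genotypes = None
    if config.genotypes_tsv is not None:
        genotypes = read_genotype_tsv(config.genotypes_tsv, records)

    # --- per-SNP association stage
    snps = (list(config.snps) if config.snps is not None
            else (list(genotypes.snp_ids) if genotypes is not None else []))
    rows = []
    genes = sorted(records["gene"].unique())
    for gene in genes:
        sub = records[records["gene"] == gene].reset_index(drop=True)
        mask = (records["gene"] == gene).to_numpy()
        for disease in config.diseases:
            inc = _incidence_for(config, gene, disease)
            for snp in snps:
                gvec = genotypes.column(snp)[mask]
                st = score_test(sub, gvec, inc, disease)
                if not st.testable:
                    exclusions.append({"stage": "assoc", "item": snp,
                                       "reason": "untestable (monomorphic)"})
                    continue
                est = estimate_hr(sub, gvec, inc, disease,
                                  profile_freq=config.profile_freq)
                rows.append({
                    "snp": snp, "gene": gene, "disease": disease,
                    "n": st.n_individuals, "n_families": st.n_families,
                    "U": st.score_U, "V": st.variance_V, "chi2": st.chi2,
                    "p": st.p, "hr": est.hr, "ci_low": est.ci95[0],
                    "ci_high": est.ci95[1], "coding": est.coding,
                })
    assoc = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(assoc):
        m = config.fdr_family_size or len(assoc)
        assoc["fdr"] = bh_fdr(assoc["p"].to_numpy(), m=max(m, len(assoc)))
    else:
        assoc["fdr"] = pd.Series(dtype=float)
    path = out / "results_assoc.tsv"
    _write(assoc, path)
    outputs.append(path)

    # --- imputed-dosage stage
    if config.genotypes_vcf is not None:
        dosages = read_vcf_dosages(config.genotypes_vcf)
        kept, excluded = filter_imputed(dosages, config.info_min, config.maf_min)
        exclusions += [{"stage": "assoc-imputed", "item": mid, "reason": r}
                       for mid, r in excluded]
        irows = []
        for gene in genes:
            sub = records[records["gene"] == gene].reset_index(drop=True)
            for disease in config.diseases:
                inc = _incidence_for(config, gene, disease)
                for j, mid in enumerate(kept.marker_ids):
                    st = dosage_score_test(sub, kept, mid, inc, disease)
                    if not st.testable:
                        exclusions.append({"stage": "assoc-imputed", "item": mid,
                                           "reason": "zero dosage variance"})
                        continue
                    irows.append({
                        "snp": mid, "gene": gene, "disease": disease,
                        "n": st.n_individuals, "n_families": st.n_families,
                        "U": st.score_U, "V": st.variance_V, "chi2": st.chi2,
                        "p": st.p, "hr": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "coding": "dosage",
                        "info": kept.info[j], "maf": kept.maf[j],
                    })
        imp = pd.DataFrame(irows, columns=RESULT_COLUMNS[:-1]
                           + ["info", "maf"])
        path = out / "results_imputed.tsv"
        _write(imp, path)
        outputs.append(path)

    # --- haplotype stage
    if config.haplotype_window and genotypes is not None:
        idx = [genotypes.snp_ids.index(s) for s in config.haplotype_window]
        model = em_haplotype_frequencies(
            genotypes.dose[:, idx], snp_ids=list(config.haplotype_window),
            individual_ids=genotypes.individual_ids)
        model = group_rare(model, keep=config.keep_haplotypes)
        hap = pd.DataFrame({
            "haplotype": model.haplotypes,
            "frequency": model.freqs,
            "class": [model.class_labels[c] for c in model.hap_class],
        }).sort_values("frequency", ascending=False, kind="stable")
        path = out / "haplotype_freqs.tsv"
        _write(hap, path)
        outputs.append(path)
        doses = diplotype_doses(model)
        path = out / "diplotypes.tsv"
        doses.to_csv(path, sep="\t", index_label="individual_id")
        outputs.append(path)
        hc = haplotype_cox(records, doses, disease="breast")
        path = out / "results_haplotype_cox.tsv"
        _write(hc, path)
        outputs.append(path)

    # --- GxG stage
    if config.gxg_index and config.gxg_partners and genotypes is not None:
        scan = gxg_scan(records, genotypes, list(config.gxg_index),
                        list(config.gxg_partners),
                        min_double_carriers=config.min_double_carriers)
        path = out / "results_gxg.tsv"
        _write(scan, path)
        outputs.append(path)

    # --- expression stage
    if config.expression is not None and config.expression_pairs:
        expr = pd.read_csv(config.expression)
        erows, kms = [], []
        for pair in config.expression_pairs:
            gene_a, gene_b = pair.split(":")
            res, km = expression_interaction_survival(expr, gene_a, gene_b)
            for t, h, pv in zip(res.term_names, res.hr, res.p):
                erows.append({"pair": pair, "term": t, "hr": h, "p": pv})
            for grp in res.empty_groups:
                exclusions.append({"stage": "expr-surv", "item": grp,
                                   "reason": "empty tertile-combination group"})
            km.insert(0, "pair", pair)
            kms.append(km)
        path = out / "results_expression.tsv"
        _write(pd.DataFrame(erows), path)
        outputs.append(path)
        path = out / "km_curves.tsv"
        _write(pd.concat(kms, ignore_index=True), path)
        outputs.append(path)

    # --- exclusion log + manifest
    path = out / "exclusions.tsv"
    _write(pd.DataFrame(exclusions, columns=["stage", "item", "reason"]), path)
    outputs.append(path)

    cfg_hash = hashlib.sha256(
        json.dumps({k: str(v) for k, v in vars(config).items()},
                   sort_keys=True).encode()).hexdigest()
    manifest = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "wall_clock_s": round(time.time() - t_start, 3),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_report(config: RunConfig, out: Path | None = None) -> Path:
    """Human-readable summary: top hits with FDR, per-stratum forest tables,
    KM pointers.  Regeneration from the same outputs is byte-identical."""
    outdir = Path(out if out is not None else config.output_dir)
    lines = ["# carriermod run report", ""]
    assoc_path = outdir / "results_assoc.tsv"
    records = read_phenotype_csv(config.phenotypes)
    genotypes = (read_genotype_tsv(config.genotypes_tsv, records)
                 if config.genotypes_tsv else None)

    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path, sep="\t")
        lines.append("## Per-SNP association")
        if len(assoc) == 0:
            lines.append("No testable markers.")
        else:
            top = assoc.sort_values("p", kind="stable").head(10)
            lines.append(top.to_string(index=False))
            # forest tables per stratum for the top hit
            hit = top.iloc[0]
            sub = records[records["gene"] == hit["gene"]].reset_index(drop=True)
            gvec = genotypes.column(hit["snp"])[
                (records["gene"] == hit["gene"]).to_numpy()]
            inc = _incidence_for(config, hit["gene"], hit["disease"])
            try:
                per_stratum, pooled = stratified_test(sub, gvec, inc,
                                                      hit["disease"])
                forest = pd.DataFrame([
                    {"stratum": s, "n": r.n_individuals, "hr": r.hr,
                     "ci_low": r.ci95[0], "ci_high": r.ci95[1]}
                    for s, r in per_stratum.items()]
                    + [{"stratum": "pooled", "n": pooled.n_individuals,
                        "hr": pooled.hr, "ci_low": pooled.ci95[0],
                        "ci_high": pooled.ci95[1]}])
                fpath = outdir / f"forest_{hit['snp']}_{hit['disease']}.tsv"
                _write(forest, fpath)
                lines.append("")
                lines.append(f"Per-stratum forest table for {hit['snp']} "
                             f"({hit['disease']}): {fpath.name}")
            except ValueError as e:
                lines.append(f"(no stratified table: {e})")
    else:
        lines.append("No testable markers.")

    for name, title in [("results_imputed.tsv", "Imputed markers"),
                        ("results_gxg.tsv", "SNP x SNP interactions"),
                        ("results_haplotype_cox.tsv", "Haplotype Cox"),
                        ("results_expression.tsv", "Expression interactions")]:
        p = outdir / name
        lines.append(f"\n## {title}")
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            lines.append(df.head(12).to_string(index=False)
                         if len(df) else "No testable markers.")
        else:
            lines.append("Stage not run.")
    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
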