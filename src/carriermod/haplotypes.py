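"""Haplotype-frequency EM and haplotype association.

Estimates haplotype frequencies over a SNP window from unphased genotypes
by expectation-maximisation under random mating: the E-step computes each
individual's posterior over compatible diplotypes given current
frequencies, the M-step re-estimates frequencies from expected haplotype
counts.  Missing genotypes are summed over.  The most frequent haplotypes
are retained (four by default) with the remainder pooled into a single
"rare" class; carriers are assigned their most likely diplotype and the
resulting per-class doses feed a standard Cox proportional-hazards model
of age at breast cancer diagnosis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stream

logger = logging.getLogger("carriermod.haplotypes")

RARE_LABEL = "rare"
MAX_EXPANSION = 1 << 16


@dataclass
class HaplotypeModel:
    haplotypes: list                  # allele strings over the window
    freqs: np.ndarray                 # sums to 1
    loglik_trace: np.ndarray          # non-decreasing
    individual_ids: np.ndarray
    pair_indices: list                # per individual: (k, 2) haplotype index pairs
    posteriors: list                  # per individual: (k,) posterior probs
    snp_ids: list = field(default_factory=list)
    class_labels: list | None = None  # set by group_rare
    class_freqs: np.ndarray | None = None
    hap_class: np.ndarray | None = None  # haplotype index -> class index

    def __post_init__(self):
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1 within 1e-9")
        if np.any(np.diff(self.loglik_trace) < -1e-8):
            raise ValueError("EM log-likelihood trace must be non-decreasing")


def _compatible_pairs(row: np.ndarray):
    """Unordered haplotype pairs (as allele tuples) compatible with one
    unphased genotype row; missing genotypes (< 0) are expanded."""
    site_options = []
    expansion = 1
    for gt in row:
        if gt == 0:
            opts = [(0, 0)]
        elif gt == 2:
            opts = [(1, 1)]
        elif gt == 1:
            opts = [(0, 1), (1, 0)]
        elif gt < 0:
            opts = [(0, 0), (0, 1), (1, 0), (1, 1)]
        else:
            raise ValueError(f"invalid genotype {gt}")
        expansion *= len(opts)
        if expansion > MAX_EXPANSION:
            raise ValueError("window too heterozygous/missing to enumerate")
        site_options.append(opts)
    pairs = set()
    for combo in itertools.product(*site_options):
        a = tuple(c[0] for c in combo)
        b = tuple(c[1] for c in combo)
        pairs.add((a, b) if a <= b else (b, a))
    return sorted(pairs)


def em_haplotype_frequencies(genotypes: np.ndarray, snp_ids=None,
                             individual_ids=None, tol: float = 1e-8,
                             max_iter: int = 1000, n_starts: int = 1,
                             seed: int = 0) -> HaplotypeModel:
    """EM haplotype-frequency estimation from unphased genotypes.

    ``genotypes``: (n, S) allele-dose matrix in {0,1,2}; negative entries
    mark missing calls (summed over in the likelihood).  Frequencies start
    uniform over the compatible haplotypes; iteration stops when the
    relative log-likelihood change falls below ``tol`` or after
    ``max_iter`` iterations.  ``n_starts > 1`` adds random restarts and
    keeps the best optimum (multimodality check).
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.size == 0:
        raise ValueError("need at least one individual and one SNP")
    n, S = genotypes.shape
    if np.all(genotypes < 0):
        raise ValueError("window contains no observed genotypes")

    hap_index: dict[tuple, int] = {}
    pair_lists = []
    for i in range(n):
        pairs = _compatible_pairs(genotypes[i])
        idx = []
        for a, b in pairs:
            ia = hap_index.setdefault(a, len(hap_index))
            ib = hap_index.setdefault(b, len(hap_index))
            idx.append((ia, ib))
        pair_lists.append(np.array(idx, int))
    H = len(hap_index)
    hap_strings = [""] * H
    for hap, k in hap_index.items():
        hap_strings[k] = "".join(str(a) for a in hap)

    # flatten for vectorised EM
    a_idx = np.concatenate([p[:, 0] for p in pair_lists])
    b_idx = np.concatenate([p[:, 1] for p in pair_lists])
    owner = np.concatenate([np.full(len(p), i) for i, p in enumerate(pair_lists)])
    het = (a_idx != b_idx).astype(float) + 1.0  # 2 for a != b, 1 otherwise

    def run(f0):
        f = f0.copy()
        trace = []
        for _ in range(max_iter):
            w = het * f[a_idx] * f[b_idx]
            per_ind = np.bincount(owner, weights=w, minlength=n)
            ll = float(np.log(per_ind).sum())
            trace.append(ll)
            w_norm = w / per_ind[owner]
            counts = (np.bincount(a_idx, weights=w_norm, minlength=H)
                      + np.bincount(b_idx, weights=w_norm, minlength=H))
            f = counts / (2.0 * n)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) \
                    <= tol * (abs(trace[-2]) + 1e-12):
                break
        return f, np.array(trace)

    starts = [np.full(H, 1.0 / H)]
    if n_starts > 1:
        rng = stream(seed, "haplotype-em")
        starts += [rng.dirichlet(np.ones(H)) for _ in range(n_starts - 1)]
    best = None
    for f0 in starts:
        f, trace = run(f0)
        if best is None or trace[-1] > best[1][-1]:
            best = (f, trace)
    f, trace = best

    posteriors = []
    w = het * f[a_idx] * f[b_idx]
    per_ind = np.bincount(owner, weights=w, minlength=n)
    w_norm = w / per_ind[owner]
    pos = 0
    for i, p in enumerate(pair_lists):
        posteriors.append(w_norm[pos:pos + len(p)])
        pos += len(p)

    ids = (np.asarray(individual_ids) if individual_ids is not None
           else np.array([f"I{i + 1}" for i in range(n)]))
    return HaplotypeModel(hap_strings, f, trace, ids, pair_lists, posteriors,
                          snp_ids=list(snp_ids) if snp_ids is not None
                          else [f"snp{j + 1}" for j in range(S)])


def group_rare(model: HaplotypeModel, keep: int = 4) -> HaplotypeModel:
    """Retain the ``keep`` most frequent haplotypes as their own classes and
    pool the remainder into a single "rare" class (possibly empty).

    Ties at the cutoff break lexicographically on the haplotype string;
    total probability is conserved exactly.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    order = sorted(range(len(model.haplotypes)),
                   key=lambda k: (-model.freqs[k], model.haplotypes[k]))
    top = order[:keep]
    hap_class = np.full(len(model.haplotypes), len(top), int)
    for c, k in enumerate(top):
        hap_class[k] = c
    labels = [model.haplotypes[k] for k in top] + [RARE_LABEL]
    class_freqs = np.zeros(len(top) + 1)
    for k, f in enumerate(model.freqs):
        class_freqs[hap_class[k]] += f
    return replace(model, class_labels=labels, class_freqs=class_freqs,
                   hap_class=hap_class)


def assign_most_likely(model: HaplotypeModel, i: int):
    """Most likely diplotype for individual ``i`` (argmax posterior, ties
    broken lexicographically) and the per-class dose vector (sums to 2)."""
    pairs = model.pair_indices[i]
    post = model.posteriors[i]
    best = min(range(len(pairs)),
               key=lambda k: (-post[k], model.haplotypes[pairs[k][0]],
                              model.haplotypes[pairs[k][1]]))
    a, b = pairs[best]
    if model.class_labels is not None:
        dose = np.zeros(len(model.class_labels))
        dose[model.hap_class[a]] += 1
        dose[model.hap_class[b]] += 1
    else:
        dose = np.zeros(len(model.haplotypes))
        dose[a] += 1
        dose[b] += 1
    return model.haplotypes[a], model.haplotypes[b], dose


def diplotype_doses(model: HaplotypeModel) -> pd.DataFrame:
    """Assigned-diplotype dose matrix (individuals x haplotype classes)."""
    labels = (model.class_labels if model.class_labels is not None
              else list(model.haplotypes))
    rows = [assign_most_likely(model, i)[2] for i in range(len(model.individual_ids))]
    return pd.DataFrame(rows, index=model.individual_ids, columns=labels)


def haplotype_cox(records: pd.DataFrame, doses: pd.DataFrame,
                  disease: str = "breast", reference: str | None = None,
                  min_age: float | None = None,
                  cluster: str | None = "family_id") -> pd.DataFrame:
    """Cox proportional-hazards association between haplotype doses and age
    at diagnosis, with the most frequent haplotype as reference."""
    from .interactions import cox_fit
    from .likelihood import DEFAULT_MIN_AGE, build_cohort

    min_age = DEFAULT_MIN_AGE if min_age is None else min_age
    cohort, _ = build_cohort(records, disease, min_age)
    d = doses.loc[cohort["individual_id"]]
    if reference is None:
        reference = d.sum(axis=0).idxmax()
    covars = []
    for col in d.columns:
        if col == reference:
            continue
        if (d[col] > 0).sum() == 0:
            logger.warning("haplotype class %s dropped: no carriers", col)
            continue
        covars.append(col)
    table = pd.DataFrame({
        "entry": cohort["entry"].to_numpy(),
        "exit": cohort["exit"].to_numpy(),
        "event": cohort["affected"].to_numpy(),
        "family_id": cohort["family_id"].to_numpy(),
    })
    for col in covars:
        table[col] = d[col].to_numpy()
    res = cox_fit(table, covars, cluster_col="family_id" if cluster else None)
    res.insert(0, "reference", reference)
    return res
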