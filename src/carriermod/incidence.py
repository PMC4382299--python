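"""Piecewise-constant age-specific incidence models for mutation carriers.

An :class:`IncidenceModel` holds the population-average (carrier) incidence
:math:`\\lambda(t)` of one cancer on an age grid.  Genotype-specific hazards
in the retrospective likelihood are constrained so that their mixture over
the genotype distribution reproduces this curve (see
:func:`carriermod.likelihood.constrain_baseline`).

Bundled defaults are *illustrative* penetrance curves of the right order of
magnitude for BRCA1/BRCA2 breast and ovarian cancer; they are NOT estimates
from any consortium and users analysing real data must supply their own
tables via :meth:`IncidenceModel.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Upper age bound to which the last interval's rate is extended.
MAX_AGE = 120.0


@dataclass(frozen=True)
class IncidenceModel:
    """Piecewise-constant hazard on an ascending age grid.

    ``rates[k]`` applies on ``[age_breaks[k], age_breaks[k + 1])``; the last
    interval extends to :data:`MAX_AGE`.
    """

    disease: str
    age_breaks: np.ndarray  # length K, ascending interval start ages
    rates: np.ndarray       # length K, per-year hazards

    def __post_init__(self) -> None:
        breaks = np.asarray(self.age_breaks, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if breaks.ndim != 1 or breaks.size < 1 or breaks.size != rates.size:
            raise ValueError("age_breaks and rates must be 1-d and equal length")
        if np.any(np.diff(breaks) <= 0):
            raise ValueError("age_breaks must be strictly ascending")
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite and >= 0")
        object.__setattr__(self, "age_breaks", breaks)
        object.__setattr__(self, "rates", rates)

    @property
    def edges(self) -> np.ndarray:
        """Interval edges, length K + 1 (last edge MAX_AGE)."""
        return np.append(self.age_breaks, MAX_AGE)

    def hazard_at(self, age):
        """Hazard at given age(s); zero below the grid."""
        age = np.asarray(age, dtype=float)
        idx = np.searchsorted(self.edges, age, side="right") - 1
        out = np.where(idx >= 0, self.rates[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def cumulative_hazard(self, age):
        """Integrated hazard from the first grid age to ``age``."""
        age = np.asarray(age, dtype=float)
        edges = self.edges
        cum = np.concatenate([[0.0], np.cumsum(self.rates * np.diff(edges))])
        a = np.clip(age, edges[0], edges[-1])
        idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, len(self.rates) - 1)
        out = cum[idx] + self.rates[idx] * (a - edges[idx])
        return out if out.ndim else float(out)

    def interval_of(self, age):
        """Index of the interval containing ``age`` (clipped to the grid)."""
        age = np.asarray(age, dtype=float)
        return np.clip(np.searchsorted(self.edges, age, side="right") - 1,
                       0, len(self.rates) - 1)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_break": self.age_breaks, "rate": self.rates}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, disease: str = "") -> "IncidenceModel":
        """Read a two-column (age_break, rate) table; each row starts an interval."""
        df = pd.read_csv(path)
        if not {"age_break", "rate"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns age_break, rate")
        return cls(disease or "unspecified",
                   df["age_break"].to_numpy(float), df["rate"].to_numpy(float))


def _model(disease, pairs):
    b, r = zip(*pairs)
    return IncidenceModel(disease, np.array(b, float), np.array(r, float))


# Illustrative per-year carrier incidences (documented above as NOT the
# study-specific curves).  Cumulative risk by age 70: ~52% / ~29% (BRCA1
# breast / ovarian), ~42% / ~8% (BRCA2).
BRCA1_BREAST = _model("breast", [
    (18, 0.0005), (25, 0.002), (30, 0.006), (35, 0.012), (40, 0.018),
    (45, 0.022), (55, 0.022), (65, 0.021), (75, 0.018), (85, 0.015),
])
BRCA1_OVARIAN = _model("ovarian", [
    (18, 0.0002), (30, 0.002), (40, 0.008), (50, 0.012), (60, 0.012),
    (70, 0.008), (85, 0.006),
])
BRCA2_BREAST = _model("breast", [
    (18, 0.0003), (25, 0.001), (30, 0.004), (35, 0.008), (40, 0.013),
    (45, 0.017), (55, 0.019), (65, 0.019), (75, 0.016), (85, 0.013),
])
BRCA2_OVARIAN = _model("ovarian", [
    (18, 0.0001), (30, 0.0005), (40, 0.002), (50, 0.004), (60, 0.005),
    (70, 0.004), (85, 0.003),
])

DEFAULT_INCIDENCE = {
    ("BRCA1", "breast"): BRCA1_BREAST,
    ("BRCA1", "ovarian"): BRCA1_OVARIAN,
    ("BRCA2", "breast"): BRCA2_BREAST,
    ("BRCA2", "ovarian"): BRCA2_OVARIAN,
}


def default_incidence(gene: str, disease: str) -> IncidenceModel:
    try:
        return DEFAULT_INCIDENCE[(gene, disease)]
    except KeyError:
        raise KeyError(f"no bundled incidence for gene={gene!r}, disease={disease!r}")
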