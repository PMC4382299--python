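"""Shared fixtures: tiny hand-built carrier tables and incidence models."""

import numpy as np
import pandas as pd
import pytest

from carriermod.incidence import IncidenceModel


def record(iid="I1", fam="F1", gene="BRCA1", stratum="S0", breast=None,
           ovarian=None, mastectomy=None, oophorectomy=None, followup=60.0,
           er="", mclass=""):
    return {
        "individual_id": iid, "family_id": fam, "gene": gene,
        "stratum": stratum, "age_breast": breast, "age_ovarian": ovarian,
        "age_mastectomy": mastectomy, "age_oophorectomy": oophorectomy,
        "age_last_followup": followup, "er_status": er,
        "mutation_class": mclass,
    }


@pytest.fixture
def make_records():
    def _make(rows):
        return pd.DataFrame([record(**r) for r in rows])
    return _make


@pytest.fixture
def flat_incidence():
    """Constant 0.01/yr hazard from age 18."""
    return IncidenceModel("breast", np.array([18.0]), np.array([0.01]))


@pytest.fixture
def stepped_incidence():
    return IncidenceModel("breast", np.array([18.0, 30.0, 40.0, 50.0, 70.0]),
                          np.array([0.001, 0.005, 0.015, 0.02, 0.015]))
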