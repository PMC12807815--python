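import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tractwise as tw

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

DORSAL = ("Left Arcuate", "Left SLF")
CONTROLS = ("wordclasses_raw", "age", "nviq")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (81 young / 164 old, 45 overlapping)."""
    spec = tw.CohortSpec()
    return tw.generate_cohort(spec, seed=1)


@pytest.fixture(scope="session")
def null_cohort_dorsal():
    """Two-tract global-null cohort used by cluster/permutation tests."""
    spec = tw.CohortSpec(tracts=DORSAL)
    return tw.generate_cohort(spec, seed=5)


@pytest.fixture()
def tiny_subjects():
    """Hand-built subject table for inclusion-rule tests."""
    return pd.DataFrame({
        "subjectID": [f"p{i}_young" for i in range(8)],
        "subjectKey": [f"p{i}" for i in range(8)],
        "cohort": ["young"] * 8,
        "age": [5.5] * 8,
        "nviq": [100, 69, 100, 100, 100, 100, 100, 100],
        "core_language": [100, 100, 79, 80, 100, 100, 100, 100],
        "elision_raw": [11, 11, 11, 11, 11, 11, 11, 30],
        "wordclasses_raw": [12] * 8,
        "wid_raw": [120] * 8,
        "maternal_ed": [4] * 8,
        "right_handed": [True, True, True, True, False, True, True, True],
        "mainstream_english": [True, True, True, True, True, False, True, True],
        "diagnosis": ["", "", "", "", "", "", "ASD", ""],
    })


def make_map(p, r, tract="Left Arcuate", measure="elision_raw", n=100):
    """Construct a NodewiseMap directly from p and r arrays."""
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    return tw.NodewiseMap(tract=tract, measure=measure, controls=(),
                          r=r, p=p, n=n, k=0)
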