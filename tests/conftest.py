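import numpy as np
import pandas as pd
import pytest

from mitomorph import default_calibration, generate_cohort
from mitomorph.calibration import PROTEINS
from mitomorph.cohort import CELL_COLUMNS, MITO_COLUMNS, Cohort


@pytest.fixture(scope="session")
def default_config():
    return default_calibration()


@pytest.fixture(scope="session")
def cohort42(default_config):
    """One default-calibration cohort, reused read-only across tests."""
    return generate_cohort(default_config, seed=42)


def build_cohort(cell_specs, mito_specs):
    """Tiny hand-written cohort from minimal per-record dicts.

    ``cell_specs``: dicts with at least cell_id and dose_um; ``mito_specs``:
    dicts with at least mito_id and cell_id. Everything else defaults to an
    intact, alive cell / intact mitochondrion.
    """
    cell_defaults = {
        "replicate": 0, "alive": True, "dead_by_tem": False,
        "fjb_positive": False, "fjb_intensity": 100.0, "tb_positive": False,
        "mtrg_od": 100.0, "mtrr_od": 100.0,
        **{f"gold_{p}_cyt": 0 for p in PROTEINS},
    }
    mito_defaults = {
        "dilution": "NONE", "crests_broken": False, "membranes_ruptured": False,
        "d_max_um": 0.8, "d_min_um": 0.5, "area_um2": 0.3, "ed_norm": 1.4,
        **{f"gold_{p}": 0 for p in PROTEINS},
    }
    cells = pd.DataFrame([{**cell_defaults, **spec} for spec in cell_specs])[CELL_COLUMNS]
    if mito_specs:
        mitos = pd.DataFrame([{**mito_defaults, **spec} for spec in mito_specs])[MITO_COLUMNS]
    else:
        mitos = pd.DataFrame(columns=MITO_COLUMNS)
    return Cohort(cells, mitos)
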