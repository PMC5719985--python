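import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from pharmacoscopy import outcomes, screen_core, synthetic_data
from pharmacoscopy.cli import packaged_table1_path


@pytest.fixture(scope="session")
def table1_records():
    return outcomes.read_clinical_table(packaged_table1_path())


@pytest.fixture(scope="session")
def small_screen():
    """8-drug screen with one strong on-target drug, 5 replicates."""
    config = synthetic_data.ScreenSimConfig(
        n_drugs=8,
        n_concentrations=2,
        n_replicates=5,
        on_target_effect={"drug_003": 0.7},
        seed=11,
    )
    wells, truth = synthetic_data.simulate_screen(config)
    return config, wells, truth


@pytest.fixture(scope="session")
def aml_cohort():
    """Default 10+10 cohort at the 125-point matrix geometry, no outlier."""
    config = synthetic_data.CohortSimConfig(seed=7)
    profiles, labels = synthetic_data.simulate_aml_cohort(config)
    return config, profiles, labels


def make_well(
    drug,
    pos,
    neg,
    well="A01",
    conc=1.0,
    replicate=1,
    marker="CD34",
    patient="P1",
    total=None,
):
    """Shorthand WellRecord constructor for hand-built fixtures."""
    return screen_core.WellRecord(
        patient_id=patient,
        plate_id="plate1",
        well=well,
        drug=drug,
        concentration_um=0.0 if drug == "DMSO" else conc,
        replicate=replicate,
        n_viable_marker_pos={marker: pos},
        n_viable_marker_neg={marker: neg},
        n_total_cells=total if total is not None else pos + neg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
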