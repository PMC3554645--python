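import numpy as np
import pandas as pd
import pytest

import urimir as u
from urimir.normalize import McmcSettings

#: small, fast sampler settings for unit tests (acceptance tests use defaults)
FAST = McmcSettings(chains=2, iterations=600)


@pytest.fixture(scope="session")
def small_experiment():
    """One simulated matched-pair experiment at a reduced size."""
    design = u.SimulationDesign(n_pairs=6, n_mirna=40, seed=11)
    panel, annotations, truth = u.simulate_panel_experiment(design)
    return design, panel, annotations, truth


@pytest.fixture(scope="session")
def small_fitted(small_experiment):
    """Plate effects + corrected panel for the small experiment."""
    _, panel, annotations, truth = small_experiment
    pe = u.estimate_plate_effects(panel, settings=FAST, seed=21)
    corrected = u.correct_cq(panel, pe)
    pairs = u.build_pairs(annotations, "DN-vs-N")
    return panel, annotations, truth, pe, corrected, pairs


def toy_panel_frame(rows):
    """Build a CqPanelSet from (species, sample, plate, rep, cq, well_class)."""
    df = pd.DataFrame(
        rows,
        columns=["species_id", "sample_id", "plate_id", "replicate_index", "cq", "well_class"],
    )
    df["mimat"] = None
    return u.CqPanelSet(df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
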