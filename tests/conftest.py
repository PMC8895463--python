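import numpy as np
import pytest

import cypscreen as cs
from cypscreen.synthetic_data import SarGroundTruth, generate_library, plant_bioassay


@pytest.fixture(scope="session")
def planted_data():
    """A labeled, split synthetic dataset under the planted activity rule."""
    lib = generate_library(800, seed=11)
    records, truth = plant_bioassay(lib, SarGroundTruth(seed=11))
    labeled = cs.resolve_duplicates(cs.label_records(records))
    split = cs.stratified_split(labeled, seed=11)
    return dict(library=lib, records=records, truth=truth, labeled=labeled, split=split)


@pytest.fixture(scope="session")
def trained_model(planted_data):
    return cs.train(planted_data["split"].train, seed=11)


@pytest.fixture(scope="session")
def apd_model(planted_data, trained_model):
    fps = [c.molecule.fingerprint for c in planted_data["split"].train]
    return cs.fit_apd(fps, fingerprint_config=trained_model.fingerprint_config)


@pytest.fixture(scope="session")
def validation_indices(planted_data, trained_model):
    val = planted_data["split"].validation
    idx = cs.predict_indices(trained_model, [c.molecule for c in val])
    return np.asarray(idx), [c.label for c in val]
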