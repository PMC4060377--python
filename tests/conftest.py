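"""Shared fixtures: small synthetic datasets generated once per session."""

import logging

import pytest

from clift_cad import SynthConfig, generate_dataset
from clift_cad.pipeline import cell_table, process_manifest

logging.getLogger("clift_cad").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dataset12(tmp_path_factory):
    """12 wells, 5 images each, default generation conditions."""
    out = tmp_path_factory.mktemp("dataset12")
    cfg = SynthConfig(seed=11, n_wells=12, fraction_positive_wells=0.5)
    manifest = generate_dataset(cfg, out)
    return manifest


@pytest.fixture(scope="session")
def processed12(dataset12):
    return process_manifest(dataset12)


@pytest.fixture(scope="session")
def table12(processed12):
    return cell_table(processed12)


@pytest.fixture(scope="session")
def model12(table12):
    """Cell classifier trained on all labeled cells of the 12-well set."""
    import numpy as np

    from clift_cad.classifier import train

    mask = table12.labeled
    y = np.array([str(v) for v in table12.true_label[mask]])
    return train(table12.X[mask], y, table12.well_id[mask], seed=11)
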