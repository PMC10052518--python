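"""Shared fixtures: all inputs are generated, nothing is downloaded.

The expensive fixtures (the reference-like complex, its catalog, and
the synthetic affinity tables) are session-scoped so the featurizer
runs once per object per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from fcaffinity.interface_features import default_catalog
from fcaffinity.synthetic_data import (
    SyntheticTruth,
    ToyGeometrySpec,
    make_fc_complex,
    make_toy_complex,
    make_variant_table,
)

RICH_TOY_SPEC = ToyGeometrySpec(
    hbond_distances=(2.8, 3.0, 3.2),
    salt_bridge_distances=(3.95,),
    ca_contact_distances=(3.8,),
    hydrophilic_distances=(3.5,),
    b2m_contact_distances=(3.8,),
    pad_fc=2,
    pad_fcrn=2,
)


@pytest.fixture(scope="session")
def toy_bundle():
    """(pdb_text, manifest, model) with one of every planted interaction."""
    return make_toy_complex(RICH_TOY_SPEC)


@pytest.fixture(scope="session")
def reference():
    return make_fc_complex()


@pytest.fixture(scope="session")
def catalog(reference):
    return default_catalog(reference)


@pytest.fixture(scope="session")
def small_dataset(reference, catalog):
    """120-variant synthetic affinity table for fast learning tests."""
    truth = SyntheticTruth(n_records=120, sigma=0.15, ph6_fraction=0.15,
                           n_duplicate_pairs=4, seed=7)
    return make_variant_table(truth, reference, catalog)


@pytest.fixture(scope="session")
def study_dataset(reference, catalog):
    """The full-size synthetic study table (n = 500, sigma = 0.15)."""
    truth = SyntheticTruth(n_records=500, sigma=0.15, ph6_fraction=0.15,
                           n_duplicate_pairs=5, seed=11)
    return make_variant_table(truth, reference, catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
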