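"""Shared fixtures: small synthetic genera and on-disk datasets."""
from __future__ import annotations

import pytest

from barcodegap.curation import filter_its_complete
from barcodegap.simulate import GenusSimConfig, generate_genus


@pytest.fixture(scope="session")
def clean_genus():
    """One clean simulated genus with a clear barcode gap, regions attached."""
    cfg = GenusSimConfig(
        genus_name="Testus",
        n_species=4,
        seqs_per_species=3,
        inter_div=0.20,
        intra_div=0.01,
        seed=11,
    )
    return filter_its_complete(generate_genus(cfg))


@pytest.fixture(scope="session")
def tiny_genus():
    """2 species x 3 sequences, zero within-species divergence."""
    cfg = GenusSimConfig(
        genus_name="Minimus",
        n_species=2,
        seqs_per_species=3,
        inter_div=0.20,
        intra_div=0.0,
        its1_len=120,
        its2_len=130,
        seed=1,
    )
    return filter_its_complete(generate_genus(cfg))
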