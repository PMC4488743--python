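"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from paleombd import (
    CaptureParams,
    DamageParams,
    GenomeConfig,
    MethylationProfile,
    SizeModel,
    assign_methylome,
    build_reference,
)

TOY_GENOME = GenomeConfig(
    nuclear_length=60_000,
    n_cgi=4,
    cgi_length=800,
    n_te_families=2,
    te_copies=2,
    te_length=600,
    mito_length=3_000,
    n_microbial=2,
    microbial_length=12_000,
)


@pytest.fixture(scope="session")
def toy_genome_config():
    return TOY_GENOME


@pytest.fixture(scope="session")
def toy_ref():
    return build_reference(TOY_GENOME, seed=20150702)


@pytest.fixture(scope="session")
def toy_methylome(toy_ref):
    return assign_methylome(toy_ref, MethylationProfile())


@pytest.fixture()
def rng():
    return np.random.default_rng(11826)


@pytest.fixture(scope="session")
def default_damage():
    return DamageParams()


@pytest.fixture(scope="session")
def default_capture():
    return CaptureParams()


@pytest.fixture(scope="session")
def short_size_model():
    return SizeModel.lognormal(60, 0.35)
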