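"""Shared fixtures: all test structures are generated programmatically."""

import numpy as np
import pytest

import nanofib as nf
from nanofib.synthetic_data import make_probe_nanoparticle


@pytest.fixture(scope="session")
def fibril():
    """Annotated 32-chain fibril with face masks."""
    return nf.build_fibril(n_repeats=4, seed=0)


@pytest.fixture(scope="session")
def fibril_unit():
    return nf.make_synthetic_fibril_unit(seed=0)


@pytest.fixture(scope="session")
def ps_chain():
    return nf.build_chain("PS", 50, seed=1)


@pytest.fixture(scope="session")
def ps_system(ps_chain):
    return nf.replicate_chains(ps_chain, 9, box=20.0, seed=2)


@pytest.fixture(scope="session")
def ps_nanoparticle(ps_system):
    """Full-size assembled PS nanoparticle (shared; treat as read-only)."""
    return nf.assemble_nanoparticle(ps_system, seed=3)


@pytest.fixture(scope="session")
def probe():
    """Small bead-ball probe whose footprint is smaller than a fibril face."""
    return make_probe_nanoparticle(n_beads=48, radius=0.5, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
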