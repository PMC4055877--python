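"""Shared fixtures: side-chain sets, the toy pocket and its score grid."""

from __future__ import annotations

import numpy as np
import pytest

from fraggrow import docking as dk
from fraggrow import fixtures as fx
from fraggrow import molecule_io as mio
from fraggrow.sidechain_library import build_all_sets


@pytest.fixture(scope="session")
def sidechain_sets():
    return build_all_sets()


@pytest.fixture(scope="session")
def toy_spec():
    return fx.SyntheticPocketSpec()


@pytest.fixture(scope="session")
def toy_receptor_path(toy_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy") / "toy_receptor.pdb"
    return fx.make_toy_receptor(toy_spec, out)


@pytest.fixture(scope="session")
def toy_receptor(toy_receptor_path):
    return dk.prepare_receptor(toy_receptor_path, "LIG")


@pytest.fixture(scope="session")
def toy_grid(toy_receptor):
    receptor, pocket = toy_receptor
    return dk.build_grid(receptor, pocket, dims=120)


@pytest.fixture(scope="session")
def phenol_seed():
    return mio.assign_gasteiger_charges(fx.make_toy_seed("benzene-like"))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
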