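"""Shared fixtures: synthetic receptor endpoints, bilayers, toy systems."""

import numpy as np
import pytest

from memgate.core import Frame, MolecularSystem
from memgate.synth import BilayerSpec, ReceptorSpec, make_bilayer, \
    make_receptor


@pytest.fixture(scope="session")
def receptor_inactive():
    return make_receptor(ReceptorSpec(), "inactive")


@pytest.fixture(scope="session")
def receptor_active():
    return make_receptor(ReceptorSpec(), "active")


@pytest.fixture(scope="session")
def flat_bilayer():
    """Protein-free 8x8-per-leaflet PC lattice, 38 Å leaflet separation."""
    return make_bilayer(BilayerSpec())


def toy_system(n, role="protein", names=None, masses=None, resseqs=None,
               resnames=None, lipid_ids=None):
    """Minimal MolecularSystem for geometric unit tests."""
    names = np.array(names if names is not None else ["X"] * n, dtype=object)
    elements = np.array([nm[0] for nm in names], dtype=object)
    return MolecularSystem(
        names=names,
        elements=elements,
        masses=np.asarray(masses if masses is not None else [12.0] * n,
                          dtype=float),
        residue_seqs=np.asarray(resseqs if resseqs is not None
                                else np.arange(1, n + 1), dtype=int),
        residue_names=np.array(resnames if resnames is not None
                               else ["UNK"] * n, dtype=object),
        chains=np.array(["A"] * n, dtype=object),
        roles=np.array([role] * n, dtype=object),
        lipid_ids=np.asarray(lipid_ids if lipid_ids is not None
                             else [-1] * n, dtype=int),
    )


def frame_of(coords, box=None, time=0.0):
    return Frame(coords=np.asarray(coords, dtype=float),
                 box=None if box is None else np.asarray(box, dtype=float),
                 time=time)
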