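import numpy as np
import pytest

from geqshift import (Conformer, ModelConfig, build_graph, generate_ensemble,
                      parse_smiles)
from geqshift.model import GeqShiftNet

# methyl alpha-D-galactopyranoside: C7H14O6, 13 heavy atoms
GAL_SMILES = "CO[C@H]1O[C@H](CO)[C@H](O)[C@H](O)[C@H]1O"

TINY_CONFIG = dict(n_layers=2, node_emb_dim=32, edge_emb_dim=8,
                   hidden="8x0e+4x1o+2x2e", readout_scalars=16,
                   readout_hidden=32, weight_hidden=16)


@pytest.fixture(scope="session")
def gal_record():
    return parse_smiles(GAL_SMILES, molecule_id="gal",
                        saccharide_class="mono")


@pytest.fixture(scope="session")
def gal_ensemble(gal_record):
    return generate_ensemble(gal_record, n_generate=8, n_keep=4, seed=3)


@pytest.fixture(scope="session")
def gal_sample(gal_record, gal_ensemble):
    return build_graph(gal_record, gal_ensemble.conformers[0])


@pytest.fixture(scope="session")
def tiny_net():
    return GeqShiftNet(ModelConfig(**TINY_CONFIG), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng, improper=False):
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    if improper:
        R = R @ np.diag([-1.0, 1.0, 1.0])
    return R


def transformed_sample(record, conformer, R=None, translation=None):
    coords = np.asarray(conformer.coords, dtype=float)
    if R is not None:
        coords = coords @ R.T
    if translation is not None:
        coords = coords + np.asarray(translation)
    return build_graph(record, Conformer(record.molecule_id, coords, 0.0))
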