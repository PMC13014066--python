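import numpy as np
import pytest

import loxpharm as lp
from loxpharm.datasets import reference_feature_sets
from loxpharm.synth import make_planted_complex, make_toy_protein


@pytest.fixture(scope="session")
def helix20():
    return make_toy_protein(20, "helix")


@pytest.fixture(scope="session")
def toy60():
    return make_toy_protein(60, "helix")


@pytest.fixture(scope="session")
def planted_all():
    """Complex with one site per feature type, plus its planted truth."""
    layout = [{"ftype": t} for t in ("METAL", "HBD", "HBA", "HYD", "NI")]
    return make_planted_complex(layout, seed=0)


@pytest.fixture(scope="session")
def reference_models():
    return list(reference_feature_sets().values())


@pytest.fixture(scope="session")
def consensus_model(reference_models):
    corr = lp.correspond(reference_models, 2.0)
    cons = lp.build_consensus(corr, lp.ConsensusRules(n_models=3))
    cons.volumes = lp.merge_excluded_volumes(reference_models)
    return cons


def rigid_motion(seed=0):
    """A deterministic random rotation + translation."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.uniform(-15, 15, 3)


def transform_model(model, rot, trans):
    out = model.copy()
    for a in out.atoms:
        a.xyz = rot @ a.xyz + trans
    return out
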