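import numpy as np
import pytest

from tmbundle.numbering import extract_bundle
from tmbundle.synthetic import PerturbationSpec, build_bundle, perturb


@pytest.fixture(scope="session")
def clean_chain():
    """One unperturbed synthetic 7TM chain plus its receptor map."""
    return build_bundle()


@pytest.fixture(scope="session")
def clean_bundle(clean_chain):
    chain, rmap = clean_chain
    return extract_bundle(chain, rmap)


def bundle_with(chain, rmap, *, entry_id="SYNX", receptor_id=None, helix=3,
                translation=(0.0, 0.0, 0.0), angle=0.0, axis=(0, 0, 1),
                sigma=0.0, seed=0, state="inactivated"):
    """Perturbed copy of a synthetic chain, extracted as a Bundle."""
    spec = PerturbationSpec(helix=helix, translation=np.asarray(translation, float),
                            rotation_axis=np.asarray(axis, float),
                            rotation_angle=angle, sigma=sigma, seed=seed)
    p = perturb(chain, rmap, spec)
    p.entry_id = entry_id
    return extract_bundle(p, rmap, state=state,
                          receptor_id=receptor_id or rmap.receptor_id)
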