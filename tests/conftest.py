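import numpy as np
import pytest

from dosewarp import (DeformationSpec, PhantomConfig, author_field, build_phantom,
                      synth_fraction_dose)

# Session-scoped phantoms at a reduced validation grid (96 x 96 x 48-56 voxels,
# 2.5 x 2.5 x 3.0 mm) so the suite exercises full anatomy at desk-scale cost.


@pytest.fixture(scope="session")
def prostate_config():
    return PhantomConfig(site="prostate_like", size=(96, 96, 48),
                         spacing=(2.5, 2.5, 3.0), seed=2)


@pytest.fixture(scope="session")
def prostate_phantom(prostate_config):
    return build_phantom(prostate_config)


@pytest.fixture(scope="session")
def cervix_phantom():
    cfg = PhantomConfig(site="cervix_like", size=(96, 96, 56),
                        spacing=(2.5, 2.5, 3.0), seed=2)
    return build_phantom(cfg)


@pytest.fixture(scope="session")
def fraction_dose(prostate_phantom):
    ct, structures, rx = prostate_phantom
    return synth_fraction_dose(structures, rx, technique="imrt9", seed=2)


@pytest.fixture(scope="session")
def bladder_expand_field(prostate_phantom):
    ct, structures, rx = prostate_phantom
    return author_field(structures, [DeformationSpec("bladder", "expand", 10.0)])
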