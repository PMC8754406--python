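import numpy as np
import pytest

from pexsite.genes import GeneModel
from pexsite.profiler import ShellSpec, shell_density_profile
from pexsite.synth import sample_default_scenes

ENSEMBLE_SEED = 1


@pytest.fixture(scope="session")
def default_scene_ensemble():
    """51 default-preset scenes (the per-study organelle count)."""
    return sample_default_scenes(51, seed=ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def default_profiles(default_scene_ensemble):
    spec = ShellSpec()
    return [
        shell_density_profile(s.membrane, s.ribosomes, spec, crop=s.crop)
        for s in default_scene_ensemble
    ]


@pytest.fixture()
def toy_genes():
    return [
        GeneModel("geneA", "chrI", "+", [(99, 200)]),
        GeneModel("geneB", "chrI", "+", [(149, 250)]),
        GeneModel("geneC", "chrI", "-", [(99, 200)]),
        GeneModel("geneD", "chrII", "+", [(500, 800), (900, 1100)]),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
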