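import numpy as np
import pytest

from retrotarget.annotate import ChdProfile
from retrotarget.library import example_library
from retrotarget.pipeline import load_config, run_pipeline


@pytest.fixture(scope="session")
def library():
    return example_library(seed=0)


@pytest.fixture(scope="session")
def chd_profile():
    return ChdProfile.packaged()


@pytest.fixture(scope="session")
def targeted_run(tmp_path_factory):
    """One mid-size simulate+analyse run shared by several tests.

    18 copies of an LTR family planted 13-33 bp upstream of tRNA genes
    at zero divergence in a 300 kb genome.
    """
    cfg = load_config({
        "seed": 11,
        "simulate": {
            "length": 300_000, "n_trna": 24,
            "profiles": [{
                "family": "DGLTA_like", "n_copies": 18, "side": "upstream",
                "gap_min": 13, "gap_max": 33,
            }],
        },
        "target": {"n_permutations": 300},
    })
    out = tmp_path_factory.mktemp("targeted_run")
    result = run_pipeline(cfg, outdir=out)
    return cfg, out, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
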