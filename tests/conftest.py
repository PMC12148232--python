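import numpy as np
import pandas as pd
import pytest

import asrpath as ap


@pytest.fixture(scope="session")
def three_tip_tree():
    return ap.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule50():
    return ap.simulate_tree(50, seed=1234)


@pytest.fixture(scope="session")
def paperlike_dataset():
    """One full-size synthetic dataset under the default study conditions."""
    return ap.generate(ap.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A 120-tip dataset with enough variation in every variable and no
    missing data, for fast end-to-end fits."""
    cfg = ap.GeneratorConfig(
        n_tips=120, seed=99, missingness={}, complete_block=0.0,
        mk_rates=(0.8, 1.6),
    )
    return ap.generate(cfg)
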