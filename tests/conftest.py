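"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from itfscreen.simulate import example_tag_inputs
from itfscreen.tags import build_tag_table


@pytest.fixture(scope="session")
def small_orfs_vec():
    """Five random ORFs (600 nt) plus vector context, fixed seed."""
    return example_tag_inputs(n_tfs=5, cds_len=600, seed=11)


@pytest.fixture(scope="session")
def small_tag_table(small_orfs_vec):
    orfs, vec = small_orfs_vec
    return build_tag_table(orfs, vec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
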