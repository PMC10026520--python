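import warnings

import numpy as np
import pytest

from snapshot_ccre import indexing
from snapshot_ccre.synthetic import FixtureConfig, generate

# The frozen acceptance fixture: 5 planted patterns with unbalanced
# abundances, 5% spurious peak-call flips, 200 singleton noise ISs.
ACCEPTANCE_SEED = 1


def acceptance_config(**overrides) -> FixtureConfig:
    defaults = dict(seed=ACCEPTANCE_SEED, bit_flip_rate=0.05, n_noise_singletons=200)
    defaults.update(overrides)
    return FixtureConfig(**defaults)


@pytest.fixture(scope="session")
def planted_fixture():
    """The default bundle: 2000/1000/500/300/174 pattern copies + noise."""
    return generate(acceptance_config())


@pytest.fixture(scope="session")
def clean_fixture():
    """No bit flips: observed matrix equals the planted matrix exactly."""
    return generate(acceptance_config(bit_flip_rate=0.0))


@pytest.fixture(scope="session")
def uniform_fixture():
    """5 planted patterns x 1000 copies + 200 singletons, no flips."""
    patterns = [(p, 1000) for p, _ in FixtureConfig().patterns]
    return generate(acceptance_config(patterns=patterns, bit_flip_rate=0.0))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The acceptance fixture written to disk as plain-text input files."""
    outdir = tmp_path_factory.mktemp("bundle")
    fx = generate(acceptance_config(), outdir=outdir)
    return fx


@pytest.fixture(scope="session")
def _planted_binary_matrix(planted_fixture):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return indexing.binarize(
            planted_fixture.master, planted_fixture.peak_lists, planted_fixture.tree
        )


@pytest.fixture
def planted_index_sets(_planted_binary_matrix):
    # fresh IndexSet objects per test: statuses are mutated downstream
    return _planted_binary_matrix, indexing.group_into_index_sets(_planted_binary_matrix)


def planted_index_strings(fx) -> set[str]:
    return {indexing.make_index(np.array(p)) for p, _ in fx.config.patterns}
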