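import numpy as np
import pandas as pd
import pytest

from cazlink.ontology import default_mapping
from cazlink.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across read-only tests."""
    return simulate(SimulationConfig(seed=11, n_bins=150))


@pytest.fixture()
def tiny_mapping(tmp_path):
    """Write a minimal two-family mapping TSV and return its path."""
    path = tmp_path / "mapping.tsv"
    path.write_text(
        "family\tcupp_group\tmajor\tbranch\tspecific\tweight\n"
        "GH13\t\tStarch\tStarch - Backbone\tα-1,4::Glc\t\n"
        "GH43\t\tXylan\tXylan - Backbone\tβ-1,4::Xyl\t0.5\n"
        "GH43\t\tPectin\tArabinogalactan\tα-1,3/α-1,5::Ara\t0.5\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_profile(values, samples=None):
    """Feature-by-sample DataFrame from a nested list."""
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                        columns=samples)
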