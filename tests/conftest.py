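import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ctnnbscan as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return cs.default_reference()


@pytest.fixture(scope="session")
def library():
    return cs.default_library()


@pytest.fixture(scope="session")
def classifier(reference, library):
    return cs.ReadClassifier(reference, library)


@pytest.fixture(scope="session")
def mes_lookup(library):
    """A deterministic synthetic MES lookup spanning weak and strong values."""
    values = np.linspace(1000.0, 40000.0, len(library))
    return pd.Series(values, index=[v.label for v in library]).to_dict()


@pytest.fixture(scope="session")
def small_sortseq():
    """A reduced-depth sort-seq simulation for fast unit tests."""
    from ctnnbscan.simulate import SortSeqConfig, simulate_sortseq

    config = SortSeqConfig(
        cells_per_variant=400, reads_per_bin=200_000, reads_control=200_000, seed=11
    )
    return simulate_sortseq(config)


def mutate_codon(reference, residue: int, codon: str) -> str:
    """Reference sequence with one target codon replaced."""
    i = (reference.target_start - 1) + 3 * (residue - reference.first_codon_number)
    return reference.sequence[:i] + codon + reference.sequence[i + 3 :]
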