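import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from shadowy.gwas import GenotypeMatrix

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_matrix(call_rows, sexes, chroms=None, positions=None):
    """GenotypeMatrix from a markers x samples list of code lists."""
    calls = np.asarray(call_rows, dtype=np.int8).T  # -> samples x markers
    n_markers = calls.shape[1]
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(n_markers)],
            "chrom": chroms or ["1"] * n_markers,
            "pos": positions or [1000 * (j + 1) for j in range(n_markers)],
            "ref": ["A"] * n_markers,
            "alt": ["G"] * n_markers,
        }
    )
    samples = pd.DataFrame(
        {"id": [f"s{i}" for i in range(len(sexes))], "sex": list(sexes)}
    )
    return GenotypeMatrix(markers=markers, samples=samples, calls=calls)


@pytest.fixture
def balanced_cohort():
    """25 males (all het) + 25 females (all hom-ref) at one marker."""
    return make_matrix([[1] * 25 + [0] * 25], ["male"] * 25 + ["female"] * 25)
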