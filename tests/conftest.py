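import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from triohet import ROLE_F1, ROLE_FEMALE, ROLE_MALE, TrioCountMatrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_trio(counts: np.ndarray, n_rep: int = 1, gene_ids=None) -> TrioCountMatrix:
    """Counts array with columns ordered female..., male..., f1...."""
    n_samples = counts.shape[1]
    assert n_samples == 3 * n_rep
    roles = [ROLE_FEMALE] * n_rep + [ROLE_MALE] * n_rep + [ROLE_F1] * n_rep
    reps = list(range(1, n_rep + 1)) * 3
    samples = [f"s{i+1}" for i in range(n_samples)]
    if gene_ids is None:
        gene_ids = [f"g{i+1}" for i in range(counts.shape[0])]
    return TrioCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        sample_meta=pd.DataFrame(
            {"role": roles, "replicate": reps}, index=pd.Index(samples, name="sample")
        ),
    )


@pytest.fixture
def tiny_trio() -> TrioCountMatrix:
    rng = np.random.default_rng(0)
    counts = rng.poisson(100, size=(20, 3))
    return make_trio(counts)
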