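import numpy as np
import pytest

from ccxpen.io_data import CaseCrossoverDataset
from ccxpen.synthetic_data import euroscar_like_spec, simulate_dataset


def dataset_from_counts(n10, n01, n11=0, n00=1, name="d"):
    """Single-drug dataset with the given discordance/concordance counts."""
    case = [1] * n10 + [0] * n01 + [1] * n11 + [0] * n00
    ref = [0] * n10 + [1] * n01 + [1] * n11 + [0] * n00
    n = len(case)
    if n == 0:
        raise ValueError("empty dataset")
    return CaseCrossoverDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        drug_names=[name],
        case_exposure=np.array(case, dtype=np.int8)[:, None],
        ref_exposure=np.array(ref, dtype=np.int8)[:, None],
    )


def multi_dataset_from_counts(counts, n_pad=1):
    """Multi-drug dataset; drugs never co-occur (block-diagonal exposures).

    ``counts`` is a list of (n10, n01) per drug; each drug's discordant
    subjects are disjoint from every other drug's.
    """
    p = len(counts)
    blocks_case, blocks_ref = [], []
    total = sum(a + b for a, b in counts) + n_pad
    row = 0
    case = np.zeros((total, p), dtype=np.int8)
    ref = np.zeros((total, p), dtype=np.int8)
    for j, (n10, n01) in enumerate(counts):
        case[row : row + n10, j] = 1
        row += n10
        ref[row : row + n01, j] = 1
        row += n01
    return CaseCrossoverDataset(
        subject_ids=[f"s{i}" for i in range(total)],
        drug_names=[f"d{j}" for j in range(p)],
        case_exposure=case,
        ref_exposure=ref,
    )


@pytest.fixture(scope="session")
def euroscar_like():
    """One fixed draw from the 351x30 sparse-exposure study layout."""
    return simulate_dataset(euroscar_like_spec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_dataset(rng, n=40, p=4, d=0.4):
    """Dense-ish random matched-pair dataset for property checks."""
    case = (rng.random((n, p)) < d).astype(np.int8)
    ref = (rng.random((n, p)) < d).astype(np.int8)
    return CaseCrossoverDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        drug_names=[f"d{j}" for j in range(p)],
        case_exposure=case,
        ref_exposure=ref,
    )
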