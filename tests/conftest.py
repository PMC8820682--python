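import numpy as np
import pandas as pd
import pytest

from hepamir.io import CountMatrix


def make_meta(sample_ids, diets=None, times=None, treatments=None):
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "diet": diets if diets is not None else ["CHO"] * n,
        "time_h": times if times is not None else [0] * n,
        "treatment": treatments if treatments is not None else ["untreated"] * n,
        "replicate": _replicates(sample_ids, diets, times, treatments),
    })


def _replicates(sample_ids, diets, times, treatments):
    seen: dict[tuple, int] = {}
    reps = []
    for i in range(len(sample_ids)):
        key = (
            diets[i] if diets is not None else "CHO",
            times[i] if times is not None else 0,
            treatments[i] if treatments is not None else "untreated",
        )
        seen[key] = seen.get(key, 0) + 1
        reps.append(seen[key])
    return reps


def make_count_matrix(array, mirna_ids=None, **meta_kwargs):
    array = np.asarray(array)
    mirnas = mirna_ids or [f"miR-t{i}" for i in range(array.shape[0])]
    sample_ids = [f"S{j}" for j in range(array.shape[1])]
    meta = make_meta(sample_ids, **meta_kwargs)
    return CountMatrix(pd.DataFrame(array, index=mirnas, columns=sample_ids), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_counts():
    """6 miRNAs x 4 samples with unequal libraries and a zero cell."""
    x = np.array([
        [100, 210, 95, 400],
        [50, 90, 60, 190],
        [1000, 2100, 980, 4100],
        [5, 12, 0, 22],
        [300, 580, 310, 1250],
        [40, 85, 38, 160],
    ])
    return make_count_matrix(x)
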