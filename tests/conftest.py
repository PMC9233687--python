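import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from occultclone.genome import toy_arms
from occultclone.io_formats import CountMatrix
from occultclone import synthetic_data as sd


@pytest.fixture(scope="session")
def arm_table():
    return toy_arms(n_chrom=4)


@pytest.fixture(scope="session")
def two_clone_structure(arm_table):
    """Two clones on a triploid background differing on two arms."""
    st = sd.simulate_clonal_structure(
        2, base_ploidy=3, events_per_clone=2, seed=5, arm_table=arm_table
    )
    assert st.arm_cn.iloc[0].nunique() == 1  # root uniform
    return st


@pytest.fixture(scope="session")
def three_clone_structure(arm_table):
    return sd.simulate_clonal_structure(
        3, base_ploidy=3, events_per_clone=2, seed=1,
        arm_table=arm_table, clone_frequencies=[0.5, 0.3, 0.2],
    )


def make_counts(dense, gene_ids=None, barcodes=None, gene_names=None):
    dense = np.asarray(dense)
    g, c = dense.shape
    return CountMatrix(
        sp.csr_matrix(dense),
        gene_ids if gene_ids is not None else [f"G{i}" for i in range(g)],
        barcodes if barcodes is not None else [f"B{i}" for i in range(c)],
        gene_names,
    )


def match_partition_accuracy(truth, labels):
    """Best label-permutation accuracy over cells with an assigned label."""
    import itertools

    truth = np.asarray(truth)
    labels = np.asarray(labels)
    mask = labels >= 0
    k = max(truth.max(), labels[mask].max() if mask.any() else 0) + 1
    best = 0.0
    for perm in itertools.permutations(range(k)):
        mapped = np.array([perm[t] for t in truth[mask]])
        best = max(best, float(np.mean(mapped == labels[mask])))
    return best
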