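import io

import numpy as np
import pandas as pd
import pytest

from phosflow.core_model import collapse_replicates, read_quant_table
from phosflow.synthetic_data import (
    generate_dataset, make_clustered_truth, make_reference_truth,
)

TOY_TSV = """\
Modified sequence\tProteins\tKinase\tRatio\tSignificance B\tReplicate
_AAS(ph)GR_\tNTH1\tSNF1\t0.5\t0.01\t1
_AAS(ph)GR_\tNTH1\tSNF1\t0.7\t0.03\t2
_AAS(ph)GR_\tNTH1\tSNF1\t0.9\t0.02\t3
_AAS(ph)GR_\tNTH1\tTPK2\t2.0\t0.2\t1
_AAS(ph)GR_\tNTH1\tTPK2\t4.0\t0.3\t2
_QQT(ph)LK_\tPFK2a;PFK2b\tELM1\t1.1\t0.8\t1
"""


@pytest.fixture
def toy_table(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(TOY_TSV)
    return path


@pytest.fixture
def toy_records(toy_table):
    return read_quant_table(toy_table)


@pytest.fixture
def toy_matrix(toy_records):
    return collapse_replicates(toy_records)


@pytest.fixture(scope="session")
def clustered_scenario():
    """Reference planted-cluster simulation: 2 x 20 block peptides + 50 nulls."""
    truth = make_clustered_truth(
        7, n_clusters=2, cluster_size=20, n_scattered=50, effect=1.0
    )
    records, _ = generate_dataset(truth, n_peptides=90, n_replicates=2, noise_sd=0.25)
    return records, truth


@pytest.fixture(scope="session")
def reference_matrix():
    """Small full-featured study (clusters + causal edges + missingness)."""
    truth = make_reference_truth(3, n_peptides=260)
    records, _ = generate_dataset(truth, n_peptides=260, n_replicates=2)
    return collapse_replicates(records), truth
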