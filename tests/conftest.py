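import numpy as np
import pandas as pd
import pytest

from medtail import SimConfig, simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_genes_exp=60, n_genes_spike=25, n_fragments=8000)


@pytest.fixture(scope="session")
def annotation(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def count_sim(annotation, small_config):
    return simulate_counts(annotation, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_de_table(gene_ids, log2fc, padj, status="tested"):
    """Minimal DE-result frame for gene-set logic tests."""
    return pd.DataFrame(
        {
            "baseMean": 100.0,
            "log2fc": np.asarray(log2fc, dtype=float),
            "se": 0.1,
            "wald_p": np.asarray(padj, dtype=float),
            "padj": np.asarray(padj, dtype=float),
            "status": status,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
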