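import numpy as np
import pandas as pd
import pytest

from haplotx import simulate
from haplotx.io import OrthologueMap, QuantTable


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(n_genes=300, rng_seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.make_truth(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_truth, small_config):
    quants, sheet, sample_truth = simulate.simulate_expression_experiment(
        small_truth, small_config
    )
    return quants, sheet, sample_truth


@pytest.fixture(scope="session")
def de_config():
    # moderate depth, mild spread: the regime the Wald engine is built for
    return simulate.SimConfig(
        n_genes=800, mean_depth=300, depth_sdlog=0.5, rng_seed=21
    )


@pytest.fixture(scope="session")
def de_experiment(de_config):
    truth = simulate.make_truth(de_config)
    quants, sheet, sample_truth = simulate.simulate_expression_experiment(
        truth, de_config
    )
    return truth, quants, sheet


def make_quant(sample_id: str, rows: dict[str, float], length: int = 900) -> QuantTable:
    """Quant table from {transcript: num_reads}, TPM scaled to 1e6."""
    ids = list(rows)
    counts = np.array([rows[i] for i in ids], dtype=float)
    eff = float(length - 150 + 1)
    rate = counts / eff
    tpm = rate / rate.sum() * 1e6 if rate.sum() else rate
    table = pd.DataFrame(
        {
            "length": length,
            "effective_length": eff,
            "tpm": tpm,
            "num_reads": counts,
        },
        index=pd.Index(ids, name="Name"),
    )
    return QuantTable(sample_id=sample_id, table=table)


@pytest.fixture
def toy_map():
    return OrthologueMap(pairs=[("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
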