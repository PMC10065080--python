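import numpy as np
import pandas as pd
import pytest

from gatarescue import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(n_genes=600, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small synthetic dataset shared across read-only tests."""
    annotation = simulate.simulate_annotation(small_config)
    truth = simulate.simulate_truth(small_config)
    counts = simulate.simulate_counts(small_config, truth, annotation)
    samples = simulate.sample_table(small_config)
    peak_table, sequences, truth = simulate.simulate_peaks_and_sequences(
        small_config, truth, annotation
    )
    return {
        "config": small_config,
        "annotation": annotation,
        "truth": truth,
        "counts": counts,
        "samples": samples,
        "peak_table": peak_table,
        "sequences": sequences,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def nb_counts(rng, mu, alpha, n_samples, prefix="s"):
    """Helper: NB count frame with constant per-gene mean across samples."""
    mu = np.asarray(mu, dtype=float)
    size = 1.0 / alpha
    cols = {
        f"{prefix}{j}": rng.negative_binomial(size, size / (size + mu))
        for j in range(n_samples)
    }
    df = pd.DataFrame(cols)
    df.index = [f"g{i}" for i in range(len(mu))]
    return df
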