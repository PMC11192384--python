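import numpy as np
import pandas as pd
import pytest

import chondroseq as cs


@pytest.fixture(scope="session")
def small_dataset():
    """A modest two-arm dataset with real DE signal, shared across tests."""
    config = cs.GeneratorConfig(
        n_genes=600, set_size=60, de_fraction=0.2, lfc_sd=1.2, seed=42
    )
    counts, samples, truth = cs.simulate_dataset(config)
    return config, counts, samples, truth


@pytest.fixture(scope="session")
def small_de_tables(small_dataset):
    """Day-14 KO-vs-WT DE tables for both arms of the small dataset."""
    _, counts, samples, _ = small_dataset
    filtered = cs.filter_low_expressed(counts)
    tables = {}
    for arm in ("KS1", "KS2"):
        spec = cs.ContrastSpec(
            factor="genotype", numerator="KO", denominator="WT",
            where={"arm": arm, "timepoint": "D14"},
        )
        tables[arm] = cs.fit_nb_contrast(filtered, samples, spec)
    return tables


def make_paired(n_both, up_up, down_down, n_extra_ns=25, seed=0):
    """Paired table with an exact both-significant sign-pair composition."""
    rng = np.random.default_rng(seed)
    discordant = n_both - up_up - down_down
    signs_a = np.concatenate([
        np.ones(up_up), -np.ones(down_down),
        np.where(np.arange(discordant) % 2 == 0, 1.0, -1.0),
    ])
    signs_b = np.concatenate([
        np.ones(up_up), -np.ones(down_down),
        np.where(np.arange(discordant) % 2 == 0, -1.0, 1.0),
    ])
    n = n_both + n_extra_ns
    lfc_a = np.concatenate([signs_a * rng.uniform(0.5, 3, n_both),
                            rng.normal(0, 0.2, n_extra_ns)])
    lfc_b = np.concatenate([signs_b * rng.uniform(0.5, 3, n_both),
                            rng.normal(0, 0.2, n_extra_ns)])
    sig = np.concatenate([np.ones(n_both, bool), np.zeros(n_extra_ns, bool)])
    p = np.where(sig, 1e-4, 0.5)
    return pd.DataFrame({
        "gene_id": [f"G{i:05d}" for i in range(n)],
        "lfc_a": lfc_a, "p_a": p, "padj_a": p, "sig_a": sig,
        "lfc_b": lfc_b, "p_b": p, "padj_b": p, "sig_b": sig,
    })
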