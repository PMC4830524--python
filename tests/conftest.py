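import numpy as np
import pandas as pd
import pytest

from pdhs.synthetic import GeneratorConfig, generate_study


def small_config(**overrides) -> GeneratorConfig:
    """A scaled-down study for fast unit/integration tests."""
    base = dict(
        n_chroms=2,
        chrom_length_bp=2_000_000,
        n_genes=120,
        n_dhs=150,
        dhs_length_bp=150,
        background_snp_rate=0.001,
        shared_fraction=0.5,
        n_causal=8,
        beta_range=(0.4, 0.7),
        n_mouse_samples=80,
        n_human_samples=160,
        censor_fraction=0.3,
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_expr(values: np.ndarray, prefix_gene="g", prefix_sample="s"):
    from pdhs.screen import ExpressionMatrix

    genes = [f"{prefix_gene}{i}" for i in range(values.shape[0])]
    samples = [f"{prefix_sample}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_pheno(times, events, counts=None, prefix_sample="s"):
    from pdhs.screen import PhenotypeTable

    d = {"dmfs_time": np.asarray(times, dtype=float), "dmfs_event": np.asarray(events)}
    if counts is not None:
        d["metastasis_count"] = np.asarray(counts)
    idx = pd.Index([f"{prefix_sample}{j}" for j in range(len(times))], name="sample_id")
    return PhenotypeTable(pd.DataFrame(d, index=idx))
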