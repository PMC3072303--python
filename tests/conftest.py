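import numpy as np
import pandas as pd
import pytest

from cadscore import ExpressionMatrix, simulate, validate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, genes=None, samples=None, scale="log2",
                platform="rtpcr"):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            scale=scale, platform=platform)


def make_samples(status, sex=None, age=None, **cols):
    n = len(status)
    df = pd.DataFrame({
        "status": status,
        "sex": sex if sex is not None else ["M"] * n,
        "age": age if age is not None else [60.0] * n,
        **cols,
    }, index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"))
    return validate_samples(df)


@pytest.fixture
def small_cohort():
    """200-sample cohort with one neutrophil-driven cluster carrying a

    sex-antagonistic CAD shift plus background genes."""
    cfg = simulate.SimulationConfig(
        n_samples=200, n_genes=40, seed=11,
        cluster_spec=[simulate.ClusterSpec("neut", 10, "neutrophil", 0.7),
                      simulate.ClusterSpec("lymph", 8, "lymphocyte_T", 0.7)],
        effect_spec=[simulate.EffectSpec("neut", 0.6, "antagonistic"),
                     simulate.EffectSpec("lymph", -0.5, "both")])
    return simulate.generate_cohort(cfg)
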