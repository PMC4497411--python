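import numpy as np
import pandas as pd
import pytest

from mirlineage.ct_preprocess import ExpressionMatrix
from mirlineage.synthetic_data import SyntheticConfig, gen_ct_plates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SyntheticConfig(n_probes=60, n_planted_per_subset=3, effect_size=3.0,
                           noise_sd=0.5, seed=11)


@pytest.fixture
def small_plates(small_config):
    return gen_ct_plates(small_config)


def make_expr(values: np.ndarray, subsets, species="mouse", probes=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a raw array and per-sample subset labels."""
    n_probes, n_samples = values.shape
    if probes is None:
        probes = [f"miR-{i:03d}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {"species": species, "subset": list(subsets), "replicate": range(n_samples)},
        index=pd.Index(samples, name="sample"),
    )
    vals = pd.DataFrame(values, index=probes, columns=samples)
    return ExpressionMatrix(values=vals, probe_class=pd.Series("target", index=vals.index),
                            sample_meta=meta, normalized=True)
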