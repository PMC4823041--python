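import numpy as np
import pytest

from mircuits import AnalysisConfig, ExpressionDataset
from mircuits.datasets import NEGATIVE, POSITIVE


@pytest.fixture
def cfg():
    return AnalysisConfig(rng_seed=1234)


def make_dataset(values, features=None, cohort_id="toy", classes=None,
                 kinds=None):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"f{i}" for i in range(n_feat)]
    samples = [f"s{i}" for i in range(n_samp)]
    if classes is None:
        half = n_samp // 2
        classes = [POSITIVE] * half + [NEGATIVE] * (n_samp - half)
    return ExpressionDataset(cohort_id, list(features), samples, values,
                             list(classes), dict(kinds or {}))


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(7)
    return make_dataset(rng.normal(8.0, 1.0, size=(5, 8)))
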