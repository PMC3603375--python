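import numpy as np
import pandas as pd
import pytest

from tsizesig.containers import ExpressionMatrix


def make_matrix(values, probe_ids=None, sample_ids=None, **kwargs) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probe_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    return ExpressionMatrix(values=df, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_labels():
    return np.array(["T1", "T1", "T1", "T2", "T2", "T2"])
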