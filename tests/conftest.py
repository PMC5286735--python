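import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lcasub as L

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def binary_codebook():
    return L.Codebook((
        L.VariableSpec(name="y", kind="nominal", domain="pain", levels=(0, 1),
                       severity_direction="higher_worse"),
    ))


@pytest.fixture
def mixed_codebook():
    return L.Codebook((
        L.VariableSpec(name="y", kind="nominal", domain="pain", levels=(0, 1)),
        L.VariableSpec(name="grade", kind="ordinal", domain="activity",
                       levels=(0, 1, 2)),
        L.VariableSpec(name="score", kind="continuous", domain="psychology",
                       range=(0.0, 10.0)),
    ))


def make_dataset(codebook, columns, index=None):
    df = pd.DataFrame(columns, index=index)
    for v in codebook.categorical:
        df[v.name] = df[v.name].astype(object)
    return L.Dataset(df, codebook, allow_all_missing_rows=True)


@pytest.fixture
def make_data():
    return make_dataset


def binary_model(codebook, pi, p1):
    """K-class model over a single binary variable: P(y=1|k) = p1[k]."""
    pi = np.asarray(pi, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    return L.LCAModel(
        codebook=codebook, K=len(pi), pi=pi,
        cat_probs={"y": np.column_stack([1 - p1, p1])},
        cont_means={}, cont_vars={},
    )


@pytest.fixture
def make_binary_model():
    return binary_model


def oracle_posteriors(model, data):
    """Direct Bayes-rule enumeration without log-space tricks.

    Independent of the package's likelihood path; used to pin the E-step.
    """
    from scipy.stats import norm

    cb = model.codebook
    out = np.zeros((data.n, model.K))
    for i, (_, row) in enumerate(data.df.iterrows()):
        joint = np.array(model.pi, dtype=float).copy()
        for v in cb:
            value = row[v.name]
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            for k in range(model.K):
                if v.is_categorical:
                    joint[k] *= model.cat_probs[v.name][k, v.levels.index(value)]
                else:
                    joint[k] *= norm.pdf(
                        float(value), model.cont_means[v.name][k],
                        np.sqrt(model.cont_vars[v.name][k]))
        out[i] = joint / joint.sum()
    return out
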