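import numpy as np
import pandas as pd
import pytest

from ruleout import Cohort, CohortSpec, FeatureCounts, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400-subject cohort with planted signal in every role, fast to fit."""
    spec = CohortSpec(
        n_pos=200,
        n_neg=200,
        features_per_category={
            "arterial_compliance": FeatureCounts(2, 1, 1, 4),
            "conduction": FeatureCounts(1, 1, 0, 6),
        },
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the study's class sizes and sex imbalance."""
    return generate_cohort(CohortSpec(seed=7))


def make_manual_cohort(n, rng, sex=None, label=None, n_features=4, feature_values=None):
    """Hand-built cohort for targeted ensemble tests."""
    ids = pd.Index([f"T{i:04d}" for i in range(n)], name="subject_id")
    if label is None:
        label = (np.arange(n) % 2).astype(int)
    if sex is None:
        sex = rng.integers(0, 2, n)
    if feature_values is None:
        feature_values = rng.standard_normal((n, n_features))
    cols = [f"f{j}" for j in range(feature_values.shape[1])]
    meta = pd.DataFrame({"category": "arterial_compliance", "role": "null"}, index=pd.Index(cols, name="feature_id"))
    return Cohort(
        features=pd.DataFrame(feature_values, index=ids, columns=cols),
        label=pd.Series(np.asarray(label, dtype=int), index=ids, name="label"),
        sex=pd.Series(np.asarray(sex, dtype=int), index=ids, name="sex"),
        covariates=pd.DataFrame(index=ids),
        feature_meta=meta,
    )
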