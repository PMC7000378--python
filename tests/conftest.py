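import numpy as np
import pandas as pd
import pytest

from roiclassify import SyntheticConfig, build_atlas, extract_features, generate_cohort
from roiclassify.atlasfeat import FeatureTable


@pytest.fixture(scope="session")
def small_atlas():
    return build_atlas((12, 12, 12), 6, seed=0)


@pytest.fixture(scope="session")
def tiny_cohort(small_atlas):
    cfg = SyntheticConfig(n_cases=6, n_controls=6, n_regions=6,
                          grid_dims=(12, 12, 12), effect_map={2: 0.3}, seed=5)
    return generate_cohort(cfg, small_atlas)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort, small_atlas):
    return extract_features(tiny_cohort, small_atlas)


def make_feature_table(n_subjects=40, n_regions=12, seed=0, effect_regions=(),
                       effect=8.0, prevalence=0.5):
    """Build a FeatureTable directly from Poisson counts, no volumes needed.

    ``effect_regions`` get their mean count raised by ``effect`` in cases.
    """
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_subjects) < prevalence).astype(int)
    # guarantee both classes are present
    labels[0], labels[1] = 1, 0
    base = rng.uniform(5, 30, size=n_regions)
    counts = rng.poisson(base, size=(n_subjects, n_regions)).astype(float)
    for r in effect_regions:
        counts[labels == 1, r - 1] += rng.poisson(effect,
                                                  size=int(labels.sum()))
    idx = pd.Index([f"s{i:03d}" for i in range(n_subjects)],
                   name="subject_id")
    cols = list(range(1, n_regions + 1))
    return FeatureTable(
        counts=pd.DataFrame(counts.astype(int), index=idx, columns=cols),
        labels=pd.Series(labels, index=idx, name="group"),
        covariates=pd.DataFrame(
            {"age": rng.uniform(25, 70, n_subjects),
             "sex": rng.integers(0, 2, n_subjects)}, index=idx),
    )
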