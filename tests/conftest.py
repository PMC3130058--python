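import numpy as np
import pytest

from tfinteract import (gen_interaction_study, gen_property_table,
                        make_stratified_folds, pair_feature_matrix)
from tfinteract.synthetic import SyntheticSpec, default_candidate_pool


@pytest.fixture(scope="session")
def small_table():
    """Four complete synthetic scales."""
    return gen_property_table(4, seed=11)


@pytest.fixture(scope="session")
def study():
    """The default planted-signal study (seed pinned)."""
    return gen_interaction_study(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def null_study():
    """Same study conditions with no planted effect."""
    return gen_interaction_study(SyntheticSpec(seed=0, effect_size=0.0))


@pytest.fixture(scope="session")
def study_matrix(study):
    """Feature matrix, labels, candidate pool and folds for the study."""
    X = pair_feature_matrix(study.pairs(), study.sequences,
                            study.table).to_numpy()
    y = np.array(study.labels())
    pool = default_candidate_pool(study)
    folds = make_stratified_folds(y, 10, seed=0)
    return X, y, pool, folds
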