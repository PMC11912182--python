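import numpy as np
import pytest

from connbench import evaluation as E
from connbench import synthdata as S
from connbench.cohort import CohortData


def tiny_generation_config(seed=0, d=1.5, **overrides):
    """A desk-scale cohort: ~200 participants, 276 edges, 202 structural features."""
    base = dict(
        n_rois=24,
        site_table=S.abide_like_site_table(0.25),
        n_informative_edges=20,
        n_informative_struct=10,
        effect_size_d=d,
        n_cortical=10,
        n_noncortical=16,
        seed=seed,
    )
    base.update(overrides)
    return S.GenerationConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    records, truth = S.generate_cohort(tiny_generation_config())
    return CohortData.from_records(records), truth


@pytest.fixture(scope="session")
def tiny_plan(tiny_cohort):
    data, _ = tiny_cohort
    return E.make_stratified_folds(data.y, data.sites, k=5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


SMALL_FEATURES = E.FeatureParams(k_fmri=80, k_smri=40, rfe_step=0.2)
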