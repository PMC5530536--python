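import numpy as np
import pytest

from ankle_ssm import (
    ShapeDataset,
    SyntheticSpec,
    default_scheme,
    generalized_procrustes,
    make_template,
    mirror_left_to_right,
    simulate_cohort,
)

# small, well-separated mode spectrum used by simulation-heavy tests
SDS8 = (3.0, 2.2, 1.6, 1.2, 0.9, 0.7, 0.55, 0.45)


def small_spec(seed, **overrides):
    """Compact 8-mode generator spec for fast simulation tests."""
    defaults = dict(
        n_participants=100,
        n_true_modes=8,
        mode_sds=SDS8,
        injury_mode_log_odds=(0.0,) * 8,
        race_injury_log_odds=0.0,
        race_mode1_shift=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def mirrored(dataset: ShapeDataset) -> ShapeDataset:
    """Mirror left ankles to right orientation (pre-GPA chirality fix)."""
    configs = [
        mirror_left_to_right(c) if c.side == "left" else c
        for c in dataset.configurations
    ]
    return ShapeDataset(
        scheme=dataset.scheme, configurations=configs, metadata=dataset.metadata
    )


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def template(scheme):
    return make_template(scheme)


@pytest.fixture(scope="session")
def cohort():
    """Default-spec cohort (study-sized, 19 true modes), with ground truth."""
    return simulate_cohort(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def aligned_cohort(cohort):
    dataset, _ = cohort
    return generalized_procrustes(mirrored(dataset))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
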