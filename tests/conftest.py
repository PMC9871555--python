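import numpy as np
import pandas as pd
import pytest

from pmifusion import (
    KineticsParams,
    StudyDesign,
    load_reference_catalog,
    simulate_cohort,
)
from pmifusion.peaks import FeatureMatrix


@pytest.fixture(scope="session")
def reference_catalog():
    return load_reference_catalog()


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign()


@pytest.fixture(scope="session")
def zero_noise_cohort(reference_catalog, default_design):
    """Training-study peak tables with no noise, jitter or dropout."""
    kinetics = KineticsParams(seed=11).zero_noise()
    return simulate_cohort(default_design, reference_catalog, kinetics)


def make_planted_matrix(
    n_per_class: int = 20,
    n_classes: int = 3,
    n_informative: int = 2,
    n_noise: int = 4,
    separation: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    organ: str = "kidney",
    cohort: str = "train",
    joint: bool = False,
) -> FeatureMatrix:
    """Feature matrix where only the first ``n_informative`` columns carry
    class signal (class-specific means ``separation`` apart); the rest are
    pure noise. With ``joint=True`` the class label is encoded in binary
    across the informative features (requires n_classes = 2**n_informative),
    so every informative feature is necessary for full separation."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    y = np.repeat(np.arange(n_classes), n_per_class)
    X = rng.normal(0, noise_sd, size=(n, n_informative + n_noise))
    for j in range(n_informative):
        if joint:
            assert n_classes == 2**n_informative
            X[:, j] += separation * ((y >> j) & 1)
        else:
            X[:, j] += separation * ((y + j) % n_classes)
    samples = [f"{cohort}_s{i:03d}" for i in range(n)]
    frame = pd.DataFrame(X, index=pd.Index(samples, name="sample_id"))
    frame.columns = list(range(1, n_informative + n_noise + 1))
    meta = pd.DataFrame(
        {
            "rat_id": [f"{cohort}_r{i:03d}" for i in range(n)],
            "organ": organ,
            "cohort": cohort,
        },
        index=frame.index,
    )
    return FeatureMatrix(
        X=frame, y=pd.Series(y, index=frame.index, name="pmi_day"), meta=meta, organ=organ
    )


@pytest.fixture
def planted_matrix():
    return make_planted_matrix
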