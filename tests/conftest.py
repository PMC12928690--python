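import numpy as np
import pandas as pd
import pytest

from cardioresp import ml, synth


@pytest.fixture(scope="session")
def clean_subject_spec():
    """Noise-free, jitter-free subject: deterministic ground truth."""
    return synth.SynthSubjectSpec(noise_sd_ms=0.0, resp_freq_jitter=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_subject(clean_subject_spec):
    return synth.gen_subject(clean_subject_spec, subject_id="clean", label=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but class-separable cohort for ML harness tests."""
    spec = synth.SynthCohortSpec(n_case=6, n_control=5, seed=3)
    return synth.gen_cohort(spec)


def make_feature_table(n_major: int, n_minor: int, n_features: int = 4, seed: int = 0,
                       separation: float = 0.0) -> ml.FeatureTable:
    """Random nondegenerate feature table with a given class imbalance.

    ``separation`` shifts the majority class mean to control class
    overlap (0 = indistinguishable, >> 1 = separable).
    """
    rng = np.random.default_rng(seed)
    x_maj = rng.standard_normal((n_major, n_features)) + separation
    x_min = rng.standard_normal((n_minor, n_features))
    x = np.vstack([x_maj, x_min])
    y = np.array([1] * n_major + [0] * n_minor)
    idx = [f"s{i:03d}" for i in range(n_major + n_minor)]
    cols = [f"f{j}" for j in range(n_features)]
    return ml.FeatureTable(pd.DataFrame(x, index=idx, columns=cols), pd.Series(y, index=idx))


@pytest.fixture
def imbalanced_table():
    """The study's 18-majority / 11-minority configuration."""
    return make_feature_table(18, 11, seed=42)
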