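import numpy as np
import pytest
from hypothesis import settings

from bohdf.model import evaluate
from bohdf.pipeline import PipelineConfig, extract_features, features_to_arrays
from bohdf.synthetic import generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    """The default synthetic study conditions: 3 classes with distinct bands,
    8 channels, 200 Hz, 10 s trials, mock deep backend, k_per_class = 8."""
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return generate_dataset(default_config.synthetic_spec(), 30)


@pytest.fixture(scope="session")
def default_features(default_config, default_dataset):
    """Raw feature table of the default synthetic dataset, extracted once and
    shared by the end-to-end tests."""
    df = extract_features(default_dataset, default_config)
    X, y, trial_ids = features_to_arrays(df)
    return df, X, y, trial_ids


@pytest.fixture(scope="session")
def default_cv_report(default_config, default_features):
    _, X, y, _ = default_features
    from bohdf.model import BoHDFClassifier

    est = BoHDFClassifier(k_per_class=default_config.k_per_class,
                          seed=default_config.seed)
    return evaluate(X, y, estimator=est, n_splits=5, seed=default_config.seed)


@pytest.fixture(scope="session")
def rendered_image(default_dataset, default_config):
    """One rendered 224x224 spectrogram image from the default dataset."""
    from bohdf.preprocess import bandpass_filter
    from bohdf.spectrogram import compute_stft, render_image

    trial = bandpass_filter(default_dataset[0], default_config.filter)
    spec = compute_stft(trial.samples[0], trial.fs, default_config.stft)
    return render_image(spec, default_config.stft)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
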