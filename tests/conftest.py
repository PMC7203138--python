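import numpy as np
import pytest

from cohdecode import FeatureTensor, TargetSet, TrialSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_features(data: np.ndarray, fs: float = 200.0) -> FeatureTensor:
    """Wrap a (trials, features, samples) array as an LFC FeatureTensor."""
    n_feat = data.shape[1]
    return FeatureTensor(data=data, fs=fs,
                         feature_ids=[(f"ch{j:02d}", "LFC") for j in range(n_feat)])


def make_targets(data: np.ndarray, fs: float = 200.0) -> TargetSet:
    return TargetSet(data=data, fs=fs, modality="synthetic")


def make_trials(data: np.ndarray, fs: float = 1000.0) -> TrialSet:
    return TrialSet(data=data, fs=fs, labels=[f"t{i}" for i in range(data.shape[0])])
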