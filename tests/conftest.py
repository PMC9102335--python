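import numpy as np
import pytest

from cnsvm.model_core import build_model, compact_config
from cnsvm.spectra_io import SpectralWindow, crop_to_window
from cnsvm.svm_head import SVMHeadConfig, fit_head
from cnsvm.synthetic_data import SimulationConfig, simulate_signatures
from cnsvm.train_engine import TrainConfig, fit, stratified_split


def quick_separable_config(seed: int = 3) -> SimulationConfig:
    """Small, strongly separable dataset for fast model-level tests."""
    return SimulationConfig(
        n_bcc=120,
        n_healthy=120,
        n_patients=12,
        effect_size=12.0,
        patient_sd=0.5,
        noise_sd=0.5,
        shadow_prob=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def separable_sets():
    """Cropped train/test split of a strongly separable synthetic sample."""
    s = crop_to_window(simulate_signatures(quick_separable_config()), SpectralWindow.default())
    train, test = stratified_split(s, 0.70, seed=3)
    return train, test


@pytest.fixture(scope="session")
def trained_backbone(separable_sets):
    """Compact backbone trained 25 epochs on the separable training split."""
    train, _ = separable_sets
    handle = build_model(compact_config(), seed=3)
    handle, log = fit(handle, train, TrainConfig(epochs=25, batch_size=32, seed=3))
    return handle, log


@pytest.fixture(scope="session")
def hybrid_model(trained_backbone, separable_sets):
    """Radial-kernel hybrid fitted on the trained backbone's features."""
    train, _ = separable_sets
    handle, _ = trained_backbone
    return fit_head(handle, train, SVMHeadConfig(kernel="radial", gamma=0.1), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
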