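"""Bayesian tuning of the SVM activation layer with TPE.

Extracts penultimate-layer features from a quickly trained backbone and
searches kernel family, soft-margin C, kernel width gamma and polynomial
degree for the best 10-fold cross-validated accuracy, using the
Tree-structured Parzen Estimator with expected-improvement selection.
"""

from cnsvm import (
    SimulationConfig,
    SpectralWindow,
    TrainConfig,
    build_model,
    compact_config,
    crop_to_window,
    extract_features,
    fit,
    optimize,
    simulate_signatures,
)
from cnsvm.hyper_opt import default_head_space
from cnsvm.svm_head import SVMHeadConfig, cross_val_accuracy

SEED = 2
N_ITER = 30  # the published experiments ran 100 iterations

signatures = crop_to_window(
    simulate_signatures(SimulationConfig(n_bcc=150, n_healthy=150, seed=SEED)),
    SpectralWindow.default(),
)
backbone = build_model(compact_config(), seed=SEED)
backbone, _ = fit(backbone, signatures, TrainConfig(epochs=25, seed=SEED))
features = extract_features(backbone, signatures)
labels = signatures.labels


def objective(config):
    head = SVMHeadConfig(
        kernel=config["kernel"], C=config["C"], gamma=config["gamma"],
        degree=int(config["degree"]),
    )
    return cross_val_accuracy(features, labels, head, seed=SEED)


best, history = optimize(objective, default_head_space(), n_iter=N_ITER, seed=SEED)
print(f"evaluated {len(history)} configurations")
print(f"best head: kernel={best['kernel']}  C={best['C']:.3g}  "
      f"gamma={best['gamma']:.3g}  degree={best['degree']}")
print(f"best 10-fold CV accuracy: {history.best().value:.3f}")
print("best-so-far trace (every 5th trial):",
      [f"{v:.3f}" for v in history.best_so_far()[::5]])
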