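"""Synthetic hyperspectral skin signatures with the statistical structure of
the clinical data.

The generator emulates the features that matter to the classifier rather
than skin optics: two classes whose mean spectra differ only inside the
discriminative 573.45-779.88 nm window (healthy reflecting more than tumour
tissue there), a per-patient random offset shared by all of a patient's
signatures, additive per-channel sensor noise, and occasional multiplicative
shadow events that scale a whole spectrum down uniformly — the illumination
failure mode that makes shadowed healthy skin resemble tumour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cnsvm.errors import ConfigError, ShapeError
from cnsvm.spectra_io import HyperCube, SignatureSet, SpectralWindow, WavelengthGrid

#: Fraction of the window half-width over which the class effect ramps
#: from zero (at the window edge) to its full size (cosine taper).
EDGE_TAPER_FRACTION = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the simulator.

    The class counts (504 BCC / 488 healthy) and the number of patients (41)
    match the clinical sample; effect size, patient and noise standard
    deviations and the shadow regime are calibration choices documented in
    the methods note.  All values are in reflectance percent.
    """

    n_bcc: int = 504
    n_healthy: int = 488
    n_patients: int = 41
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.default)
    window: SpectralWindow = field(default_factory=SpectralWindow.default)
    effect_size: float = 6.0
    patient_sd: float = 1.5
    noise_sd: float = 1.0
    shadow_prob: float = 0.1
    shadow_range: tuple[float, float] = (0.5, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bcc < 0 or self.n_healthy < 0:
            raise ConfigError("signature counts must be >= 0")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.patient_sd < 0 or self.noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not 0.0 <= self.shadow_prob <= 1.0:
            raise ConfigError("shadow_prob must lie in [0, 1]")
        lo, hi = self.shadow_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ConfigError("shadow_range must satisfy 0 < min <= max <= 1")


def _effect_profile(grid: WavelengthGrid, window: SpectralWindow) -> np.ndarray:
    """Class-difference shape: 0 outside the window, 1 over the inner 80%,
    cosine ramps over the outer 10% at each edge."""
    wl = grid.values
    width = window.high_nm - window.low_nm
    ramp = EDGE_TAPER_FRACTION * width
    profile = np.zeros_like(wl)
    inside = (wl >= window.low_nm) & (wl <= window.high_nm)
    dist_to_edge = np.minimum(wl - window.low_nm, window.high_nm - wl)
    in_ramp = inside & (dist_to_edge < ramp)
    profile[inside] = 1.0
    profile[in_ramp] = 0.5 * (1 - np.cos(np.pi * dist_to_edge[in_ramp] / ramp))
    return profile


def baseline_spectrum(
    grid: WavelengthGrid,
    class_label: int,
    window: SpectralWindow | None = None,
    effect_size: float = 6.0,
) -> np.ndarray:
    """Deterministic mean reflectance curve (percent) for one class.

    Healthy skin follows a smooth sigmoidal rise through the red/NIR (skin
    reflects more at longer wavelengths); the tumour curve equals it outside
    the window and sits ``effect_size`` percent lower at the window centre,
    tapering smoothly to zero difference at the window edges.
    """
    if window is None:
        window = SpectralWindow.default()
    wl = grid.values
    healthy = 20.0 + 35.0 / (1.0 + np.exp(-(wl - 620.0) / 55.0))
    if class_label == 0:
        curve = healthy
    elif class_label == 1:
        centre_scale = _effect_profile(grid, window)
        # The profile is 1 at the centre by construction, so the mean
        # difference at the window centre is exactly effect_size.
        curve = healthy - effect_size * centre_scale
    else:
        raise ConfigError(f"class_label must be 0 or 1, got {class_label}")
    return np.clip(curve, 0.0, 100.0)


def _draw_signatures(
    cfg: SimulationConfig, labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample reflectance rows for the given label vector.

    Each signature: (class baseline + patient offset + channel noise) scaled
    by a shadow factor drawn with probability ``shadow_prob``.  Patients are
    assigned round-robin; their scalar offsets are drawn once.
    """
    n = labels.size
    baselines = np.stack(
        [
            baseline_spectrum(cfg.grid, 0, cfg.window, cfg.effect_size),
            baseline_spectrum(cfg.grid, 1, cfg.window, cfg.effect_size),
        ]
    )
    patient_offsets = rng.normal(0.0, cfg.patient_sd, size=cfg.n_patients)
    patient_idx = np.arange(n) % cfg.n_patients
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, cfg.grid.n_channels))
    shadowed = rng.random(n) < cfg.shadow_prob
    factors = np.ones(n)
    factors[shadowed] = rng.uniform(*cfg.shadow_range, size=int(shadowed.sum()))
    spectra = baselines[labels] + patient_offsets[patient_idx, None] + noise
    spectra *= factors[:, None]
    patient_ids = np.array([f"P{idx:03d}" for idx in patient_idx], dtype=object)
    return spectra, patient_ids


def simulate_signatures(cfg: SimulationConfig) -> SignatureSet:
    """Generate a labelled signature set, fully reproducible from ``cfg.seed``.

    BCC signatures (label 1) come first, then healthy (label 0), matching the
    simple blocked layout of the deposited tables; downstream splits shuffle.
    """
    n = cfg.n_bcc + cfg.n_healthy
    if n < 1:
        raise ConfigError("n_bcc + n_healthy must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    labels = np.concatenate(
        [np.ones(cfg.n_bcc, dtype=np.int64), np.zeros(cfg.n_healthy, dtype=np.int64)]
    )
    spectra, patient_ids = _draw_signatures(cfg, labels, rng)
    return SignatureSet(cfg.grid, spectra, labels, patient_ids)


def simulate_cube(
    cfg: SimulationConfig,
    shape: tuple[int, int],
    tumor_mask: np.ndarray,
) -> tuple[HyperCube, np.ndarray]:
    """Generate a cube whose pixels are class draws dictated by ``tumor_mask``.

    Returns the cube and a copy of the ground-truth mask.  Pixel (r, c) uses
    the BCC baseline where ``tumor_mask[r, c]`` is truthy.
    """
    rows, cols = shape
    mask = np.asarray(tumor_mask)
    if mask.shape != (rows, cols):
        raise ConfigError(
            f"tumor_mask shape {mask.shape} does not match cube shape {(rows, cols)}"
        )
    rng = np.random.default_rng(cfg.seed)
    labels = mask.reshape(-1).astype(np.int64)
    spectra, _ = _draw_signatures(cfg, labels, rng)
    cube = HyperCube(cfg.grid, spectra.reshape(rows, cols, cfg.grid.n_channels))
    return cube, (mask != 0).astype(np.int64)


def separable_config(seed: int = 0) -> SimulationConfig:
    """Strongly separable regime (large effect, little noise, no shadows),
    used for parameter-recovery style checks such as segmentation."""
    return SimulationConfig(
        effect_size=12.0,
        patient_sd=0.5,
        noise_sd=0.5,
        shadow_prob=0.0,
        seed=seed,
    )
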