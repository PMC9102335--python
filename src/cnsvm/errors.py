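"""Exception hierarchy shared across the package."""


class CNSVMError(Exception):
    """Base class for all package errors."""


class FormatError(CNSVMError):
    """Malformed input file (ragged rows, non-numeric values, bad header)."""


class LabelError(CNSVMError):
    """Missing label column or labels outside the binary {0, 1} domain."""


class MetadataError(CNSVMError):
    """Required file metadata (e.g. ENVI wavelengths) absent or inconsistent."""


class WindowError(CNSVMError):
    """Spectral window does not intersect the wavelength grid."""


class ConfigError(CNSVMError):
    """Invalid configuration object."""


class ShapeError(CNSVMError):
    """Array shapes incompatible with the operation's contract."""


class TrainingError(CNSVMError):
    """Training preconditions violated (e.g. unlabelled data)."""


class DivergenceError(TrainingError):
    """Non-finite loss encountered during optimisation."""


class StratificationError(CNSVMError):
    """A class has too few members for the requested split or fold count."""


class CVError(StratificationError):
    """Cross-validation fold count exceeds the smallest class size."""


class UndefinedMetricError(CNSVMError):
    """Metric undefined for the given inputs (e.g. one class absent)."""


class OptimizationError(CNSVMError):
    """Hyperparameter search failed (e.g. every trial non-finite)."""
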