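"""Typed exceptions raised across the package."""


class AnnealClustError(Exception):
    """Base class for all package errors."""


class MatrixIOError(AnnealClustError):
    """Malformed or inconsistent expression-matrix input/output."""


class PreprocessingError(AnnealClustError):
    """Invalid input to normalization / dimensionality reduction."""


class GraphError(AnnealClustError):
    """Invalid shared-nearest-neighbor graph construction or content."""


class BQMError(AnnealClustError):
    """Invalid binary quadratic model parameters or evaluation input."""


class SamplerError(AnnealClustError):
    """Sampler misuse (bad schedule, size limits, ...)."""


class BackendUnavailableError(SamplerError):
    """A sampling backend cannot be reached; never silently fall back."""


class SampleSetValidationError(SamplerError):
    """A backend returned a sample set violating the SampleSet contract."""


class ClusteringError(AnnealClustError):
    """Recursive clustering / gamma tuning failure."""


class SimulationError(AnnealClustError):
    """Infeasible synthetic-data specification."""
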