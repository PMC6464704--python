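"""Exception hierarchy shared across the pipeline stages."""


class SynaptodevError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SynaptodevError, ValueError):
    """A simulation or analysis parameter is invalid; message names the field."""


class DegenerateInputError(SynaptodevError, ValueError):
    """Input is structurally valid but degenerate (all-zero trace, zero cytosol...)."""


class FitError(SynaptodevError, RuntimeError):
    """Nonlinear fit failed to converge; carries solver diagnostics."""


class GeometryError(SynaptodevError, ValueError):
    """An ROI falls outside the image bounds."""


class BaselineError(SynaptodevError, ValueError):
    """Baseline fluorescence is non-positive, so ΔF/F0 is undefined."""


class ConfigError(SynaptodevError, KeyError):
    """A required configuration entry (e.g. a channel threshold) is missing."""


class PlacementError(SynaptodevError, RuntimeError):
    """Synthetic puncta could not be placed after bounded retries."""


class InferenceError(SynaptodevError, ValueError):
    """Group-comparison preconditions (replicates, design) are not met."""
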