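"""Exception hierarchy for the spherohca pipeline."""


class SpheroHCAError(Exception):
    """Base class for all spherohca errors."""


class ValidationError(SpheroHCAError):
    """Invalid experimental design, layout or argument."""


class GeometryError(SpheroHCAError):
    """Unsupported plate geometry or mismatched image shapes."""


class DilutionError(SpheroHCAError):
    """Infeasible dilution plan (stock weaker than working solution)."""


class NoObjectError(SpheroHCAError):
    """No segmented object available for the requested measurement."""


class InsufficientDataError(SpheroHCAError):
    """Too few timepoints / replicates / densities for the analysis."""


class FitError(SpheroHCAError):
    """Nonlinear fit failed to converge across all starts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NormalizationError(SpheroHCAError):
    """Degenerate control (vehicle mean not positive after blanking)."""
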