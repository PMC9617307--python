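"""Exception hierarchy for the mrlap package."""


class MrlapError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleGeometryError(MrlapError):
    """The descent-interval ratio admits no non-negative LAP solution."""


class ConvergenceError(MrlapError):
    """The LAP root finder failed to converge within its bracket/budget."""


class InfeasiblePhysiologyError(MrlapError):
    """Requested hemodynamic state cannot produce a regurgitant jet."""


class EmptySignalError(MrlapError):
    """Spectrogram contains no jet signal at all."""


class RefinementError(MrlapError):
    """Too few valid envelope columns to fit the refinement model."""


class RuleViolationError(MrlapError):
    """Envelope fails a calculability rule (peak < 3 m/s, incomplete descent)."""

    def __init__(self, reasons):
        self.reasons = tuple(reasons)
        super().__init__("; ".join(self.reasons))


class CalibrationError(MrlapError):
    """Axis calibration is inconsistent with the pixel grid."""


class UndefinedCorrelationError(MrlapError):
    """Correlation requested on a constant input."""


class DegenerateTableError(MrlapError):
    """Contingency table has a zero marginal."""


class MissingDataError(MrlapError):
    """Rating grid is incomplete."""


class AlignmentError(MrlapError):
    """Estimate and reference tables share no case identifiers."""


class ConfigError(MrlapError):
    """Invalid run or cohort configuration."""
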