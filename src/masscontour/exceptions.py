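"""Exception and warning types shared across the package."""


class MassContourError(Exception):
    """Base class for all masscontour errors."""


class ChainCodeError(MassContourError):
    """Malformed Freeman chain code (unknown code, empty sequence, ...)."""


class OpenPathError(ChainCodeError):
    """A traced chain-code path does not return to its start pixel."""

    def __init__(self, terminal, start):
        self.terminal = tuple(terminal)
        self.start = tuple(start)
        super().__init__(
            f"chain code does not close: path ends at {self.terminal}, "
            f"start is {self.start}"
        )


class DegenerateContourError(MassContourError):
    """Contour collapses onto a line or point (a bounding diameter is 0)."""


class InsufficientDataError(MassContourError):
    """A signature or subsection is too short for the requested statistic."""


class DegenerateSignalError(MassContourError):
    """Zero-variance signature where a normalized quantity is undefined."""


class FitError(MassContourError):
    """Log-log power-law fit has too few usable lags."""


class ParameterError(MassContourError):
    """Invalid parameter combination (self-intersecting contour spec, ...)."""


class MissingLabelError(MassContourError):
    """A contour id has no pathology label in the manifest."""


class RegularSignatureWarning(UserWarning):
    """sigma = 0: the mu/sigma circularity ratio was capped."""


class SubsectionSkippedWarning(UserWarning):
    """An infeasible subsection count C was skipped for a short signature."""


class EmbeddingFallbackWarning(UserWarning):
    """Circulant embedding was not positive definite; spectral fallback used."""
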