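"""Exception types shared across the pipeline."""


class HerfretError(Exception):
    """Base class for package errors."""


class InsufficientPhotonsError(HerfretError, ValueError):
    """Histogram carries fewer photons than the configured minimum."""


class NoEvaluablePixelsError(HerfretError, RuntimeError):
    """No pixel survived intensity thresholding, convergence and filtering."""


class CoreExcludedError(HerfretError, RuntimeError):
    """A donor / donor+acceptor core pair could not yield a FRET estimate.

    Mirrors the exclusion of unusable tissue cores from downstream survival
    modelling; carries a human-readable reason.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class EquilibriumError(HerfretError, RuntimeError):
    """The mass-action equilibrium solver failed to converge."""


class FormatError(HerfretError, ValueError):
    """On-disk artifact is inconsistent with its metadata sidecar."""
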