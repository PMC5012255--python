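"""Exception hierarchy for the clotqcm pipeline."""


class ClotQCMError(Exception):
    """Base class for all clotqcm errors."""


class FlatSpectrumError(ClotQCMError):
    """Conductance spectrum has no interior resonance peak to fit."""


class FitError(ClotQCMError):
    """Nonlinear least-squares resonance fit did not converge.

    Carries the solver diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class NoResponseError(ClotQCMError):
    """Starred shift series never rises above its loading baseline."""


class DegenerateThresholdError(ClotQCMError):
    """Image is constant; a mean-intensity threshold cannot split it."""


class ConfigError(ClotQCMError):
    """Pipeline configuration invalid or incomplete."""
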