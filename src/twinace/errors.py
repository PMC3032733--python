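"""Exception hierarchy for twinace.

All package errors derive from :class:`TwinAceError` so callers can catch
one base class at pipeline boundaries.
"""


class TwinAceError(Exception):
    """Base class for all twinace errors."""


class ConfigError(TwinAceError):
    """Invalid or inconsistent configuration."""


class InvalidModelError(TwinAceError):
    """A model's implied covariance structure is invalid (e.g. not PSD)."""


class ParseError(TwinAceError):
    """A cohort file could not be parsed; message carries the row number."""


class DegenerateScaleError(TwinAceError):
    """A phenotype has (numerically) zero variance and cannot be standardized."""


class RankDeficiencyError(TwinAceError):
    """Collinear covariates in a residualization regression."""


class InsufficientDataError(TwinAceError):
    """Too few complete observations for the requested statistic."""


class ConvergenceError(TwinAceError):
    """Likelihood optimization failed; carries diagnostics."""

    def __init__(self, message, loglik=None, grad_norm=None):
        super().__init__(message)
        self.loglik = loglik
        self.grad_norm = grad_norm


class ProfileError(TwinAceError):
    """Profile-likelihood bound could not be bracketed; carries diagnostics."""


class UndefinedCorrelationError(TwinAceError):
    """A genetic correlation is undefined (zero genetic variance)."""
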