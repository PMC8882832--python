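"""Exception hierarchy shared across the package."""


class BiopsyReduceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BiopsyReduceError, ValueError):
    """An input value violated a documented invariant."""


class FitError(BiopsyReduceError, RuntimeError):
    """Logistic model fitting failed (separation, singular design, too few data)."""


class StratificationError(BiopsyReduceError, ValueError):
    """Risk scores cannot be split into quintile layers."""


class EligibilityError(BiopsyReduceError, ValueError):
    """Patient does not meet the inclusion criteria of the recommendation model."""


class GenerationError(BiopsyReduceError, RuntimeError):
    """Synthetic cohort generation failed (e.g. rejection-sampling cap exceeded)."""


class CohortParseError(BiopsyReduceError, ValueError):
    """A cohort CSV could not be parsed; carries row-level messages."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
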