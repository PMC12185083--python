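"""Exception hierarchy for the spry package."""


class SpryError(Exception):
    """Base class for all package errors."""


class ConfigError(SpryError):
    """A configuration value is invalid; the message names the field."""


class DesignError(SpryError):
    """A randomization/design input is inconsistent with the arm set."""


class EligibilityError(SpryError):
    """A patient does not meet the trial's eligibility rules."""


class EndpointUndefinedError(SpryError):
    """The requested endpoint is undefined for this hospital course."""


class DataIntegrityError(SpryError):
    """Patient-level tables are inconsistent (e.g., duplicated ids)."""


class DegenerateDataError(SpryError):
    """The outcome data cannot identify the model (e.g., disjoint supports)."""


class ConvergenceError(SpryError):
    """The posterior sampler failed its diagnostics.

    The partially fitted results object is attached as ``.results`` so the
    draws remain available for inspection.
    """

    def __init__(self, message, results=None):
        super().__init__(message)
        self.results = results
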