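"""Exception hierarchy for jointmsm."""


class JointMSMError(Exception):
    """Base class for all jointmsm errors."""


class SpecError(JointMSMError):
    """A model specification is internally inconsistent."""


class MissingCovariateError(JointMSMError):
    """A covariate named in the design was not supplied."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"covariate {name!r} required by the design is missing")


class DataValidityError(JointMSMError):
    """Panel data violate a structural invariant (e.g. damage reversal)."""


class FitError(JointMSMError):
    """Model fitting failed in a way that cannot be reported as a result."""
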