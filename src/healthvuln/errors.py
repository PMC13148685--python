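"""Exception hierarchy for the healthvuln package."""


class HealthVulnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HealthVulnError):
    """A configuration problem: missing column, mismatched factors, bad bands."""


class ValidationError(HealthVulnError, ValueError):
    """An input value violates a documented constraint."""


class DegenerateVariableError(HealthVulnError):
    """An ordinal variable has fewer than two observed categories."""


class InconsistencyError(HealthVulnError):
    """A recovered quantity is not consistent with its stated provenance
    (e.g. a backed-out exposure level is not close to an integer)."""
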