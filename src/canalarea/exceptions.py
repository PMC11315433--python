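"""Exception hierarchy for canalarea.

All package errors derive from :class:`CanalAreaError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal bad
input values rather than programming faults.
"""


class CanalAreaError(Exception):
    """Base class for all canalarea errors."""


class SchemaError(CanalAreaError, ValueError):
    """A required column is missing from an input table."""


class ValidationError(CanalAreaError, ValueError):
    """A row or field violates the measurement-data invariants."""


class ParameterError(CanalAreaError, ValueError):
    """A simulation or model parameter is outside its admissible range."""


class FittingError(CanalAreaError, ValueError):
    """A coefficient fit is impossible on the given data (degenerate level)."""


class ConfigurationError(CanalAreaError, ValueError):
    """A run configuration is inconsistent (e.g. missing level coefficient)."""
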