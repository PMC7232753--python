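"""Exception hierarchy.

All package errors derive from :class:`ProbeneError` so callers can catch
one base class; subclasses distinguish user-input problems from study-design
problems that make a quantity unidentifiable.
"""


class ProbeneError(Exception):
    """Base class for all errors raised by probene."""


class ConfigurationError(ProbeneError, ValueError):
    """Invalid scenario, preset name, or run configuration."""


class DesignError(ProbeneError, ValueError):
    """The experimental design cannot identify the requested quantity
    (e.g. a single group level, constant density within a group)."""


class DomainError(ProbeneError, ValueError):
    """A value outside its scientific domain (e.g. negative raw density)."""


class DiagnosticError(ProbeneError, ValueError):
    """A diagnostic cannot be computed (e.g. zero-width density range)."""


class FormatError(ProbeneError, ValueError):
    """Malformed input file: missing columns or unparseable values."""
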