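"""Exception hierarchy.

All package-specific failures derive from :class:`MycoforestError` so callers
can catch one base class; most also derive from :class:`ValueError` because
they signal invalid inputs rather than internal faults.
"""


class MycoforestError(Exception):
    """Base class for all mycoforest errors."""


class ConfigurationError(MycoforestError, ValueError):
    """Invalid simulation or run configuration."""


class SchemaError(MycoforestError, ValueError):
    """An input table is missing required columns or has unparseable values."""


class ReferentialIntegrityError(MycoforestError, ValueError):
    """A foreign key (e.g. a stem's species_id) does not resolve."""


class DomainError(MycoforestError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class ImputationError(MycoforestError, ValueError):
    """A trait cannot be imputed because no species carries a value for it."""


class StagingError(MycoforestError, ValueError):
    """Too few plots to assign successional stages."""


class SpecificationError(MycoforestError, ValueError):
    """A model specification is inconsistent (e.g. interaction without main effect)."""


class DegenerateInputError(MycoforestError, ValueError):
    """Zero-variance or otherwise degenerate numerical input."""
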