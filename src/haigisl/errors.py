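"""Exception hierarchy for the vergence optics and cohort I/O layers."""


class HaigislError(Exception):
    """Base class for all package-specific errors."""


class SingularVergenceError(HaigislError):
    """A vergence denominator is zero (or numerically indistinguishable from it)."""


class GeometryError(HaigislError):
    """Physically impossible model-eye geometry, e.g. lens plane behind the retina."""


class MissingFieldError(HaigislError):
    """A required measurement is absent from a case record."""


class DegenerateSeriesError(HaigislError):
    """A statistical operation received a constant or too-short series."""


class SchemaError(HaigislError):
    """A cohort table is missing a required column or a cell fails to parse."""
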