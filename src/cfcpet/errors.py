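"""Exception hierarchy shared across the pipeline stages."""


class CfcPetError(Exception):
    """Base class for all package errors."""


class ParseError(CfcPetError):
    """A polar-map or table file could not be parsed; names the offending line/field."""


class GeometryError(CfcPetError):
    """Pixel count or ring/sector layout does not match the LV grid."""


class ValidationError(CfcPetError):
    """Input values violate a domain invariant (negative perfusion, bad fractions, ...)."""


class EmptyMapError(CfcPetError):
    """An operation that needs at least one valid pixel received none."""


class AnalysisError(CfcPetError):
    """A statistical fit could not be computed (no events, separation, rank deficiency)."""


class ConfigError(CfcPetError):
    """Pipeline configuration is missing or inconsistent."""
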