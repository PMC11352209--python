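"""Exception hierarchy shared across the package."""


class SersdxError(Exception):
    """Base class for all package errors."""


class ValidationError(SersdxError):
    """A dataset, manifest, or domain object violates an invariant."""


class FormatError(SersdxError):
    """An input file is malformed (bad header, wrong columns, ...)."""


class ConfigError(SersdxError):
    """A configuration value violates its constraints."""


class DegenerateInputError(SersdxError):
    """The input is valid but the operation is undefined on it
    (constant spectrum under min-max normalization, empty crop, ...)."""


class UndefinedMetricError(SersdxError):
    """A performance metric has an empty denominator."""
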