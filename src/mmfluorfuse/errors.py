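"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A table or record is missing required columns/parameters."""


class ParseError(ValueError):
    """A cell could not be parsed; message names the offending row."""


class DimensionError(ValueError):
    """An array has an incompatible shape for the requested operation."""


class ConfigError(ValueError):
    """A configuration file or object violates its contract."""


class DataError(ValueError):
    """A dataset-level invariant is violated (counts, splits, labels)."""
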