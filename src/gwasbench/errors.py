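"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value or combination of values is invalid."""


class ColumnMappingError(ConfigurationError):
    """A mandatory column named in the column mapping is absent from the file."""


class PlacementError(RuntimeError):
    """Synthetic placement constraints cannot be satisfied on the given genome."""
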