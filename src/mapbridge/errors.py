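"""Exception hierarchy."""


class MapbridgeError(Exception):
    """Base class for package errors."""


class MapFormatError(MapbridgeError):
    """A file could not be parsed into the expected layout."""


class MapValidationError(MapbridgeError):
    """Parsed data violates an invariant (duplicate ids, bad coordinates...)."""


class ConfigError(MapbridgeError):
    """Invalid configuration (unknown arm, bad rate, inconsistent tree)."""
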