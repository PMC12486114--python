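"""Exception hierarchy shared across the package."""


class NeuromodError(Exception):
    """Base class for package-specific failures."""


class ConfigurationError(NeuromodError):
    """A configuration or registry request is invalid (e.g. missing ROI channels)."""


class DataError(NeuromodError):
    """Input data violates a precondition (too short, degenerate, missing channel)."""
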