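"""Exception hierarchy used across the package."""


class OxstrataError(Exception):
    """Base class for package errors."""


class InvalidConfigError(OxstrataError, ValueError):
    """A configuration value violates its constraints."""


class MetadataError(OxstrataError, KeyError):
    """Required per-cell or per-sample metadata is missing."""


class EmptyGeneSetError(OxstrataError, ValueError):
    """A gene set is empty after intersecting with the measured genes."""


class DegenerateDataError(OxstrataError, ValueError):
    """Input data is degenerate for the requested computation."""
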