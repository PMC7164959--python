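"""Exception hierarchy shared across the toolkit."""


class McartError(Exception):
    """Base class for all toolkit errors."""


class FormatError(McartError):
    """A file violates its format contract (names the offending field)."""


class GeometryError(McartError):
    """A mesh/plane operation received degenerate or invalid geometry."""


class SamplingError(McartError):
    """Density sampling failed (e.g. surface/volume mismatch)."""


class PackingError(McartError):
    """Random placement could not satisfy the non-overlap constraint."""
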