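"""Exception types shared across the package."""


class VcohortError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VcohortError):
    """A surface or table file could not be parsed."""


class GeometryError(VcohortError):
    """Input geometry is degenerate for the requested operation."""


class GenerationError(VcohortError):
    """Virtual-shape generation failed (e.g. repeated plausibility rejection)."""
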