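"""Exception hierarchy for the phenotyping pipeline."""


class TrichophenoError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TrichophenoError):
    """Malformed input file (missing column, non-monotone frame index, ...)."""


class DesignError(TrichophenoError):
    """Inconsistent experimental design (broken subline nesting, duplicates)."""


class GeometryError(TrichophenoError):
    """Point outside the arena, or invalid arena configuration."""


class DegenerateInputError(TrichophenoError):
    """Input too small or empty for the requested computation."""


class FitError(TrichophenoError):
    """Model fitting failed (singular design, non-convergence)."""
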