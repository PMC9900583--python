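"""Exception hierarchy shared across the package."""


class PepspecError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PepspecError):
    """A file did not parse under its declared format."""


class ValidationError(PepspecError, ValueError):
    """An input violated a documented invariant."""


class PeptideStructureError(PepspecError):
    """The molecule is not a linear peptide with free NH2/COOH termini."""


class DegenerateGeometryError(PepspecError):
    """Geometry is degenerate (e.g. collinear points in a dihedral)."""


class CoverageError(PepspecError):
    """A grid does not cover the region required by an operation."""


class UndefinedSimilarityError(PepspecError):
    """Similarity is undefined (zero-variance spectrum)."""


class InfiniteDepletionError(PepspecError):
    """All parent ions depleted; the cross-section estimate diverges."""


class InstabilityError(PepspecError):
    """Numerical integration diverged (energy blow-up or unstable step)."""


class UnstableStepError(InstabilityError):
    """Time step beyond the stability limit of the integrator."""


class FixtureError(PepspecError):
    """A synthetic fixture request cannot be realized."""


class ConvergenceError(PepspecError):
    """An iterative numerical procedure failed to converge."""
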