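"""Exception hierarchy for the karyomorph pipeline."""


class KaryomorphError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(KaryomorphError):
    """A sperm-head measurement is missing, non-positive, or otherwise unusable."""


class InvalidKaryotypeError(KaryomorphError):
    """A karyotype record violates its invariants (empty or non-positive lengths)."""


class NewickParseError(KaryomorphError):
    """Malformed Newick input; the message names the offending token."""


class InsufficientOverlapError(KaryomorphError):
    """Fewer than two species are shared between trait table and tree."""


class InsufficientDataError(KaryomorphError):
    """Too few complete observations to fit the requested model."""


class InsufficientVariationError(KaryomorphError):
    """All predictor values identical after listwise deletion; fit is degenerate."""


class CollinearityError(KaryomorphError):
    """Design matrix is rank deficient; the message names dependent columns."""


class DegenerateCovarianceError(KaryomorphError):
    """Phylogenetic covariance is singular (duplicated tips / zero terminal branches)."""


class OptimizationError(KaryomorphError):
    """Profile-likelihood optimization failed to produce a finite optimum."""
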