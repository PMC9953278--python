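"""Exception hierarchy shared across the package."""


class CfrmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CfrmError, ValueError):
    """A file does not conform to the expected text dialect."""


class BoundsError(CfrmError, IndexError):
    """A spatial rectangle or index falls outside the map."""


class RangeError(CfrmError, ValueError):
    """A wavenumber query falls outside the axis range."""


class ParameterError(CfrmError, ValueError):
    """An operation parameter violates its preconditions."""


class DegenerateInputError(CfrmError, ValueError):
    """Input is structurally valid but degenerate (zero variance, fully masked, ...)."""


class AxisError(CfrmError, ValueError):
    """Two spectra that must share a wavenumber axis do not."""


class ArityError(CfrmError, ValueError):
    """Too few point correspondences for the requested transform."""


class RankError(CfrmError, ValueError):
    """Degenerate point configuration (collinear points, rank-deficient system)."""


class PointAtInfinityError(CfrmError, ValueError):
    """A projective map sends a point to infinity (homogeneous w ~ 0)."""


class MaskError(CfrmError, ValueError):
    """Region masks are empty or overlap where they must not."""


class SizeError(CfrmError, ValueError):
    """A map is smaller than the requested crop."""


class ConfigError(CfrmError, ValueError):
    """A run configuration violates one or more invariants."""


class StratificationError(CfrmError, ValueError):
    """A class is empty under stratified splitting."""


class DivergenceError(CfrmError, RuntimeError):
    """Training produced a non-finite loss."""


class PipelineStageError(CfrmError, RuntimeError):
    """A pipeline stage failed; the cause is chained."""
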