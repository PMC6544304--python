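"""Exception hierarchy for mosaicopt.

All package-specific errors derive from :class:`MosaicoptError` so callers can
catch everything from one root. The CLI maps these onto exit codes.
"""


class MosaicoptError(Exception):
    """Base class for all mosaicopt errors."""


# --- grid / exchange mechanics -------------------------------------------------

class SameStateError(MosaicoptError):
    """Both parcels of an exchange are in the same land state."""


class ExcludedParcelError(MosaicoptError):
    """An exchange touches an immutable excluded (urban/water) parcel."""


class DisallowedPairError(MosaicoptError):
    """The exchange's state pair is not in the allowed pair set."""


class InvalidStateError(MosaicoptError):
    """Operation applied to a patch of an unsupported land state."""


# --- SAR curves ---------------------------------------------------------------

class EmptyTableError(MosaicoptError):
    """Quadrat table has no quadrats."""


class UnderdeterminedError(MosaicoptError):
    """Too few usable points to fit a two-parameter power law."""


class NonPositiveError(MosaicoptError):
    """Non-positive value where a positive one is required (e.g. log fit)."""


class GridMismatchError(MosaicoptError):
    """Curves to be averaged do not share the same area grid."""


# --- objective ----------------------------------------------------------------

class MissingCostError(MosaicoptError):
    """A state-change pair has no entry in the cost table."""


class ConfigError(MosaicoptError):
    """Invalid or inconsistent run configuration."""


# --- search -------------------------------------------------------------------

class PathExplosionError(MosaicoptError):
    """Node budget exceeded during exhaustive tie-following search."""


class EmptyResultError(MosaicoptError):
    """Classification requested on a search result with no paths."""


# --- synthetic data / fixtures ------------------------------------------------

class CountMismatchError(MosaicoptError):
    """State counts do not sum to the number of grid cells."""


class InfeasibleTargetError(MosaicoptError):
    """Target SAR curve exceeds what the species pool can supply."""


class UnknownFixtureError(MosaicoptError):
    """No packaged fixture under the requested name."""


class FixtureUnavailableError(MosaicoptError):
    """A referenced external dataset could not be packaged (provenance gap)."""


# --- I/O ----------------------------------------------------------------------

class ParseError(MosaicoptError):
    """Malformed input file; message carries row/column context."""


class CodeError(MosaicoptError):
    """Unmapped land-state symbol in an input raster."""
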