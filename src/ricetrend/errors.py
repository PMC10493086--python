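"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`RicetrendError` so the CLI can
abort with a stage-named, actionable message.
"""


class RicetrendError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(RicetrendError):
    """A scenario or analysis configuration is invalid."""


class CoverageError(RicetrendError):
    """A climate series does not cover a cultivar's cultivation span."""


class AggregationError(RicetrendError):
    """A season window contains an unresolved missing value."""


class InsufficientDataError(RicetrendError):
    """Too few observations for the requested fit."""


class RankError(RicetrendError):
    """The regression design matrix is rank deficient."""


class CollinearityError(RankError):
    """Rank deficiency attributable to (near-)collinear columns."""
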