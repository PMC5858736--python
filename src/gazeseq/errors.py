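"""Exception hierarchy shared across the package."""


class GazeSeqError(Exception):
    """Base class for all package-specific errors."""


class CompositionError(GazeSeqError, ValueError):
    """Pathology/density fractions are invalid (e.g. do not sum to 1)."""


class ParseError(GazeSeqError, ValueError):
    """A tabular file contains a malformed row; message names the line."""


class SchemaError(GazeSeqError, ValueError):
    """A tabular file is missing a required column or metadata key."""


class EmptyScanpathError(GazeSeqError, ValueError):
    """A scanpath operation received zero gaze samples."""


class InsufficientScalesError(GazeSeqError, ValueError):
    """Fewer than three usable box-count scales remain after saturation filtering."""


class DegenerateSeriesError(GazeSeqError, ValueError):
    """An autocorrelation was requested for a zero-variance series."""


class CodingError(GazeSeqError, ValueError):
    """A rating or density value is outside its allowed domain."""


class DataError(GazeSeqError, ValueError):
    """A dataset is structurally unusable (e.g. missing FD values)."""


class SpecificationError(GazeSeqError, ValueError):
    """A model/ANOVA term specification is invalid for the dataset."""


class RankDeficiencyError(GazeSeqError, ValueError):
    """The ANOVA design matrix is singular; message names aliased terms."""


class DegenerateLabelsError(GazeSeqError, ValueError):
    """A classification dataset contains a single response class."""
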