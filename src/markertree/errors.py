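"""Exception hierarchy for markertree.

All package errors derive from :class:`MarkerTreeError` so callers (and the
CLI) can distinguish input/usage problems from genuine bugs.
"""


class MarkerTreeError(Exception):
    """Base class for all markertree errors."""


class FormatError(MarkerTreeError):
    """A file does not conform to its declared format."""


class ConsistencyError(MarkerTreeError):
    """Components of a multi-file input disagree (e.g. matrix vs barcodes)."""


class LabelingError(MarkerTreeError):
    """Cluster label table does not match the dataset's cells."""


class ValidationError(MarkerTreeError):
    """A dataset or configuration invariant is violated."""


class EmptyDatasetError(MarkerTreeError):
    """An operation removed every cell (or was given none)."""


class DegenerateGroupError(MarkerTreeError):
    """A cell group is too small for the requested statistical operation."""


class SimSpecError(MarkerTreeError):
    """A synthetic-data specification is infeasible."""
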