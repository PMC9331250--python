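"""Named error types raised by the pipeline.

Each input-contract violation gets its own exception class so callers (and the
CLI) can report which contract was broken rather than a generic ValueError.
"""


class XtalkError(Exception):
    """Base class for all package errors."""


class SampleSheetError(XtalkError):
    """Sample sheet violates its invariants (duplicates, bad enum values...)."""


class CountMatrixError(XtalkError):
    """Base for count-matrix contract violations."""


class NegativeCountError(CountMatrixError):
    """A count entry is negative."""


class NonIntegerCountError(CountMatrixError):
    """A count entry is not an integer."""


class DuplicateGeneError(CountMatrixError):
    """Gene identifiers in a count matrix are not unique."""


class SampleMismatchError(CountMatrixError):
    """Count-matrix sample ids are not a subset of the sample sheet."""


class GmtFormatError(XtalkError):
    """A GMT line is malformed."""


class EmptyGeneSetError(GmtFormatError):
    """A GMT line declares a gene set with zero genes."""


class ConfigError(XtalkError):
    """Pipeline configuration is invalid."""


class DesignError(XtalkError):
    """Requested simulation or analysis design is infeasible."""


class MissingGroupError(XtalkError):
    """A diet/timepoint cell required by an analysis has no samples."""


class BipartiteViolationError(XtalkError):
    """An edge's source gene appears among the target genes."""


class DuplicateRegulatorError(XtalkError):
    """A regulator appears more than once in a concordance input."""


class StageError(XtalkError):
    """A pipeline stage failed; message carries the stage label."""
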