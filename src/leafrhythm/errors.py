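"""Exception hierarchy.

Every failure mode that callers are expected to handle gets its own class so
the CLI can map them one-to-one onto exit codes.
"""


class LeafRhythmError(Exception):
    """Base class for all package-specific errors."""


class MarkDetectionError(LeafRhythmError):
    """Not exactly four qualifying red registration marks were found."""


class LayoutError(LeafRhythmError):
    """The four marks are inconsistent with the requested chamber grid."""


class EmptyMaskError(LeafRhythmError):
    """Tip tracing was asked to operate on an empty segmentation mask."""


class InsufficientDataError(LeafRhythmError):
    """A time series is too short for rhythm fitting."""


class NoCandidateError(LeafRhythmError):
    """No spectral peak fell inside the admissible period window."""


class ConvergenceError(LeafRhythmError):
    """Gauss-Newton step halving exhausted without reducing the SSE."""


class CIError(LeafRhythmError):
    """A support-plane confidence bound could not be bracketed."""


class GroupSizeError(LeafRhythmError):
    """A group comparison needs at least two observations per group."""


class SpecError(LeafRhythmError):
    """A simulation or render specification violates its invariants."""
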