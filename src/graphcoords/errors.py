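"""Exception hierarchy for graphcoords.

Every error raised on a user-facing code path derives from
:class:`GraphCoordsError`, so callers (and the CLI) can catch one type.
"""


class GraphCoordsError(Exception):
    """Base class for all graphcoords errors."""


class ValidationError(GraphCoordsError):
    """A data structure violates one of its invariants."""


class UnknownBlockError(ValidationError):
    """An edge, path or lookup references a block id that does not exist."""


class CycleError(ValidationError):
    """The input graph contains a directed cycle."""


class PathOverflowError(GraphCoordsError):
    """Path enumeration exceeded the caller-supplied ``max_paths`` bound."""


class NoPathError(GraphCoordsError):
    """No block-level path is consistent with the requested endpoints."""


class AmbiguousPathError(GraphCoordsError):
    """More than one block-level path matches an interval description.

    ``candidates`` holds the full-form text of every matching path.
    """

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class MissingSequenceError(GraphCoordsError):
    """A sequence-requiring operation hit a block without sequence."""


class CoordinateError(GraphCoordsError):
    """A position is out of range or names an unknown region path."""


class EndpointMismatchError(GraphCoordsError):
    """A multipath membership query was made with mismatching endpoints."""


class PartitionError(GraphCoordsError):
    """A region-path partition is invalid (overlap, gap, or broken path)."""


class NameCollisionError(GraphCoordsError):
    """A naming policy produced the same name for two region paths."""


class ParseError(GraphCoordsError):
    """Malformed position/interval text or an unreadable table row."""


class PlacementError(GraphCoordsError):
    """An alt-locus placement table is inconsistent or unsupported."""


class AlignmentError(GraphCoordsError):
    """Alt-to-main alignment records are inconsistent."""


class FixtureParamError(GraphCoordsError):
    """Synthetic fixture parameters are infeasible."""
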