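"""Exception hierarchy shared across ehrfrag modules."""


class EhrfragError(Exception):
    """Base class for all ehrfrag errors."""


class NavTableError(EhrfragError, ValueError):
    """Malformed navigation-structure table."""


class EmptyInputError(NavTableError):
    """No rows to parse."""


class AnnotationConflictError(NavTableError):
    """Two rows assign conflicting annotations to the same path."""


class RaggedPathError(NavTableError):
    """A blank cell appears between non-blank level cells."""


class DuplicateSiblingLabelError(NavTableError):
    """Sibling labels collide, so the path-per-row dialect cannot represent the tree."""


class TreeInvariantError(EhrfragError, ValueError):
    """A NavTree structural invariant is violated."""


class MissingNodeError(EhrfragError, KeyError):
    """A referenced node id is not in the tree."""


class EmptyTargetsError(EhrfragError, ValueError):
    """trace_pathway called with no targets."""


class PathwayInconsistencyError(EhrfragError, ValueError):
    """A pathway references nodes absent from, or not adjacent in, the tree."""


class SessionLogError(EhrfragError, ValueError):
    """Malformed session event log."""


class OverlapError(SessionLogError):
    """Two segments of one session overlap in time."""


class MalformedSegmentError(SessionLogError):
    """A segment has end <= start or negative times."""


class MissingTaskError(EhrfragError, KeyError):
    """A task label does not occur in the session."""


class UndefinedMetricError(EhrfragError, ValueError):
    """A metric is undefined (e.g. zero total session time)."""


class CapacityError(EhrfragError, ValueError):
    """A synthetic-data spec asks for more targets than available leaves."""


class EmptyReportError(EhrfragError, ValueError):
    """build_report called with neither trees nor sessions."""
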