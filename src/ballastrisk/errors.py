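"""Exception hierarchy.

Loaders distinguish *structural* problems (missing columns, unreadable
formats), which abort, from *record-level* problems (bad coordinates,
unparseable dates), which drop the offending row and report it.
"""


class BallastRiskError(Exception):
    """Base class for all package errors."""


class FormatError(BallastRiskError):
    """A file is structurally unusable (missing column, wrong layout)."""


class ValidationError(BallastRiskError):
    """Input data violates an invariant that cannot be repaired by dropping rows."""


class UsageError(BallastRiskError):
    """A function was called with out-of-domain arguments."""


class PipelineError(BallastRiskError):
    """A pipeline stage produced nothing to continue with."""
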