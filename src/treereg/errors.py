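"""Exception hierarchy for the registration pipeline.

Every failure mode a caller may want to branch on gets its own class; the CLI
maps them onto documented exit codes.
"""


class TreeRegError(Exception):
    """Base class for all package errors."""


class CloudParseError(TreeRegError):
    """Malformed point-cloud file (names the offending line/offset)."""


class CloudIOError(TreeRegError):
    """Unreadable or unwritable point-cloud path."""


class DegenerateInputError(TreeRegError):
    """Too few / collinear / otherwise degenerate input for a geometric fit."""


class FitFailureError(TreeRegError):
    """RANSAC found no model satisfying its constraints."""


class DegenerateProjectionError(TreeRegError):
    """Axis projects to a null direction on the XOY plane."""


class ParallelLinesError(TreeRegError):
    """2D lines are (near-)parallel; no unique intersection."""


class EmptyRegionError(TreeRegError):
    """A height/ring selection produced no points; matching cannot proceed."""


class MatchFailureError(TreeRegError):
    """No branch pair survived gating; registration fails."""


class CoarseFailureError(TreeRegError):
    """Coarse alignment could not be constructed."""


class FineFailureError(TreeRegError):
    """Fine (ICP) stage could not run or collapsed."""


class SimulationError(TreeRegError):
    """Synthetic scan generation produced an empty/invalid result."""


class TreeSpecError(TreeRegError):
    """Infeasible synthetic-tree specification."""


class EvaluationError(TreeRegError):
    """Missing ground truth or other evaluation prerequisite."""


class ConfigError(TreeRegError):
    """Invalid configuration file or value."""


class ContractViolationError(TreeRegError):
    """An internal precondition was violated by the caller."""
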