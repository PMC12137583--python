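"""Exception hierarchy for the orchestrator.

Every error a caller is expected to handle derives from :class:`OrchestralError`;
validation problems that are *data*, not control flow, travel as issue lists
instead (see :mod:`orchestral.compiler`).
"""

from __future__ import annotations


class OrchestralError(Exception):
    """Base class for all orchestrator errors."""


class MissingBindingError(OrchestralError):
    """A name in an include list is absent from the supplied bindings."""


class IncludeExcludeConflictError(OrchestralError):
    """The same name appears in both the include and exclude sets."""


class SnapshotFormatError(OrchestralError):
    """A platform-abstraction snapshot file is unreadable or malformed."""


class SchemaError(OrchestralError):
    """A workflow document violates the document schema.

    Carries *all* violations found, each with a human message and a
    slash-separated position inside the document.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("; ".join(f"{pos}: {msg}" for pos, msg in self.issues))


class PhaseConstraintError(OrchestralError):
    """A dynamic parameter was placed in a run-once (prep/cleanup) phase."""


class StepNotFoundError(OrchestralError):
    """No step with the given id exists in the document."""


class ResolutionError(OrchestralError):
    """A saved output refers to a component/method unknown to the abstraction."""


class CompileRefusedError(OrchestralError):
    """compile() was called on a document with outstanding validation errors."""

    def __init__(self, issues):
        self.issues = list(issues)
        msgs = "; ".join(i.code for i in self.issues)
        super().__init__(f"cannot compile: validation errors present ({msgs})")


class ModeError(OrchestralError):
    """The requested iteration plan is not available for this workflow."""


class PreRunError(OrchestralError):
    """The device registry is missing a component the plan requires."""


class HeaderMismatchError(OrchestralError):
    """CSV header names do not match the dynamic-parameter signature."""

    def __init__(self, expected, got):
        self.expected = sorted(expected)
        self.got = sorted(got)
        super().__init__(
            f"CSV header mismatch: expected columns {self.expected}, got {self.got}"
        )


class CellError(OrchestralError):
    """A CSV cell could not be coerced to its parameter's type."""

    def __init__(self, row, column, value, message):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(f"row {row}, column {column!r}: {message} (value {value!r})")


class ConfigurationError(OrchestralError):
    """Invalid configuration value (unknown backend, bad target, bad port...)."""


class CapabilityError(OrchestralError):
    """A baseline optimizer was asked for something it does not support."""


class ProtocolError(OrchestralError):
    """The ask/tell alternation contract was violated."""


class WorkflowExistsError(OrchestralError):
    """save_workflow(overwrite=False) hit an existing name."""


class ProtectedWorkflowError(OrchestralError):
    """Attempt to overwrite or delete a protected workflow."""


class WorkflowNotFoundError(OrchestralError):
    """No stored workflow has the given name."""


class OfflineError(OrchestralError):
    """An execution endpoint was called while the service is offline."""


class ExtractionError(OrchestralError):
    """No JSON document could be extracted from a model transcript."""


class UnusableAbstractionError(OrchestralError):
    """A prompt was requested for an abstraction with no modules."""


class AbortRun(OrchestralError):
    """Internal signal: a run was aborted by policy after a step failure."""
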