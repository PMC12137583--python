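"""Run compiled plans under repeat / manual / CSV / adaptive iteration plans.

Phase semantics are fixed: preparation executes exactly once before the first
iteration, the main (experiment) phase once per iteration with that
iteration's dynamic bindings, and cleanup exactly once at run end — including
after a failure or abort, because hardware must always be reset.  Execution is
strictly serial.  Every run streams :class:`StatusEvent` objects, with strictly
increasing sequence numbers, to a caller-supplied sink; the same events are
kept on each :class:`ExecutionRecord`.

Which iteration plans are available depends on the workflow itself: a plan
with no dynamic parameters can only be repeated; dynamic parameters enable
manual rows and CSV upload; at least one numeric saved output additionally
enables the adaptive (ask–tell optimizer driven) mode.
"""

from __future__ import annotations

import csv
import io
import time as _time
from dataclasses import dataclass, field

from .compiler import ExecutablePlan, ExecutionContext, StepFailure
from .errors import CellError, HeaderMismatchError, ModeError, PreRunError
from .forms import coerce
from .optimizers import FAILURE, make_optimizer

MODES = ("repeat", "manual", "csv", "adaptive")


@dataclass(frozen=True)
class Repeat:
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("repeat count must be >= 1")


@dataclass(frozen=True)
class Manual:
    rows: tuple

    def __init__(self, rows):
        object.__setattr__(self, "rows", tuple(dict(r) for r in rows))


@dataclass(frozen=True)
class ParameterRange:
    """Continuous [lower, upper] or categorical choice set for one parameter."""

    name: str
    lower: float | None = None
    upper: float | None = None
    choices: tuple | None = None

    def __post_init__(self):
        if self.choices is None:
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(
                    f"parameter {self.name!r}: need lower < upper or a choice set")
        elif not self.choices:
            raise ValueError(f"parameter {self.name!r}: empty choice set")

    @property
    def is_continuous(self) -> bool:
        return self.choices is None


@dataclass(frozen=True)
class ObjectiveSpec:
    output_name: str
    goal: str = "none"  # minimize | maximize | none

    def __post_init__(self):
        if self.goal not in ("minimize", "maximize", "none"):
            raise ValueError(f"unknown goal {self.goal!r}")


@dataclass(frozen=True)
class Adaptive:
    space: tuple
    objectives: tuple
    budget: int
    seed: int = 0
    backend: str = "coordinate"

    def __init__(self, space, objectives, budget, seed=0, backend="coordinate"):
        object.__setattr__(self, "space", tuple(space))
        object.__setattr__(self, "objectives", tuple(objectives))
        object.__setattr__(self, "budget", int(budget))
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "backend", backend)
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass(frozen=True)
class StatusEvent:
    seq: int
    time: float
    category: str  # run_start phase_start step_start step_end step_error iteration_end run_end
    payload: dict = field(default_factory=dict)

    def to_json_obj(self):
        return {"seq": self.seq, "time": self.time,
                "category": self.category, "payload": self.payload}


@dataclass
class ExecutionRecord:
    iteration_index: int
    bindings: dict
    outputs: dict = field(default_factory=dict)
    status: str = "completed"  # completed | failed | aborted
    events: list = field(default_factory=list)


class EventLog:
    """Monotone event sequencer fanning out to an optional sink."""

    def __init__(self, sink=None):
        self.sink = sink
        self.events: list[StatusEvent] = []
        self._seq = 0

    def emit(self, category, **payload):
        self._seq += 1
        ev = StatusEvent(seq=self._seq, time=_time.time(),
                         category=category, payload=payload)
        self.events.append(ev)
        if self.sink is not None:
            self.sink(ev)
        return ev


def available_modes(plan: ExecutablePlan) -> set:
    """Execution options permitted for this plan.

    No dynamic parameters → {repeat}.  Dynamic parameters → {manual, csv},
    plus adaptive when at least one saved output is numeric (only numeric
    outputs can serve as optimization objectives).
    """
    if not plan.dynamic_signature:
        return {"repeat"}
    modes = {"manual", "csv"}
    if any(o["numeric"] for o in plan.output_spec):
        modes.add("adaptive")
    return modes


def rows_from_csv(text: str, signature) -> list[dict]:
    """Parse an RFC-4180 CSV (header row mandatory) into per-iteration bindings.

    Header names must equal the dynamic-parameter names as a set; cells are
    coerced per the parameters' type tags; row order is preserved.
    """
    names = {n for n, _ in signature}
    tags = dict(signature)
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise HeaderMismatchError(names, set()) from None
    header = [h.strip() for h in header]
    if set(header) != names or len(header) != len(set(header)):
        raise HeaderMismatchError(names, header)
    rows = []
    for r, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise CellError(r, "", row, f"expected {len(header)} cells, got {len(row)}")
        binding = {}
        for col, cell in zip(header, row):
            try:
                binding[col] = coerce(cell.strip(), tags[col])
            except ValueError as exc:
                raise CellError(r, col, cell, str(exc)) from exc
        rows.append(binding)
    return rows


class _Runner:
    """Shared run skeleton: prep once, iterate, cleanup always."""

    def __init__(self, plan, registry, sink, clock=None, failure_policy="abort_run"):
        if failure_policy not in ("abort_run", "skip_to_next"):
            raise ValueError(f"unknown failure policy {failure_policy!r}")
        missing = plan.components - set(registry)
        if missing:
            raise PreRunError(f"registry missing components: {sorted(missing)}")
        self.plan = plan
        self.registry = registry
        self.log = EventLog(sink)
        self.clock = clock
        self.failure_policy = failure_policy
        self.records: list[ExecutionRecord] = []

    def _ctx(self):
        return ExecutionContext(self.registry, emit=self.log.emit, clock=self.clock)

    def run_iterations(self, bindings_source):
        """bindings_source yields (index, bindings); returns records.

        Saved-variable bindings reset at each iteration start — no
        cross-iteration leakage.
        """
        self.log.emit("run_start")
        aborted = False
        try:
            self.log.emit("phase_start", phase="prep")
            ctx = self._ctx()
            try:
                self.plan.prep_proc(ctx)
            except StepFailure:
                aborted = True
                return self.records
            for index, bindings in bindings_source:
                if aborted:
                    break
                record = ExecutionRecord(iteration_index=index, bindings=dict(bindings))
                self.records.append(record)
                start = len(self.log.events)
                self.log.emit("phase_start", phase="main", iteration=index)
                ctx = self._ctx()  # fresh variables each iteration
                try:
                    self.plan.main_proc(ctx, bindings)
                except StepFailure:
                    record.status = "failed"
                    if self.failure_policy == "abort_run":
                        aborted = True
                record.outputs = dict(ctx.outputs)
                self.log.emit("iteration_end", iteration=index, status=record.status)
                record.events = self.log.events[start:]
                self.after_iteration(record)
        finally:
            self.log.emit("phase_start", phase="cleanup")
            try:
                self.plan.cleanup_proc(self._ctx())
            except StepFailure:
                pass  # cleanup failures are logged as step_error and swallowed
            self.log.emit("run_end", iterations=len(self.records))
        return self.records

    def after_iteration(self, record):  # hook for adaptive mode
        pass


def run(plan: ExecutablePlan, iteration, registry: dict, sink=None, *,
        clock=None, failure_policy="abort_run") -> list[ExecutionRecord]:
    """Execute a compiled plan under a Repeat or Manual iteration plan.

    The iteration plan must be one the workflow makes available (see
    :func:`available_modes`); a mismatch raises :class:`ModeError`.
    """
    modes = available_modes(plan)
    if isinstance(iteration, Repeat):
        if "repeat" not in modes:
            raise ModeError(
                "repeat mode requires a workflow with constant parameters; "
                f"this one declares {[n for n, _ in plan.dynamic_signature]}")
        source = ((i, {}) for i in range(1, iteration.n + 1))
    elif isinstance(iteration, Manual):
        if "manual" not in modes:
            raise ModeError("manual rows require dynamic parameters")
        names = {n for n, _ in plan.dynamic_signature}
        for i, row in enumerate(iteration.rows):
            if set(row) != names:
                raise ModeError(
                    f"row {i + 1} binds {sorted(row)}, expected exactly {sorted(names)}")
        source = ((i, dict(row)) for i, row in enumerate(iteration.rows, start=1))
    elif isinstance(iteration, Adaptive):
        return run_adaptive(plan, iteration, registry, sink, clock=clock,
                            failure_policy=failure_policy)[0]
    else:
        raise ModeError(f"unknown iteration plan {type(iteration).__name__}")
    runner = _Runner(plan, registry, sink, clock=clock, failure_policy=failure_policy)
    return runner.run_iterations(source)


def run_adaptive(plan: ExecutablePlan, adaptive: Adaptive, registry: dict,
                 sink=None, *, optimizer=None, clock=None,
                 failure_policy="skip_to_next"):
    """Closed-loop execution: ask the optimizer, run, tell it the objective.

    Returns ``(records, best_trace)`` where ``best_trace[i]`` is the best
    objective value observed in iterations 1..i+1 — monotone non-worsening in
    the goal direction.  Failed iterations are told to the optimizer as an
    explicit failure marker; objective values are never fabricated.
    """
    modes = available_modes(plan)
    if "adaptive" not in modes:
        raise ModeError(
            "adaptive mode requires dynamic parameters and >= 1 numeric output")
    sig_names = [n for n, _ in plan.dynamic_signature]
    space_names = [p.name for p in adaptive.space]
    if sorted(space_names) != sorted(sig_names):
        raise ModeError(
            f"space covers {sorted(space_names)}, workflow declares {sorted(sig_names)}")
    numeric = {o["name"] for o in plan.output_spec if o["numeric"]}
    active = [o for o in adaptive.objectives if o.goal != "none"]
    for o in active:
        if o.output_name not in numeric:
            raise ModeError(
                f"objective {o.output_name!r} is not a numeric output "
                "(only numeric outputs can be optimization objectives)")
    if not active:
        raise ModeError("adaptive mode needs at least one objective with a goal")
    opt = optimizer if optimizer is not None else make_optimizer(
        adaptive.space, adaptive.objectives, adaptive.seed, adaptive.backend)
    objective = active[0]  # shipped baselines optimize a single goal
    sign = 1.0 if objective.goal == "minimize" else -1.0

    trace: list[float] = []

    class _AdaptiveRunner(_Runner):
        def after_iteration(self, record):
            value = record.outputs.get(objective.output_name)
            ok = record.status == "completed" and isinstance(value, (int, float)) \
                and not isinstance(value, bool)
            if ok:
                opt.tell(record.bindings, {objective.output_name: float(value)})
                best = trace[-1] if trace else None
                cand = float(value)
                if best is None or sign * cand < sign * best:
                    trace.append(cand)
                else:
                    trace.append(best)
            else:
                if record.status == "completed":
                    record.status = "failed"  # objective missing/non-numeric
                opt.tell(record.bindings, FAILURE)
                if trace:
                    trace.append(trace[-1])

    def source():
        for i in range(1, adaptive.budget + 1):
            yield i, opt.ask()

    runner = _AdaptiveRunner(plan, registry, sink, clock=clock,
                             failure_policy=failure_policy)
    records = runner.run_iterations(source())
    return records, trace
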