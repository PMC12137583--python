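"""Validate workflow documents against an abstraction and compile them.

Validation returns a flat list of :class:`ValidationIssue`; a document with no
error-severity issues is guaranteed to compile.  Compilation produces an
:class:`ExecutablePlan` whose phase procedures are ordinary closures over a
device registry — execution never evaluates generated source text.  A cosmetic
:func:`export_source` renders equivalent, readable Python for users who want
to take a designed workflow back into their own scripts.

Issue catalogue (code — meaning):

- ``unknown-component`` — step names an instance absent from the abstraction
- ``unknown-method`` — component exists but has no such method
- ``unknown-argument`` — argument name not in the method signature
- ``missing-required-argument`` — required parameter not supplied
- ``literal-type-mismatch`` — literal arg incompatible with a validated tag
- ``undefined-variable`` — VariableRef with no earlier save_as/define in phase
- ``dynamic-in-static-phase`` — DynamicRef in prep or cleanup
- ``ambiguous-dynamic-type`` — one #name feeding parameters of different tags
- ``bad-loop-bound`` — non-positive repeat count or while guard
- ``duplicate-save-as`` — (warning) later save shadows an earlier one
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CompileRefusedError
from .refs import DynamicRef, VariableRef
from .workflow import (
    ActionStep,
    ControlStep,
    PHASES,
    WorkflowScript,
    dynamic_parameters,
    outputs,
)

_CHECKED_TAGS = {"integer", "real", "boolean", "text"}


def _literal_matches(value, tag: str) -> bool:
    if tag == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    if tag == "real":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if tag == "boolean":
        return isinstance(value, bool)
    if tag == "text":
        return isinstance(value, str)
    return True


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # error | warning
    code: str
    message: str
    step_id: str | None = None

    def to_json_obj(self):
        return {"severity": self.severity, "code": self.code,
                "message": self.message, "step_id": self.step_id}


def errors_of(issues) -> list:
    return [i for i in issues if i.severity == "error"]


@dataclass
class ExecutablePlan:
    """Compiled phase procedures plus the plan's external signature.

    ``main_proc(ctx, bindings)`` requires exactly the names in
    ``dynamic_signature``; ``prep_proc(ctx)`` / ``cleanup_proc(ctx)`` take none.
    """

    prep_proc: object
    main_proc: object
    cleanup_proc: object
    dynamic_signature: list  # ordered [(name, type_tag)]
    output_spec: list  # [{name, numeric}]
    source: WorkflowScript = None

    @property
    def components(self) -> set:
        return {s.component for _, s in self.source.walk() if isinstance(s, ActionStep)}


# ---------------------------------------------------------------------------
# validation


def validate(w: WorkflowScript, abstraction) -> list[ValidationIssue]:
    """Check a document against an abstraction; empty-of-errors iff it compiles."""
    issues: list[ValidationIssue] = []
    dyn_tags: dict[str, str] = {}
    seen_saves: set[str] = set()

    def check_action(step: ActionStep, phase: str, defined: set):
        mod = abstraction.module(step.component)
        if mod is None:
            issues.append(ValidationIssue(
                "error", "unknown-component",
                f"no component named {step.component!r} in the abstraction", step.id))
            return
        rec = mod.method(step.method)
        if rec is None:
            issues.append(ValidationIssue(
                "error", "unknown-method",
                f"component {step.component!r} has no method {step.method!r}", step.id))
            return
        params = {p.name: p for p in rec.parameters}
        for arg_name, value in step.args.items():
            p = params.get(arg_name)
            if p is None:
                issues.append(ValidationIssue(
                    "error", "unknown-argument",
                    f"{step.component}.{step.method} has no parameter {arg_name!r}",
                    step.id))
                continue
            if isinstance(value, DynamicRef):
                if phase != "main":
                    issues.append(ValidationIssue(
                        "error", "dynamic-in-static-phase",
                        f"dynamic parameter #{value.name} in the {phase} phase "
                        "(prep and cleanup execute once with constant inputs)",
                        step.id))
                prev = dyn_tags.get(value.name)
                if prev is not None and prev != p.type_tag:
                    issues.append(ValidationIssue(
                        "error", "ambiguous-dynamic-type",
                        f"#{value.name} feeds parameters of type {prev} and "
                        f"{p.type_tag}", step.id))
                else:
                    dyn_tags.setdefault(value.name, p.type_tag)
            elif isinstance(value, VariableRef):
                if value.name not in defined:
                    issues.append(ValidationIssue(
                        "error", "undefined-variable",
                        f"variable {value.name!r} is not defined earlier in this phase",
                        step.id))
            else:
                if p.type_tag in _CHECKED_TAGS and not _literal_matches(value, p.type_tag):
                    issues.append(ValidationIssue(
                        "error", "literal-type-mismatch",
                        f"argument {arg_name!r} expects {p.type_tag}, got "
                        f"{type(value).__name__} {value!r}", step.id))
        missing = [n for n, p in params.items()
                   if p.required and n not in step.args]
        for n in missing:
            issues.append(ValidationIssue(
                "error", "missing-required-argument",
                f"required argument {n!r} of {step.component}.{step.method} missing",
                step.id))
        if step.save_as:
            if step.save_as in seen_saves:
                issues.append(ValidationIssue(
                    "warning", "duplicate-save-as",
                    f"save name {step.save_as!r} shadows an earlier save", step.id))
            seen_saves.add(step.save_as)
            defined.add(step.save_as)

    def check_seq(steps, phase, defined):
        for step in steps:
            if isinstance(step, ActionStep):
                check_action(step, phase, defined)
            else:
                check_control(step, phase, defined)

    def check_control(step: ControlStep, phase: str, defined: set):
        if step.kind in ("if", "while") and step.condition is not None:
            for operand in (step.condition.left, step.condition.right):
                if isinstance(operand, VariableRef) and operand.name not in defined:
                    issues.append(ValidationIssue(
                        "error", "undefined-variable",
                        f"variable {operand.name!r} in condition is not defined "
                        "earlier in this phase", step.id))
        if step.kind == "repeat" and (step.count is None or step.count < 1):
            issues.append(ValidationIssue(
                "error", "bad-loop-bound", "repeat count must be >= 1", step.id))
        if step.kind == "while" and step.max_iterations < 1:
            issues.append(ValidationIssue(
                "error", "bad-loop-bound", "while guard must be >= 1", step.id))
        if step.kind == "define":
            defined.add(step.name)
        check_seq(step.body, phase, defined)
        if step.else_body:
            check_seq(step.else_body, phase, defined)

    for phase in PHASES:
        check_seq(w.phases[phase], phase, set())
    try:
        outputs(w, abstraction)
    except Exception:
        pass  # unknown components already reported above
    return issues


# ---------------------------------------------------------------------------
# compilation


class ExecutionContext:
    """Carries the device registry, event emitter, variables and outputs."""

    def __init__(self, registry, emit=None, clock=None):
        self.registry = registry
        self.emit = emit or (lambda category, **payload: None)
        self.clock = clock
        self.variables: dict = {}
        self.outputs: dict = {}

    def sleep(self, seconds: float):
        if self.clock is not None:
            self.clock.sleep(seconds)
        # a None clock is a virtual clock: waits complete instantly


class StepFailure(Exception):
    """A device call raised during a step; carries the step id and cause."""

    def __init__(self, step_id, cause):
        self.step_id = step_id
        self.cause = cause
        super().__init__(f"step {step_id} failed: {cause}")


def _resolve_arg(value, ctx, bindings):
    if isinstance(value, DynamicRef):
        return bindings[value.name]
    if isinstance(value, VariableRef):
        return ctx.variables[value.name]
    return value


def _exec_step(step, ctx, bindings, saved_names):
    if isinstance(step, ActionStep):
        ctx.emit("step_start", step_id=step.id,
                 component=step.component, method=step.method)
        try:
            device = ctx.registry[step.component]
            args = {k: _resolve_arg(v, ctx, bindings) for k, v in step.args.items()}
            result = getattr(device, step.method)(**args)
        except Exception as exc:
            ctx.emit("step_error", step_id=step.id, message=str(exc))
            raise StepFailure(step.id, exc) from exc
        if step.save_as:
            ctx.variables[step.save_as] = result
            if step.save_as in saved_names:
                ctx.outputs[step.save_as] = result
        ctx.emit("step_end", step_id=step.id)
        return
    if step.kind == "wait":
        ctx.emit("step_start", step_id=step.id, kind="wait",
                 duration_s=step.duration_s)
        ctx.sleep(step.duration_s)
        ctx.emit("step_end", step_id=step.id, kind="wait")
        return
    if step.kind == "define":
        ctx.variables[step.name] = _resolve_arg(step.value, ctx, bindings)
        return
    if step.kind == "repeat":
        for _ in range(step.count):
            for s in step.body:
                _exec_step(s, ctx, bindings, saved_names)
        return
    if step.kind == "if":
        branch = step.body if step.condition.evaluate(ctx.variables) else (step.else_body or ())
        for s in branch:
            _exec_step(s, ctx, bindings, saved_names)
        return
    if step.kind == "while":
        n = 0
        while step.condition.evaluate(ctx.variables):
            if n >= step.max_iterations:
                break  # guard: unattended loops terminate
            n += 1
            for s in step.body:
                _exec_step(s, ctx, bindings, saved_names)
        return
    raise AssertionError(f"unhandled step kind {step.kind!r}")


def compile_workflow(w: WorkflowScript, abstraction) -> ExecutablePlan:
    """Compile a validated document into executable phase procedures.

    Refuses (raising :class:`CompileRefusedError`) when validation reports any
    error.  Running ``main_proc`` with bindings B is observably equivalent —
    identical device call sequence — to compiling a copy of the document with
    every ``#name`` replaced by the literal ``B[name]``.
    """
    issues = validate(w, abstraction)
    errs = errors_of(issues)
    if errs:
        raise CompileRefusedError(errs)
    signature = []
    dyn_tags = {}
    for _, step in w.walk():
        if isinstance(step, ActionStep):
            rec = abstraction.resolve(step.component, step.method)
            for arg_name, v in step.args.items():
                if isinstance(v, DynamicRef) and v.name not in dyn_tags:
                    p = next(p for p in rec.parameters if p.name == arg_name)
                    dyn_tags[v.name] = p.type_tag
    for name in dynamic_parameters(w):
        signature.append((name, dyn_tags[name]))
    output_spec = outputs(w, abstraction)
    saved_names = {o["name"] for o in output_spec}

    def make_phase_proc(phase, needs_bindings):
        steps = w.phases[phase]

        if needs_bindings:
            def proc(ctx, bindings):
                missing = {n for n, _ in signature} - set(bindings)
                if missing:
                    raise KeyError(f"missing dynamic bindings: {sorted(missing)}")
                for s in steps:
                    _exec_step(s, ctx, bindings, saved_names)
        else:
            def proc(ctx):
                for s in steps:
                    _exec_step(s, ctx, {}, saved_names)
        return proc

    return ExecutablePlan(
        prep_proc=make_phase_proc("prep", False),
        main_proc=make_phase_proc("main", True),
        cleanup_proc=make_phase_proc("cleanup", False),
        dynamic_signature=signature,
        output_spec=output_spec,
        source=w,
    )


# ---------------------------------------------------------------------------
# cosmetic source export


def _fmt_value(v):
    if isinstance(v, DynamicRef):
        return v.name
    if isinstance(v, VariableRef):
        return v.name
    return repr(v)


def _emit_steps(steps, lines, indent):
    pad = "    " * indent
    for step in steps:
        if isinstance(step, ActionStep):
            call = f"{step.component}.{step.method}(" + ", ".join(
                f"{k}={_fmt_value(v)}" for k, v in step.args.items()) + ")"
            lines.append(pad + (f"{step.save_as} = {call}" if step.save_as else call))
        elif step.kind == "wait":
            lines.append(pad + f"time.sleep({step.duration_s!r})")
        elif step.kind == "define":
            lines.append(pad + f"{step.name} = {_fmt_value(step.value)}")
        elif step.kind == "repeat":
            lines.append(pad + f"for _ in range({step.count}):")
            _emit_steps(step.body, lines, indent + 1)
        elif step.kind in ("if", "while"):
            c = step.condition
            lines.append(pad + f"{step.kind} {_fmt_value(c.left)} {c.op} {_fmt_value(c.right)}:")
            _emit_steps(step.body, lines, indent + 1)
            if step.kind == "if" and step.else_body:
                lines.append(pad + "else:")
                _emit_steps(step.else_body, lines, indent + 1)


def export_source(w: WorkflowScript) -> str:
    """Render the workflow as readable Python using the captured instance names.

    For human consumption only — execution always goes through the compiled
    closures, never through this text.
    """
    lines = ["import time", ""]
    sig = ", ".join(dynamic_parameters(w))
    for phase, fname, args in (("prep", "prep", ""), ("main", "main", sig),
                               ("cleanup", "cleanup", "")):
        lines.append(f"def {fname}({args}):")
        if w.phases[phase]:
            _emit_steps(w.phases[phase], lines, 1)
        else:
            lines.append("    pass")
        lines.append("")
    return "\n".join(lines)
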