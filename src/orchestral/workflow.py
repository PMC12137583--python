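"""The three-phase workflow document: steps, flow control, (de)serialization.

A workflow is a named document with exactly three phases — ``prep`` runs once
before the iterations, ``main`` runs once per iteration and may carry dynamic
(``#name``) parameters, ``cleanup`` runs once afterwards.  Each phase is an
ordered list of action steps (a component-method call with arguments and an
optional ``save_as`` output capture) and flow-control steps (``if``, ``while``,
``repeat``, ``wait``, ``define``).

Editing operations are pure: they return a new document and never mutate their
input, so a half-applied edit is never observable.  Serialization is canonical
— equal documents produce byte-identical JSON — which makes storage and
transport diffs meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .errors import PhaseConstraintError, SchemaError, StepNotFoundError, ResolutionError
from .refs import DynamicRef, VariableRef, is_identifier

PHASES = ("prep", "main", "cleanup")

# Display names used by the web interface tabs map onto the document keys.
PHASE_ALIASES = {
    "prepare": "prep", "prep": "prep",
    "script": "main", "experiment": "main", "main": "main",
    "cleanup": "cleanup", "clean up": "cleanup",
}

COMPARISON_OPS = ("==", "!=", "<", "<=", ">", ">=")

DEFAULT_WHILE_GUARD = 1000  # unattended hardware must not spin forever


@dataclass(frozen=True)
class Comparison:
    """A minimal condition: ``<operand> <op> <operand>``.

    Operands are literals or :class:`VariableRef`; deliberately not a general
    expression grammar.
    """

    left: object
    op: str
    right: object

    def __post_init__(self):
        if self.op not in COMPARISON_OPS:
            raise ValueError(f"unknown comparison operator: {self.op!r}")

    def evaluate(self, variables: dict):
        def resolve(x):
            if isinstance(x, VariableRef):
                return variables[x.name]
            return x

        a, b = resolve(self.left), resolve(self.right)
        return {
            "==": a == b, "!=": a != b,
            "<": a < b, "<=": a <= b,
            ">": a > b, ">=": a >= b,
        }[self.op]


@dataclass(frozen=True)
class ActionStep:
    """A single instrument call: ``component.method(**args)``, optionally saved."""

    id: str
    component: str
    method: str
    args: dict = field(default_factory=dict)
    save_as: str | None = None


@dataclass(frozen=True)
class ControlStep:
    """A flow-control construct.

    kind ``if``/``while`` use ``condition`` (+ ``body``, ``else_body`` for if);
    ``repeat`` uses ``count`` + ``body``; ``wait`` uses ``duration_s``;
    ``define`` binds ``name`` to ``value``.
    """

    id: str
    kind: str
    condition: Comparison | None = None
    count: int | None = None
    duration_s: float | None = None
    name: str | None = None
    value: object = None
    body: tuple = ()
    else_body: tuple | None = None
    max_iterations: int = DEFAULT_WHILE_GUARD


@dataclass(frozen=True)
class WorkflowScript:
    """A named workflow document with exactly the phases prep / main / cleanup."""

    name: str
    phases: dict = field(default_factory=lambda: {p: () for p in PHASES})

    def __post_init__(self):
        if set(self.phases) != set(PHASES):
            raise ValueError(f"phases must be exactly {PHASES}")

    # -- traversal ----------------------------------------------------------

    def walk(self, phase: str | None = None):
        """Yield (phase, step) depth-first in document order."""
        for ph in PHASES if phase is None else (phase,):
            for step in self.phases[ph]:
                yield from _walk_step(ph, step)

    def find(self, step_id: str):
        for ph, step in self.walk():
            if step.id == step_id:
                return ph, step
        raise StepNotFoundError(f"no step with id {step_id!r}")

    def all_ids(self) -> list[str]:
        return [s.id for _, s in self.walk()]

    def next_id(self) -> str:
        mx = 0
        for sid in self.all_ids():
            if sid.startswith("s") and sid[1:].isdigit():
                mx = max(mx, int(sid[1:]))
        return f"s{mx + 1}"


def _walk_step(phase, step):
    yield phase, step
    if isinstance(step, ControlStep):
        for sub in step.body:
            yield from _walk_step(phase, sub)
        for sub in step.else_body or ():
            yield from _walk_step(phase, sub)


def _step_has_dynamic(step) -> bool:
    if isinstance(step, ActionStep):
        return any(isinstance(v, DynamicRef) for v in step.args.values())
    if isinstance(step, ControlStep):
        return any(_step_has_dynamic(s) for s in tuple(step.body) + tuple(step.else_body or ()))
    return False


# ---------------------------------------------------------------------------
# editing operations (pure)


def _validate_document(w: WorkflowScript) -> WorkflowScript:
    ids = w.all_ids()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError([("phases", f"duplicate step ids: {dupes}")])
    for ph in ("prep", "cleanup"):
        for step in w.phases[ph]:
            if _step_has_dynamic(step):
                raise PhaseConstraintError(
                    f"dynamic parameters are not allowed in the {ph} phase "
                    "(it executes once with constant inputs)"
                )
    return w


def add_step(w: WorkflowScript, phase: str, index: int, step) -> WorkflowScript:
    """Insert a step; assigns a fresh monotone id when step.id is empty."""
    phase = PHASE_ALIASES.get(phase, phase)
    if phase not in PHASES:
        raise ValueError(f"unknown phase: {phase!r}")
    seq = list(w.phases[phase])
    if not 0 <= index <= len(seq):
        raise IndexError(f"index {index} out of bounds for phase {phase!r}")
    if not step.id:
        step = replace(step, id=w.next_id())
    seq.insert(index, step)
    out = replace(w, phases={**w.phases, phase: tuple(seq)})
    return _validate_document(out)


def remove_step(w: WorkflowScript, step_id: str) -> WorkflowScript:
    w.find(step_id)  # raises if absent
    phases = {ph: _remove_from(seq, step_id) for ph, seq in w.phases.items()}
    return replace(w, phases=phases)


def _remove_from(steps, step_id):
    out = []
    for s in steps:
        if s.id == step_id:
            continue
        if isinstance(s, ControlStep):
            s = replace(
                s,
                body=_remove_from(s.body, step_id),
                else_body=_remove_from(s.else_body, step_id) if s.else_body is not None else None,
            )
        out.append(s)
    return tuple(out)


def move_step(w: WorkflowScript, step_id: str, phase: str, index: int) -> WorkflowScript:
    _, step = w.find(step_id)
    phase = PHASE_ALIASES.get(phase, phase)
    if phase in ("prep", "cleanup") and _step_has_dynamic(step):
        raise PhaseConstraintError(
            f"step {step_id!r} carries dynamic parameters and cannot move to {phase!r}"
        )
    return add_step(remove_step(w, step_id), phase, index, step)


def edit_args(w: WorkflowScript, step_id: str, args: dict) -> WorkflowScript:
    ph, step = w.find(step_id)
    if not isinstance(step, ActionStep):
        raise ValueError(f"step {step_id!r} is not an action step")
    new_step = replace(step, args=dict(args))
    if ph in ("prep", "cleanup") and _step_has_dynamic(new_step):
        raise PhaseConstraintError(
            f"dynamic parameters are not allowed in the {ph} phase"
        )
    phases = {p: _replace_in(seq, step_id, new_step) for p, seq in w.phases.items()}
    return _validate_document(replace(w, phases=phases))


def _replace_in(steps, step_id, new_step):
    out = []
    for s in steps:
        if s.id == step_id:
            out.append(new_step)
            continue
        if isinstance(s, ControlStep):
            s = replace(
                s,
                body=_replace_in(s.body, step_id, new_step),
                else_body=_replace_in(s.else_body, step_id, new_step)
                if s.else_body is not None else None,
            )
        out.append(s)
    return tuple(out)


# ---------------------------------------------------------------------------
# dynamic parameters, outputs, substitution


def dynamic_parameters(w: WorkflowScript) -> list[str]:
    """Distinct dynamic-parameter names in first-appearance (document) order."""
    seen = []
    for _, step in w.walk():
        if isinstance(step, ActionStep):
            for v in step.args.values():
                if isinstance(v, DynamicRef) and v.name not in seen:
                    seen.append(v.name)
    return seen


def outputs(w: WorkflowScript, abstraction) -> list[dict]:
    """One ``{name, numeric}`` entry per save_as, in document order.

    An output is numeric — hence usable as an optimization objective — when
    the producing method's return tag is integer or real.
    """
    out = []
    for _, step in w.walk():
        if isinstance(step, ActionStep) and step.save_as:
            rec = abstraction.resolve(step.component, step.method)
            if rec is None:
                raise ResolutionError(
                    f"save_as {step.save_as!r}: method "
                    f"{step.component}.{step.method} unknown to the abstraction"
                )
            out.append({
                "name": step.save_as,
                "numeric": rec.return_tag in ("integer", "real"),
            })
    return out


def substitute(w: WorkflowScript, bindings: dict) -> WorkflowScript:
    """Replace every DynamicRef ``r`` with the literal ``bindings[r.name]``.

    Used by the substitution-equivalence property: a compiled plan run with
    bindings B must produce the same device transcript as the substituted
    document compiled and run with no bindings.
    """

    def sub_step(step):
        if isinstance(step, ActionStep):
            args = {
                k: (bindings[v.name] if isinstance(v, DynamicRef) else v)
                for k, v in step.args.items()
            }
            return replace(step, args=args)
        return replace(
            step,
            body=tuple(sub_step(s) for s in step.body),
            else_body=tuple(sub_step(s) for s in step.else_body)
            if step.else_body is not None else None,
        )

    phases = {ph: tuple(sub_step(s) for s in seq) for ph, seq in w.phases.items()}
    return replace(w, phases=phases)


# ---------------------------------------------------------------------------
# JSON document (canonical)

SCHEMA_VERSION = 1


def _encode_value(v):
    if isinstance(v, DynamicRef):
        return {"dynamic": v.name}
    if isinstance(v, VariableRef):
        return {"variable": v.name}
    return {"literal": v}


def _encode_step(step):
    if isinstance(step, ActionStep):
        obj = {
            "id": step.id,
            "type": "action",
            "component": step.component,
            "method": step.method,
            "args": {k: _encode_value(v) for k, v in step.args.items()},
        }
        if step.save_as:
            obj["save_as"] = step.save_as
        return obj
    obj = {"id": step.id, "type": step.kind}
    if step.kind in ("if", "while"):
        c = step.condition
        obj["condition"] = {
            "left": _encode_value(c.left), "op": c.op, "right": _encode_value(c.right),
        }
    if step.kind == "while" and step.max_iterations != DEFAULT_WHILE_GUARD:
        obj["max_iterations"] = step.max_iterations
    if step.kind == "repeat":
        obj["count"] = step.count
    if step.kind == "wait":
        obj["duration_s"] = step.duration_s
    if step.kind == "define":
        obj["name"] = step.name
        obj["value"] = _encode_value(step.value)
    if step.kind in ("if", "while", "repeat"):
        obj["body"] = [_encode_step(s) for s in step.body]
        if step.kind == "if" and step.else_body is not None:
            obj["else"] = [_encode_step(s) for s in step.else_body]
    return obj


def to_document(w: WorkflowScript) -> str:
    """Canonical JSON: sorted keys, compact separators — equal documents are
    byte-identical."""
    obj = {
        "schema": SCHEMA_VERSION,
        "name": w.name,
        "phases": {ph: [_encode_step(s) for s in w.phases[ph]] for ph in PHASES},
    }
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False)


class _Issues:
    def __init__(self):
        self.items = []

    def add(self, pos, msg):
        self.items.append((pos, msg))


_STEP_KEYS = {
    "action": {"id", "type", "component", "method", "args", "save_as"},
    "if": {"id", "type", "condition", "body", "else"},
    "while": {"id", "type", "condition", "body", "max_iterations"},
    "repeat": {"id", "type", "count", "body"},
    "wait": {"id", "type", "duration_s"},
    "define": {"id", "type", "name", "value"},
}


def _decode_value(obj, pos, issues, allow_dynamic):
    if not isinstance(obj, dict) or len(obj) != 1:
        issues.add(pos, "value must be a one-key object {literal|dynamic|variable: ...}")
        return None
    (kind, v), = obj.items()
    if kind == "literal":
        return v
    if kind == "dynamic":
        if not is_identifier(v):
            issues.add(pos, f"dynamic name {v!r} is not a valid identifier")
            return None
        if not allow_dynamic:
            issues.add(pos, "dynamic parameters are only allowed in the main phase")
            return None
        return DynamicRef(v)
    if kind == "variable":
        if not is_identifier(v):
            issues.add(pos, f"variable name {v!r} is not a valid identifier")
            return None
        return VariableRef(v)
    issues.add(pos, f"unknown value kind {kind!r}")
    return None


def _decode_step(obj, pos, issues, allow_dynamic):
    if not isinstance(obj, dict):
        issues.add(pos, "step must be an object")
        return None
    stype = obj.get("type")
    if stype not in _STEP_KEYS:
        issues.add(pos, f"unknown step type {stype!r}")
        return None
    unknown = set(obj) - _STEP_KEYS[stype]
    if unknown:
        issues.add(pos, f"unknown keys for {stype} step: {sorted(unknown)}")
        return None
    sid = obj.get("id")
    if not isinstance(sid, str) or not sid:
        issues.add(pos, "step id must be a nonempty string")
        return None
    if stype == "action":
        comp, meth = obj.get("component"), obj.get("method")
        if not is_identifier(comp):
            issues.add(pos, f"component {comp!r} is not a valid identifier")
            return None
        if not is_identifier(meth):
            issues.add(pos, f"method {meth!r} is not a valid identifier")
            return None
        raw_args = obj.get("args", {})
        if not isinstance(raw_args, dict):
            issues.add(pos + "/args", "args must be an object")
            return None
        args = {}
        for k, v in raw_args.items():
            if not is_identifier(k):
                issues.add(pos + f"/args/{k}", "argument name is not a valid identifier")
                continue
            args[k] = _decode_value(v, pos + f"/args/{k}", issues, allow_dynamic)
        save_as = obj.get("save_as")
        if save_as is not None and not is_identifier(save_as):
            issues.add(pos, f"save_as {save_as!r} is not a valid identifier")
            return None
        return ActionStep(id=sid, component=comp, method=meth, args=args, save_as=save_as)
    if stype in ("if", "while"):
        c = obj.get("condition")
        cond = None
        if (not isinstance(c, dict) or set(c) != {"left", "op", "right"}
                or c.get("op") not in COMPARISON_OPS):
            issues.add(pos + "/condition", "condition must be {left, op, right} with a "
                       f"comparison op from {list(COMPARISON_OPS)}")
        else:
            left = _decode_value(c["left"], pos + "/condition/left", issues, False)
            right = _decode_value(c["right"], pos + "/condition/right", issues, False)
            cond = Comparison(left, c["op"], right)
        body = _decode_body(obj.get("body"), pos + "/body", issues, allow_dynamic)
        else_body = None
        if stype == "if" and "else" in obj:
            else_body = _decode_body(obj["else"], pos + "/else", issues, allow_dynamic,
                                     may_be_empty=True)
        guard = obj.get("max_iterations", DEFAULT_WHILE_GUARD)
        if not (isinstance(guard, int) and guard > 0):
            issues.add(pos, "max_iterations must be a positive integer")
            guard = DEFAULT_WHILE_GUARD
        return ControlStep(id=sid, kind=stype, condition=cond, body=body,
                           else_body=else_body, max_iterations=guard)
    if stype == "repeat":
        count = obj.get("count")
        if not (isinstance(count, int) and not isinstance(count, bool) and count >= 1):
            issues.add(pos, "repeat count must be a positive integer")
            count = 1
        body = _decode_body(obj.get("body"), pos + "/body", issues, allow_dynamic)
        return ControlStep(id=sid, kind="repeat", count=count, body=body)
    if stype == "wait":
        dur = obj.get("duration_s")
        if not (isinstance(dur, (int, float)) and not isinstance(dur, bool) and dur >= 0):
            issues.add(pos, "wait duration_s must be a nonnegative number")
            dur = 0.0
        return ControlStep(id=sid, kind="wait", duration_s=float(dur))
    # define
    name = obj.get("name")
    if not is_identifier(name):
        issues.add(pos, f"define name {name!r} is not a valid identifier")
        return None
    value = _decode_value(obj.get("value"), pos + "/value", issues, False)
    return ControlStep(id=sid, kind="define", name=name, value=value)


def _decode_body(obj, pos, issues, allow_dynamic, may_be_empty=False):
    if not isinstance(obj, list):
        issues.add(pos, "body must be an array of steps")
        return ()
    if not obj and not may_be_empty:
        issues.add(pos, "body must be nonempty")
    steps = []
    for i, s in enumerate(obj):
        st = _decode_step(s, f"{pos}/{i}", issues, allow_dynamic)
        if st is not None:
            steps.append(st)
    return tuple(steps)


def from_document(text: str) -> WorkflowScript:
    """Parse a workflow JSON document, reporting *all* schema violations."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError([("", f"not valid JSON: {exc}")]) from exc
    issues = _Issues()
    if not isinstance(obj, dict):
        raise SchemaError([("", "document root must be an object")])
    unknown = set(obj) - {"schema", "name", "phases"}
    if unknown:
        issues.add("", f"unknown document keys: {sorted(unknown)}")
    if obj.get("schema") != SCHEMA_VERSION:
        issues.add("schema", f"unsupported schema version {obj.get('schema')!r}")
    name = obj.get("name")
    if not isinstance(name, str) or not name:
        issues.add("name", "workflow name must be a nonempty string")
        name = "?"
    raw_phases = obj.get("phases")
    phases = {p: () for p in PHASES}
    if not isinstance(raw_phases, dict):
        issues.add("phases", "phases must be an object")
    else:
        for p in PHASES:
            if p not in raw_phases:
                issues.add("phases", f"{p} missing")
        for key in set(raw_phases) - set(PHASES):
            issues.add(f"phases/{key}", "unknown phase key")
        for p in PHASES:
            steps = raw_phases.get(p, [])
            if not isinstance(steps, list):
                issues.add(f"phases/{p}", "phase must be an array of steps")
                continue
            decoded = []
            for i, s in enumerate(steps):
                st = _decode_step(s, f"phases/{p}/{i}", issues, allow_dynamic=(p == "main"))
                if st is not None:
                    decoded.append(st)
            phases[p] = tuple(decoded)
    w = WorkflowScript(name=name, phases=phases)
    ids = w.all_ids()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        issues.add("phases", f"duplicate step ids: {dupes}")
    if issues.items:
        raise SchemaError(issues.items)
    return w
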