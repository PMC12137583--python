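"""Render method signatures as validating input forms and parse submissions.

Two contexts exist.  *Control* forms drive immediate instrument calls; every
value must be a literal.  *Design* forms build workflow steps; there a value
written ``#name`` becomes a :class:`~orchestral.refs.DynamicRef` bound per
iteration at execution time, and a save field is appended for capturing the
method's return value.

Typed widgets (integer, real, checkbox) validate and coerce their input;
collection / custom / unannotated parameters render as raw text passed to the
method verbatim — no literal evaluation is ever performed on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .introspect import MethodRecord, ParameterSpec
from .refs import DynamicRef, is_identifier

VALIDATED_WIDGETS = ("integer_input", "real_input", "checkbox")

_WIDGET_FOR_TAG = {
    "integer": "integer_input",
    "real": "real_input",
    "boolean": "checkbox",
    "text": "text_input",
    "collection": "raw_text",
    "custom": "raw_text",
    "unspecified": "raw_text",
}

_TRUE_TOKENS = {"true", "on", "1"}
_FALSE_TOKENS = {"false", "off", "0"}


@dataclass(frozen=True)
class FieldSpec:
    name: str
    widget: str
    default: object = None
    has_default: bool = False
    validated: bool = False
    allow_dynamic: bool = False
    label: str = ""
    type_tag: str = "unspecified"

    @property
    def required(self) -> bool:
        return not self.has_default


@dataclass(frozen=True)
class FormSpec:
    module: str
    method: str
    fields: tuple = ()
    save_field: FieldSpec | None = None
    context: str = "control"

    def field(self, name: str) -> FieldSpec | None:
        for f in self.fields:
            if f.name == name:
                return f
        return None

    def to_json_obj(self) -> dict:
        def enc(f):
            obj = {
                "name": f.name, "widget": f.widget, "validated": f.validated,
                "allow_dynamic": f.allow_dynamic, "label": f.label,
                "required": f.required, "type_tag": f.type_tag,
            }
            if f.has_default:
                obj["default"] = f.default
            return obj

        out = {
            "module": self.module, "method": self.method, "context": self.context,
            "fields": [enc(f) for f in self.fields],
        }
        if self.save_field is not None:
            out["save_field"] = enc(self.save_field)
        return out


@dataclass(frozen=True)
class FieldIssue:
    field: str
    code: str  # not-coercible | missing-required | dynamic-syntax | dynamic-not-allowed | unknown-field
    message: str


@dataclass
class ParsedSubmission:
    values: dict = field(default_factory=dict)
    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def field_for(p: ParameterSpec, context: str = "control") -> FieldSpec:
    """Map one parameter to its input field.

    Typed tags get validating widgets; collection/custom/unspecified fall back
    to unvalidated raw text.  Dynamic (``#``) input is permitted only in the
    design context.
    """
    widget = _WIDGET_FOR_TAG[p.type_tag]
    return FieldSpec(
        name=p.name,
        widget=widget,
        default=p.default,
        has_default=p.has_default,
        validated=widget in VALIDATED_WIDGETS,
        allow_dynamic=(context == "design"),
        label=p.name.replace("_", " "),
        type_tag=p.type_tag,
    )


def form_for(m: MethodRecord, module: str, context: str = "control") -> FormSpec:
    """One field per parameter, in signature order; design forms get a save field."""
    fields = tuple(field_for(p, context) for p in m.parameters)
    save_field = None
    if context == "design":
        save_field = FieldSpec(
            name="save_as", widget="text_input", has_default=True, default=None,
            validated=False, allow_dynamic=False, label="save as", type_tag="text",
        )
    return FormSpec(module=module, method=m.name, fields=fields,
                    save_field=save_field, context=context)


def coerce(raw: str, type_tag: str):
    """Coerce a raw string to the tag's Python type; raises ValueError.

    Integer fields reject reals with fractional parts rather than truncating.
    Checkbox tokens accepted case-insensitively: true/false, on/off, 1/0.
    """
    if type_tag == "integer":
        s = raw.strip()
        try:
            return int(s)
        except ValueError:
            f = float(s)  # may raise again — propagate
            if not f.is_integer():
                raise ValueError(f"{raw!r} has a fractional part")
            return int(f)
    if type_tag == "real":
        return float(raw.strip())
    if type_tag == "boolean":
        s = raw.strip().lower()
        if s in _TRUE_TOKENS:
            return True
        if s in _FALSE_TOKENS:
            return False
        raise ValueError(f"{raw!r} is not a boolean token")
    # text / collection / custom / unspecified: verbatim
    return raw


def parse_submission(raw: dict, form: FormSpec) -> ParsedSubmission:
    """Parse a raw text mapping against a form.

    In the design context a value ``#name`` yields a DynamicRef; ``\\#`` at the
    start of a text value escapes a literal ``#``.  All problems are collected
    as issues — this function never raises on bad input.
    """
    result = ParsedSubmission()
    known = {f.name for f in form.fields}
    if form.save_field is not None:
        known.add(form.save_field.name)
    for key in raw:
        if key not in known:
            result.issues.append(FieldIssue(key, "unknown-field",
                                            f"form has no field named {key!r}"))
    for f in form.fields:
        if f.name not in raw or raw[f.name] == "":
            if f.has_default:
                result.values[f.name] = f.default
            else:
                result.issues.append(FieldIssue(
                    f.name, "missing-required", f"required field {f.name!r} missing"))
            continue
        value = raw[f.name]
        if isinstance(value, str) and value.startswith("#"):
            name = value[1:]
            if not f.allow_dynamic:
                result.issues.append(FieldIssue(
                    f.name, "dynamic-not-allowed",
                    "dynamic (#) parameters are only allowed when designing workflows"))
                continue
            if not is_identifier(name):
                result.issues.append(FieldIssue(
                    f.name, "dynamic-syntax",
                    f"'#' must be followed by an identifier, got {name!r}"))
                continue
            result.values[f.name] = DynamicRef(name)
            continue
        if isinstance(value, str) and value.startswith("\\#"):
            value = value[1:]  # escaped literal '#...'
        if not isinstance(value, str):
            result.values[f.name] = value  # already typed (JSON API clients)
            continue
        try:
            result.values[f.name] = coerce(value, f.type_tag)
        except ValueError as exc:
            result.issues.append(FieldIssue(f.name, "not-coercible", str(exc)))
    if form.save_field is not None and raw.get("save_as"):
        save = raw["save_as"]
        if not is_identifier(save):
            result.issues.append(FieldIssue(
                "save_as", "not-coercible", f"save name {save!r} is not an identifier"))
        else:
            result.values["save_as"] = save
    return result


def render(values: dict, form: FormSpec) -> dict:
    """Render typed values back to the raw text a client would submit.

    Inverse of :func:`parse_submission` on well-typed literals.
    """
    out = {}
    for f in form.fields:
        if f.name not in values:
            continue
        v = values[f.name]
        if isinstance(v, DynamicRef):
            out[f.name] = f"#{v.name}"
        elif isinstance(v, bool):
            out[f.name] = "true" if v else "false"
        elif isinstance(v, str) and v.startswith("#"):
            out[f.name] = "\\" + v
        else:
            out[f.name] = str(v)
    return out
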