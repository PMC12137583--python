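"""Capture live instrument instances into a serializable platform abstraction.

The orchestrator does not require instrument drivers to implement any
interface: it walks a mapping of name -> object (typically the globals of the
user's control script), keeps the objects whose type is user-defined, and
records every public, non-property method with its parameter signature, type
tags, defaults and docstring.  The result — a :class:`PlatformAbstraction` —
is the single source of truth for form generation, workflow validation and
direct control, and it serializes to a JSON snapshot so experimental design
can continue offline, away from the hardware.
"""

from __future__ import annotations

import datetime as _dt
import inspect
import json
import sys
import types
from dataclasses import dataclass, field

from .errors import (
    IncludeExcludeConflictError,
    MissingBindingError,
    SnapshotFormatError,
)
from .refs import is_identifier

# ---------------------------------------------------------------------------
# type tags

TYPE_TAGS = ("integer", "real", "boolean", "text", "collection", "custom", "unspecified")

_COLLECTION_TYPES = (list, tuple, set, frozenset, dict)

_NAME_TO_TAG = {
    "int": "integer",
    "float": "real",
    "bool": "boolean",
    "str": "text",
    "list": "collection",
    "tuple": "collection",
    "set": "collection",
    "frozenset": "collection",
    "dict": "collection",
    "List": "collection",
    "Tuple": "collection",
    "Set": "collection",
    "Dict": "collection",
    "Sequence": "collection",
    "Mapping": "collection",
    "None": "unspecified",
}


def type_tag_of(annotation) -> str:
    """Map a signature annotation to one of the abstraction's type tags.

    Unannotated parameters map to ``unspecified`` (rendered as free text and
    never validated); annotations that are neither primitives nor standard
    collections map to ``custom``.
    """
    if annotation is inspect.Parameter.empty or annotation is None:
        return "unspecified"
    if isinstance(annotation, str):  # postponed annotations arrive as strings
        base = annotation.split("[", 1)[0].strip().rsplit(".", 1)[-1]
        return _NAME_TO_TAG.get(base, "custom")
    origin = getattr(annotation, "__origin__", None)
    if origin is not None:
        return "collection" if origin in _COLLECTION_TYPES else "custom"
    if isinstance(annotation, type):
        if issubclass(annotation, bool):
            return "boolean"
        if issubclass(annotation, int):
            return "integer"
        if issubclass(annotation, float):
            return "real"
        if issubclass(annotation, str):
            return "text"
        if annotation in _COLLECTION_TYPES:
            return "collection"
        if annotation is type(None):
            return "unspecified"
        return "custom"
    return "custom"


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class ParameterSpec:
    """One method parameter: name, type tag, default, and whether required.

    ``required`` is true exactly when no default exists.
    """

    name: str
    type_tag: str = "unspecified"
    default: object = None
    has_default: bool = False

    def __post_init__(self):
        if not is_identifier(self.name):
            raise ValueError(f"invalid parameter name: {self.name!r}")
        if self.type_tag not in TYPE_TAGS:
            raise ValueError(f"unknown type tag: {self.type_tag!r}")

    @property
    def required(self) -> bool:
        return not self.has_default


@dataclass(frozen=True)
class MethodRecord:
    """A public method: its parameters (receiver excluded), doc and return tag."""

    name: str
    parameters: tuple = ()
    doc: str | None = None
    return_tag: str = "unspecified"


@dataclass(frozen=True)
class ModuleRecord:
    """One captured instrument instance and its callable surface."""

    instance_name: str
    type_name: str
    methods: tuple = ()

    def method(self, name: str) -> MethodRecord | None:
        for m in self.methods:
            if m.name == name:
                return m
        return None


@dataclass
class PlatformAbstraction:
    """The serialized capture of a control script's instrument instances."""

    modules: dict = field(default_factory=dict)  # instance_name -> ModuleRecord
    source_label: str = ""
    created_at: str = ""

    def module(self, name: str) -> ModuleRecord | None:
        return self.modules.get(name)

    def resolve(self, component: str, method: str) -> MethodRecord | None:
        mod = self.modules.get(component)
        return mod.method(method) if mod else None

    def structurally_equal(self, other: "PlatformAbstraction") -> bool:
        """Equality ignoring timestamps and source labels."""
        return self.modules == other.modules

    # -- JSON document ------------------------------------------------------

    def to_json_obj(self) -> dict:
        return {
            "source_label": self.source_label,
            "created_at": self.created_at,
            "modules": {
                name: {
                    "type_name": mod.type_name,
                    "methods": [
                        {
                            "name": m.name,
                            "doc": m.doc,
                            "return_tag": m.return_tag,
                            "parameters": [
                                {
                                    "name": p.name,
                                    "type_tag": p.type_tag,
                                    "required": p.required,
                                    **({"default": p.default} if p.has_default else {}),
                                }
                                for p in m.parameters
                            ],
                        }
                        for m in mod.methods
                    ],
                }
                for name, mod in sorted(self.modules.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_obj(), sort_keys=True, indent=2)

    @classmethod
    def from_json_obj(cls, obj: dict) -> "PlatformAbstraction":
        try:
            modules = {}
            for name, mod in obj["modules"].items():
                methods = []
                for m in mod["methods"]:
                    params = []
                    for p in m["parameters"]:
                        has_default = "default" in p
                        if has_default == p["required"]:
                            raise ValueError(
                                f"parameter {p['name']!r}: required flag inconsistent "
                                "with presence of default"
                            )
                        params.append(
                            ParameterSpec(
                                name=p["name"],
                                type_tag=p["type_tag"],
                                default=p.get("default"),
                                has_default=has_default,
                            )
                        )
                    methods.append(
                        MethodRecord(
                            name=m["name"],
                            parameters=tuple(params),
                            doc=m.get("doc"),
                            return_tag=m.get("return_tag", "unspecified"),
                        )
                    )
                modules[name] = ModuleRecord(
                    instance_name=name,
                    type_name=mod["type_name"],
                    methods=tuple(methods),
                )
            return cls(
                modules=modules,
                source_label=obj.get("source_label", ""),
                created_at=obj.get("created_at", ""),
            )
        except (KeyError, TypeError, AttributeError, ValueError) as exc:
            raise SnapshotFormatError(f"malformed abstraction document: {exc}") from exc


# ---------------------------------------------------------------------------
# capture


def _is_user_defined_instance(obj) -> bool:
    """True when obj is an instance of a user-defined (non-stdlib) class.

    Modules, functions, classes themselves, and primitive / collection
    literals are never instruments.
    """
    if isinstance(obj, (types.ModuleType, types.FunctionType, types.BuiltinFunctionType,
                        types.MethodType, type)):
        return False
    if obj is None or isinstance(obj, (bool, int, float, complex, str, bytes, bytearray,
                                       list, tuple, set, frozenset, dict, range)):
        return False
    cls = type(obj)
    top = (cls.__module__ or "").split(".", 1)[0]
    if top == "builtins" or top in sys.stdlib_module_names:
        return False
    return True


def describe_instance(obj) -> list[MethodRecord]:
    """Return one record per public, non-property, non-special method of obj.

    Inherited methods are included, except anything defined on ``object``
    itself.  Properties and underscore-prefixed names never appear.  Static
    and class methods are included; the bound receiver is excluded from the
    parameter list (binding through the instance drops it automatically).
    """
    cls = type(obj)
    records = []
    for name in sorted(dir(cls)):
        if name.startswith("_"):
            continue
        static_attr = inspect.getattr_static(cls, name, None)
        if isinstance(static_attr, property) or inspect.isdatadescriptor(static_attr):
            continue
        if not any(name in vars(k) for k in cls.__mro__[:-1]):
            continue  # defined only on the universal base type
        attr = getattr(obj, name, None)
        if not callable(attr):
            continue
        try:
            sig = inspect.signature(attr)
        except (TypeError, ValueError):
            continue
        params = []
        for pname, p in sig.parameters.items():
            if pname in ("self", "cls"):
                continue
            if p.kind in (inspect.Parameter.VAR_POSITIONAL, inspect.Parameter.VAR_KEYWORD):
                continue
            has_default = p.default is not inspect.Parameter.empty
            params.append(
                ParameterSpec(
                    name=pname,
                    type_tag=type_tag_of(p.annotation),
                    default=p.default if has_default else None,
                    has_default=has_default,
                )
            )
        records.append(
            MethodRecord(
                name=name,
                parameters=tuple(params),
                doc=inspect.getdoc(attr),
                return_tag=type_tag_of(
                    sig.return_annotation
                    if sig.return_annotation is not inspect.Signature.empty
                    else inspect.Parameter.empty
                ),
            )
        )
    return records


def capture(bindings: dict, include=None, exclude=None,
            source_label: str = "") -> PlatformAbstraction:
    """Capture a namespace of instrument instances into an abstraction.

    Parameters
    ----------
    bindings
        Mapping of names to live objects — typically ``globals()`` of the
        control script.  Only instances of user-defined types are kept.
    include, exclude
        Optional name sets restricting the capture.  A name in both raises
        :class:`IncludeExcludeConflictError`; an include name absent from the
        bindings raises :class:`MissingBindingError`.
    """
    include = set(include) if include is not None else None
    exclude = set(exclude) if exclude is not None else set()
    if include is not None:
        conflict = include & exclude
        if conflict:
            raise IncludeExcludeConflictError(
                f"names in both include and exclude: {sorted(conflict)}"
            )
        missing = include - set(bindings)
        if missing:
            raise MissingBindingError(
                f"include names not present in bindings: {sorted(missing)}"
            )
    modules = {}
    for name, obj in bindings.items():
        if not is_identifier(name) or name.startswith("_"):
            continue
        if include is not None and name not in include:
            continue
        if name in exclude:
            continue
        if not _is_user_defined_instance(obj):
            continue
        modules[name] = ModuleRecord(
            instance_name=name,
            type_name=type(obj).__name__,
            methods=tuple(describe_instance(obj)),
        )
    return PlatformAbstraction(
        modules=modules,
        source_label=source_label,
        created_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


# ---------------------------------------------------------------------------
# snapshots


def save_snapshot(abstraction: PlatformAbstraction, path) -> None:
    """Write the abstraction to a JSON snapshot file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(abstraction.to_json())
        fh.write("\n")


def load_snapshot(path) -> PlatformAbstraction:
    """Load a JSON snapshot; raises :class:`SnapshotFormatError` if corrupt."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
    except OSError as exc:
        raise SnapshotFormatError(f"cannot read snapshot: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise SnapshotFormatError(f"snapshot is not valid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise SnapshotFormatError("snapshot root must be a JSON object")
    return PlatformAbstraction.from_json_obj(obj)
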