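"""Dynamic and variable references used inside workflow documents.

A *dynamic* parameter (``#name`` in the design interface) is bound at execution
time, once per iteration.  A *variable* reference names a value saved earlier in
the same phase (a ``save_as`` capture or a ``define`` step).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def is_identifier(name: object) -> bool:
    return isinstance(name, str) and bool(IDENTIFIER_RE.match(name))


@dataclass(frozen=True)
class DynamicRef:
    """A per-iteration configurable parameter, written ``#name``."""

    name: str

    def __post_init__(self):
        if not is_identifier(self.name):
            raise ValueError(f"invalid dynamic parameter name: {self.name!r}")


@dataclass(frozen=True)
class VariableRef:
    """A reference to a value saved earlier in the same phase."""

    name: str

    def __post_init__(self):
        if not is_identifier(self.name):
            raise ValueError(f"invalid variable name: {self.name!r}")
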