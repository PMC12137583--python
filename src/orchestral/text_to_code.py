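"""Natural-language task descriptions -> workflow documents, post-validated.

The language-model client is injected (any object with ``send(prompt) ->
text``); this module owns only the prompt construction and the hard gate on
the way back: whatever the model emits is parsed with the same schema parser
and validated with the same validator as a human-authored workflow.  Nothing
reaches the executor through a side door.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from .compiler import ValidationIssue, errors_of, validate
from .errors import ExtractionError, SchemaError, UnusableAbstractionError
from .workflow import WorkflowScript, from_document

try:
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    _resources = None

_FENCE_RE = re.compile(r"```(?:json)?\s*\n(.*?)```", re.DOTALL)


def _preamble() -> str:
    return (_resources.files("orchestral") / "resources" / "prompt_preamble.txt"
            ).read_text("utf-8")


def _format_example() -> str:
    return (_resources.files("orchestral") / "fixtures" / "fixture.workflow.json"
            ).read_text("utf-8")


@dataclass(frozen=True)
class PromptBundle:
    instruction_preamble: str
    abstraction_block: str
    format_example: str
    user_request: str

    @property
    def text(self) -> str:
        return "\n\n".join([
            self.instruction_preamble,
            "Available platform modules and methods (JSON):",
            self.abstraction_block,
            "Expected workflow document format (example):",
            self.format_example,
            "Task:",
            self.user_request,
        ])


def build_prompt(abstraction, request: str) -> PromptBundle:
    """Assemble the grounded prompt: instructions + abstraction + format example.

    Deterministic for fixed inputs.  Raises for an empty abstraction (there is
    nothing the model could legally call) or an empty request.
    """
    if not abstraction.modules:
        raise UnusableAbstractionError(
            "cannot build a prompt from an abstraction with no modules")
    if not request or not request.strip():
        raise ValueError("task request must be nonempty")
    return PromptBundle(
        instruction_preamble=_preamble(),
        abstraction_block=abstraction.to_json(),
        format_example=_format_example(),
        user_request=request.strip(),
    )


def extract_json(text: str) -> tuple[str, list]:
    """Pull the first JSON document out of a model transcript.

    Fenced code blocks are tried first, in order; otherwise the first
    balanced ``{...}`` region that parses as JSON.  Returns (candidate text,
    warnings); raises :class:`ExtractionError` when nothing parses.
    """
    warnings = []
    candidates = _FENCE_RE.findall(text)
    parseable = []
    for c in candidates:
        try:
            json.loads(c)
            parseable.append(c)
        except json.JSONDecodeError:
            continue
    if not parseable:
        # brace scan outside fences
        depth, start = 0, None
        for i, ch in enumerate(text):
            if ch == "{":
                if depth == 0:
                    start = i
                depth += 1
            elif ch == "}" and depth > 0:
                depth -= 1
                if depth == 0:
                    chunk = text[start:i + 1]
                    try:
                        json.loads(chunk)
                        parseable.append(chunk)
                    except json.JSONDecodeError:
                        pass
    if not parseable:
        raise ExtractionError("no JSON document found in the model output")
    if len(parseable) > 1:
        warnings.append(ValidationIssue(
            "warning", "multiple-json-candidates",
            f"output contained {len(parseable)} JSON candidates; using the first"))
    return parseable[0], warnings


def parse_and_validate(model_output: str, abstraction):
    """Return a validated :class:`WorkflowScript`, or the issue list.

    Total: any input string yields either a valid script or diagnostics —
    never an exception escape.  The validation path is exactly the one used
    for human-authored documents.
    """
    try:
        candidate, warnings = extract_json(model_output)
    except ExtractionError as exc:
        return [ValidationIssue("error", "no-json-found", str(exc))]
    try:
        w = from_document(candidate)
    except SchemaError as exc:
        return warnings + [
            ValidationIssue("error", "schema-error", f"{pos}: {msg}" if pos else msg)
            for pos, msg in exc.issues
        ]
    issues = validate(w, abstraction)
    if errors_of(issues):
        return warnings + issues
    return w
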