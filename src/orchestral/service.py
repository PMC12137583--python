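"""HTTP service over the orchestrator library, plus the one-call launcher.

The service is a plain WSGI application — every route is a thin adapter over
the library API (capture, forms, workflow storage, compiler, engine), so
anything reachable over HTTP is equally reachable and tested in-process.
Design and storage endpoints work offline from a snapshot alone; execution
endpoints require live instruments and refuse otherwise.

Real-time status uses an in-memory replay ring: every execution event is
appended with its monotone sequence number, and ``GET /api/status?since=k``
returns the events after ``k`` — a reconnecting client resumes exactly where
it left off.  (A push channel can sit on top; the ring is the contract.)

Routes
------
- ``GET  /api/abstraction`` — the captured platform abstraction
- ``GET  /api/forms/{module}/{method}?context=control|design`` — form schema
- ``POST /api/control/{module}/{method}`` — direct method invocation
- ``GET/POST /api/workflows`` ; ``GET/PUT/DELETE /api/workflows/{name}``
- ``POST /api/workflows/{name}/protect`` — set the protected flag
- ``POST /api/workflows/{name}/validate`` ; ``.../compile``
- ``POST /api/runs`` — execute a stored workflow under an iteration plan
- ``GET  /api/runs/{id}`` ; ``POST /api/runs/{id}/abort``
- ``GET  /api/status?since=k`` — event replay
- ``POST /api/text2code/{name}`` — natural-language workflow design (optional)
"""

from __future__ import annotations

import json
import re
import threading
from dataclasses import dataclass, field
from wsgiref.simple_server import WSGIServer, WSGIRequestHandler, make_server

from . import text_to_code as _ttc
from .compiler import compile_workflow, errors_of, export_source, validate
from .engine import (
    Adaptive,
    Manual,
    ObjectiveSpec,
    ParameterRange,
    Repeat,
    available_modes,
    rows_from_csv,
    run as run_plan,
)
from .errors import (
    ModeError,
    OfflineError,
    OrchestralError,
    ProtectedWorkflowError,
    SchemaError,
    WorkflowExistsError,
    WorkflowNotFoundError,
)
from .forms import form_for, parse_submission
from .introspect import capture, load_snapshot
from .storage import WorkflowStore
from .workflow import from_document, to_document


@dataclass
class ServiceConfig:
    host: str = "127.0.0.1"
    port: int = 0  # 0 = pick a free port
    db_path: str = ":memory:"
    snapshot_path: str | None = None
    offline: bool = False
    log_level: str = "info"
    llm_client: object = None  # injected; absent -> text2code disabled
    replay_ring_size: int = 10_000


class _ReplayRing:
    """Bounded buffer of status events keyed by their sequence numbers."""

    def __init__(self, size: int):
        self.size = size
        self.events: list = []
        self.lock = threading.Lock()

    def append(self, event):
        with self.lock:
            self.events.append(event)
            if len(self.events) > self.size:
                del self.events[: len(self.events) - self.size]

    def since(self, seq: int) -> list:
        with self.lock:
            return [e for e in self.events if e.seq > seq]


class _HTTPError(Exception):
    def __init__(self, status: int, body: dict):
        self.status = status
        self.body = body


def _problem(status, code, message, **extra):
    return _HTTPError(status, {"error": {"code": code, "message": message, **extra}})


_STATUS_TEXT = {
    200: "200 OK", 201: "201 Created", 204: "204 No Content",
    400: "400 Bad Request", 404: "404 Not Found", 405: "405 Method Not Allowed",
    409: "409 Conflict", 422: "422 Unprocessable Entity",
    500: "500 Internal Server Error", 503: "503 Service Unavailable",
}


@dataclass
class RunInfo:
    run_id: int
    workflow: str
    mode: str
    status: str = "running"
    records: list = field(default_factory=list)
    abort_requested: bool = False


class OrchestratorService:
    """The WSGI application.  ``registry=None`` puts the service offline."""

    def __init__(self, abstraction, registry=None, store=None,
                 config: ServiceConfig | None = None):
        self.config = config or ServiceConfig()
        self.abstraction = abstraction
        self.registry = registry
        self.store = store or WorkflowStore(self.config.db_path)
        self.ring = _ReplayRing(self.config.replay_ring_size)
        self.runs: dict[int, RunInfo] = {}
        self._run_seq = 0
        self._idempotency: dict[str, tuple] = {}
        self._lock = threading.Lock()

    @property
    def offline(self) -> bool:
        return self.registry is None

    # ------------------------------------------------------------------ wsgi

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        try:
            status, body = self._dispatch(method, path, environ)
        except _HTTPError as exc:
            status, body = exc.status, exc.body
        except OrchestralError as exc:
            status, body = 400, {"error": {"code": type(exc).__name__,
                                           "message": str(exc)}}
        except Exception as exc:  # pragma: no cover - defensive
            status, body = 500, {"error": {"code": "internal", "message": str(exc)}}
        payload = json.dumps(body).encode("utf-8")
        start_response(_STATUS_TEXT.get(status, f"{status} ?"), [
            ("Content-Type", "application/json"),
            ("Content-Length", str(len(payload))),
        ])
        return [payload]

    def _read_json(self, environ) -> dict:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        raw = environ["wsgi.input"].read(length) if length else b""
        if not raw:
            return {}
        try:
            obj = json.loads(raw.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise _problem(400, "bad-json", f"request body is not valid JSON: {exc}")
        if not isinstance(obj, dict):
            raise _problem(400, "bad-json", "request body must be a JSON object")
        return obj

    def _dispatch(self, method, path, environ):
        # idempotent retry: replay the cached response for a repeated request id
        req_id = environ.get("HTTP_X_REQUEST_ID")
        if req_id and method in ("POST", "PUT", "DELETE"):
            with self._lock:
                if req_id in self._idempotency:
                    return self._idempotency[req_id]
        result = self._route(method, path, environ)
        if req_id and method in ("POST", "PUT", "DELETE"):
            with self._lock:
                self._idempotency[req_id] = result
        return result

    def _route(self, method, path, environ):
        qs = environ.get("QUERY_STRING", "")
        params = dict(p.split("=", 1) for p in qs.split("&") if "=" in p)

        if path == "/api/abstraction" and method == "GET":
            return 200, self.abstraction.to_json_obj()

        m = re.fullmatch(r"/api/forms/([\w]+)/([\w]+)", path)
        if m and method == "GET":
            rec = self._resolve(m.group(1), m.group(2))
            context = params.get("context", "control")
            if context not in ("control", "design"):
                raise _problem(400, "bad-context", f"unknown context {context!r}")
            return 200, form_for(rec, m.group(1), context).to_json_obj()

        m = re.fullmatch(r"/api/control/([\w]+)/([\w]+)", path)
        if m and method == "POST":
            return self._call_method_route(m.group(1), m.group(2), environ)

        if path == "/api/workflows":
            if method == "GET":
                return 200, {"workflows": self.store.list_workflows()}
            if method == "POST":
                return self._save_workflow_route(environ, None)
            raise _problem(405, "method-not-allowed", method)

        m = re.fullmatch(r"/api/workflows/([\w.-]+)", path)
        if m:
            name = m.group(1)
            if method == "GET":
                stored = self._get_stored(name)
                return 200, {"name": stored.name, "protected": stored.protected,
                             "document": json.loads(stored.document)}
            if method == "PUT":
                return self._save_workflow_route(environ, name)
            if method == "DELETE":
                try:
                    self.store.delete_workflow(name)
                except WorkflowNotFoundError as exc:
                    raise _problem(404, "not-found", str(exc))
                except ProtectedWorkflowError as exc:
                    raise _problem(409, "protected", str(exc))
                return 200, {"deleted": name}
            raise _problem(405, "method-not-allowed", method)

        m = re.fullmatch(r"/api/workflows/([\w.-]+)/protect", path)
        if m and method == "POST":
            body = self._read_json(environ)
            flag = bool(body.get("protected", True))
            try:
                self.store.set_protected(m.group(1), flag)
            except WorkflowNotFoundError as exc:
                raise _problem(404, "not-found", str(exc))
            return 200, {"name": m.group(1), "protected": flag}

        m = re.fullmatch(r"/api/workflows/([\w.-]+)/validate", path)
        if m and method == "POST":
            w = self._load(m.group(1))
            issues = validate(w, self.abstraction)
            return 200, {"issues": [i.to_json_obj() for i in issues],
                         "ok": not errors_of(issues)}

        m = re.fullmatch(r"/api/workflows/([\w.-]+)/compile", path)
        if m and method == "POST":
            w = self._load(m.group(1))
            issues = validate(w, self.abstraction)
            if errors_of(issues):
                raise _HTTPError(422, {"error": {"code": "validation-failed",
                                                 "message": "document has validation errors"},
                                       "issues": [i.to_json_obj() for i in issues]})
            plan = compile_workflow(w, self.abstraction)
            return 200, {
                "dynamic_signature": [{"name": n, "type_tag": t}
                                      for n, t in plan.dynamic_signature],
                "outputs": plan.output_spec,
                "modes": sorted(available_modes(plan)),
                "source": export_source(w),
            }

        if path == "/api/runs" and method == "POST":
            return self._start_run_route(environ)

        m = re.fullmatch(r"/api/runs/(\d+)", path)
        if m and method == "GET":
            return 200, self._run_json(self._get_run(int(m.group(1))))

        m = re.fullmatch(r"/api/runs/(\d+)/abort", path)
        if m and method == "POST":
            info = self._get_run(int(m.group(1)))
            info.abort_requested = True
            if info.status == "running":
                info.status = "abort_requested"
            return 200, {"run_id": info.run_id, "status": info.status}

        if path == "/api/status" and method == "GET":
            try:
                since = int(params.get("since", 0))
            except ValueError:
                raise _problem(400, "bad-since", "since must be an integer")
            return 200, {"events": [e.to_json_obj() for e in self.ring.since(since)]}

        m = re.fullmatch(r"/api/text2code/([\w.-]+)", path)
        if m and method == "POST":
            return self._text2code_route(environ, m.group(1))

        raise _problem(404, "no-such-route", f"{method} {path}")

    # ------------------------------------------------------------ helpers

    def _resolve(self, module, method):
        rec = self.abstraction.resolve(module, method)
        if rec is None:
            raise _problem(404, "unknown-method",
                           f"no method {module}.{method} in the abstraction")
        return rec

    def _get_stored(self, name):
        try:
            return self.store.get_document(name)
        except WorkflowNotFoundError as exc:
            raise _problem(404, "not-found", str(exc))

    def _load(self, name):
        try:
            return self.store.load_workflow(name)
        except WorkflowNotFoundError as exc:
            raise _problem(404, "not-found", str(exc))

    def _get_run(self, run_id):
        info = self.runs.get(run_id)
        if info is None:
            raise _problem(404, "no-such-run", f"no run with id {run_id}")
        return info

    # ------------------------------------------------------------ routes

    def call_method(self, module, method, raw_args: dict) -> dict:
        """Direct control: parse raw args against the control form and invoke.

        Returns an ``{ok, value | error, issues?}`` envelope; parse issues
        leave the device untouched.
        """
        if self.offline:
            raise OfflineError(
                "service is offline (designing from a snapshot); "
                "direct control requires live instruments")
        rec = self.abstraction.resolve(module, method)
        if rec is None:
            raise _problem(404, "unknown-method",
                           f"no method {module}.{method} in the abstraction")
        form = form_for(rec, module, "control")
        parsed = parse_submission(raw_args, form)
        if not parsed.ok:
            return {"ok": False, "issues": [
                {"field": i.field, "code": i.code, "message": i.message}
                for i in parsed.issues]}
        device = self.registry[module]
        try:
            value = getattr(device, method)(**parsed.values)
        except Exception as exc:
            return {"ok": False, "error": {"code": "device-error", "message": str(exc)}}
        return {"ok": True, "value": value}

    def _call_method_route(self, module, method, environ):
        try:
            envelope = self.call_method(module, method, self._read_json(environ))
        except OfflineError as exc:
            raise _problem(503, "offline", str(exc))
        if envelope["ok"]:
            return 200, envelope
        if "issues" in envelope:
            return 422, envelope
        return 500, envelope

    def _save_workflow_route(self, environ, name):
        body = self._read_json(environ)
        if name is None:
            name = body.get("name")
        if not name:
            raise _problem(400, "missing-name", "workflow name required")
        doc = body.get("document")
        if doc is None:
            raise _problem(400, "missing-document", "workflow document required")
        text = doc if isinstance(doc, str) else json.dumps(doc)
        try:
            w = from_document(text)
        except SchemaError as exc:
            raise _HTTPError(422, {"error": {"code": "schema-error",
                                             "message": "invalid workflow document"},
                                   "issues": [{"position": p, "message": m}
                                              for p, m in exc.issues]})
        overwrite = bool(body.get("overwrite", False))
        try:
            stored = self.store.save_workflow(name, w, overwrite=overwrite)
        except WorkflowExistsError as exc:
            raise _problem(409, "exists", str(exc))
        except ProtectedWorkflowError as exc:
            raise _problem(409, "protected", str(exc))
        return 201, {"name": stored.name, "protected": stored.protected}

    def _start_run_route(self, environ):
        if self.offline:
            raise _problem(503, "offline",
                           "workflow execution requires live instruments; "
                           "this service is designing from a snapshot")
        body = self._read_json(environ)
        name = body.get("workflow")
        if not name:
            raise _problem(400, "missing-workflow", "workflow name required")
        w = self._load(name)
        issues = validate(w, self.abstraction)
        if errors_of(issues):
            raise _HTTPError(422, {"error": {"code": "validation-failed",
                                             "message": "document has validation errors"},
                                   "issues": [i.to_json_obj() for i in issues]})
        plan = compile_workflow(w, self.abstraction)
        mode = body.get("mode")
        payload = body.get("payload", {})
        try:
            iteration = self._iteration_plan(plan, mode, payload)
        except (ModeError, OrchestralError) as exc:
            raise _problem(409, "mode-unavailable", str(exc),
                           available=sorted(available_modes(plan)))
        with self._lock:
            self._run_seq += 1
            info = RunInfo(run_id=self._run_seq, workflow=name, mode=mode)
            self.runs[info.run_id] = info
        try:
            records = run_plan(plan, iteration, self.registry, sink=self.ring.append)
            info.records = records
            info.status = "completed" if all(
                r.status == "completed" for r in records) else "finished_with_failures"
        except OrchestralError as exc:
            info.status = "error"
            raise _problem(409, "run-refused", str(exc))
        return 201, self._run_json(info)

    def _iteration_plan(self, plan, mode, payload):
        modes = available_modes(plan)
        if mode not in modes:
            raise ModeError(
                f"mode {mode!r} is not available for this workflow "
                f"(available: {sorted(modes)}; adaptive additionally requires "
                "a numeric saved output)")
        if mode == "repeat":
            return Repeat(int(payload.get("n", 1)))
        if mode == "manual":
            return Manual(payload.get("rows", []))
        if mode == "csv":
            rows = rows_from_csv(payload.get("csv", ""), plan.dynamic_signature)
            return Manual(rows)
        # adaptive
        space = []
        for p in payload.get("space", []):
            if "choices" in p:
                space.append(ParameterRange(p["name"], choices=tuple(p["choices"])))
            else:
                space.append(ParameterRange(p["name"], lower=float(p["lower"]),
                                            upper=float(p["upper"])))
        objectives = [ObjectiveSpec(o["output_name"], o.get("goal", "none"))
                      for o in payload.get("objectives", [])]
        return Adaptive(space=space, objectives=objectives,
                        budget=int(payload.get("budget", 10)),
                        seed=int(payload.get("seed", 0)),
                        backend=payload.get("backend", "coordinate"))

    def _run_json(self, info: RunInfo):
        return {
            "run_id": info.run_id,
            "workflow": info.workflow,
            "mode": info.mode,
            "status": info.status,
            "records": [
                {"iteration_index": r.iteration_index, "bindings": r.bindings,
                 "outputs": r.outputs, "status": r.status}
                for r in info.records
            ],
        }

    def _text2code_route(self, environ, name):
        if self.config.llm_client is None:
            raise _problem(503, "feature-disabled",
                           "no language-model client configured")
        body = self._read_json(environ)
        request = body.get("request", "")
        bundle = _ttc.build_prompt(self.abstraction, request)
        output = self.config.llm_client.send(bundle.text)
        result = _ttc.parse_and_validate(output, self.abstraction)
        if isinstance(result, list):
            return 422, {"issues": [i.to_json_obj() for i in result]}
        self.store.save_workflow(name, result, overwrite=True)
        return 201, {"name": name, "document": json.loads(to_document(result))}


# ---------------------------------------------------------------------------
# launcher


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, *args):  # keep stdout clean; structured logs go elsewhere
        pass


@dataclass
class ServiceHandle:
    service: OrchestratorService
    server: WSGIServer
    thread: threading.Thread

    @property
    def url(self) -> str:
        host, port = self.server.server_address[:2]
        return f"http://{host}:{port}"

    @property
    def app(self):
        return self.service

    def stop(self):
        self.server.shutdown()
        self.thread.join(timeout=5)
        self.server.server_close()


def launch(bindings: dict | None = None, config: ServiceConfig | None = None,
           **capture_kwargs) -> ServiceHandle:
    """One-call launcher: capture the caller's instruments and start serving.

    ``launch(globals())`` from a control script captures its instrument
    instances, opens the workflow store, and serves the API; the returned
    handle supports graceful ``stop()``.  With ``config.offline=True`` and a
    snapshot path, no live objects are needed and execution endpoints refuse.
    """
    config = config or ServiceConfig()
    if config.offline:
        if not config.snapshot_path:
            raise OrchestralError(
                "offline mode requires a snapshot_path to design against")
        abstraction = load_snapshot(config.snapshot_path)
        registry = None
    else:
        bindings = bindings or {}
        abstraction = capture(bindings, **capture_kwargs)
        registry = {name: bindings[name] for name in abstraction.modules}
    service = OrchestratorService(abstraction, registry=registry, config=config)
    server = make_server(config.host, config.port, service,
                         handler_class=_QuietHandler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return ServiceHandle(service=service, server=server, thread=thread)
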