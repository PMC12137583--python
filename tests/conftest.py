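import io
import json

import pytest

import orchestral as o


@pytest.fixture
def sdl_platform():
    """The abstract SDL trio (balance / pump / sdl) and its shared call log."""
    bindings, log = o.virtual.make_abstract_sdl(seed=0)
    return bindings, log


@pytest.fixture
def abstraction(sdl_platform):
    bindings, _ = sdl_platform
    return o.capture(bindings)


@pytest.fixture
def workflows():
    return o.virtual.fixture_workflows()


@pytest.fixture
def color_platform():
    return o.virtual.make_color_platform(target=(0.3, 0.7), noise_sd=0.0)


class Client:
    """Minimal in-process WSGI client returning (status_code, json_body)."""

    def __init__(self, app):
        self.app = app

    def request(self, method, path, body=None, query="", headers=None):
        raw = json.dumps(body).encode() if body is not None else b""
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": path,
            "QUERY_STRING": query,
            "CONTENT_LENGTH": str(len(raw)),
            "wsgi.input": io.BytesIO(raw),
        }
        for k, v in (headers or {}).items():
            environ["HTTP_" + k.upper().replace("-", "_")] = v
        captured = {}

        def start_response(status, response_headers):
            captured["status"] = int(status.split()[0])

        data = b"".join(self.app(environ, start_response))
        return captured["status"], json.loads(data)

    def get(self, path, **kw):
        return self.request("GET", path, **kw)

    def post(self, path, body=None, **kw):
        return self.request("POST", path, body, **kw)

    def put(self, path, body=None, **kw):
        return self.request("PUT", path, body, **kw)

    def delete(self, path, **kw):
        return self.request("DELETE", path, **kw)


@pytest.fixture
def live_service(sdl_platform):
    bindings, log = sdl_platform
    svc = o.OrchestratorService(o.capture(bindings), registry=bindings)
    return Client(svc), svc, log
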