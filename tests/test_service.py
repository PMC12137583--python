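"""The HTTP surface: thin adapter over the library, online and offline."""

import pytest

import orchestral as o
from tests.conftest import Client


def save(client, name, w, **extra):
    status, body = client.post("/api/workflows",
                               {"name": name, "document": o.to_document(w), **extra})
    assert status == 201, body
    return body


def test_abstraction_endpoint_lists_modules(live_service):
    client, _, _ = live_service
    status, body = client.get("/api/abstraction")
    assert status == 200
    assert sorted(body["modules"]) == ["balance", "pump", "sdl"]


def test_form_endpoint_mirrors_library_schema(live_service, abstraction):
    client, _, _ = live_service
    status, body = client.get("/api/forms/sdl/analyze", query="context=design")
    assert status == 200
    expected = o.form_for(abstraction.resolve("sdl", "analyze"), "sdl", "design")
    assert body == expected.to_json_obj()


def test_workflow_crud_cycle(live_service, workflows):
    client, _, _ = live_service
    save(client, "wf", workflows["constant"])
    status, body = client.get("/api/workflows/wf")
    assert status == 200 and body["document"]["name"] == "constant"
    status, body = client.post("/api/workflows",
                               {"name": "wf", "document": o.to_document(workflows["fixture"])})
    assert status == 409  # exists, no overwrite
    status, _ = client.put("/api/workflows/wf",
                           {"document": o.to_document(workflows["fixture"]),
                            "overwrite": True})
    assert status == 201
    status, body = client.get("/api/workflows")
    assert [s["name"] for s in body["workflows"]] == ["wf"]
    assert client.delete("/api/workflows/wf")[0] == 200
    assert client.get("/api/workflows/wf")[0] == 404


def test_protected_workflow_rejected_over_http(live_service, workflows):
    client, _, _ = live_service
    save(client, "locked", workflows["constant"])
    assert client.post("/api/workflows/locked/protect", {"protected": True})[0] == 200
    status, _ = client.put("/api/workflows/locked",
                           {"document": o.to_document(workflows["fixture"]),
                            "overwrite": True})
    assert status == 409
    assert client.delete("/api/workflows/locked")[0] == 409


def test_invalid_document_rejected_with_issue_list(live_service):
    client, _, _ = live_service
    status, body = client.post("/api/workflows",
                               {"name": "bad", "document": {"schema": 1, "name": "x",
                                                            "phases": {"prep": []}}})
    assert status == 422
    assert any("missing" in i["message"] for i in body["issues"])


def test_validate_and_compile_endpoints(live_service, workflows):
    client, _, _ = live_service
    save(client, "fx", workflows["fixture"])
    status, body = client.post("/api/workflows/fx/validate")
    assert status == 200 and body["ok"] and body["issues"] == []
    status, body = client.post("/api/workflows/fx/compile")
    assert status == 200
    assert body["dynamic_signature"] == [{"name": "param_1", "type_tag": "real"},
                                         {"name": "param_2", "type_tag": "real"}]
    assert body["modes"] == ["adaptive", "csv", "manual"]
    assert "def main(param_1, param_2):" in body["source"]


def test_direct_control_invokes_device(live_service):
    client, _, log = live_service
    status, body = client.post("/api/control/balance/weigh", {})
    assert status == 200 and body["ok"] and isinstance(body["value"], float)
    assert log.transcript() == [("balance", "weigh", ())]


def test_direct_control_validation_leaves_device_untouched(live_service):
    client, _, log = live_service
    status, body = client.post("/api/control/pump/dose", {"volume": "abc"})
    assert status == 422 and not body["ok"]
    assert body["issues"][0]["field"] == "volume"
    assert log.transcript() == []  # call log empty: device never touched


def test_direct_control_rejects_dynamic_refs(live_service):
    client, _, log = live_service
    status, body = client.post("/api/control/sdl/analyze",
                               {"param_1": "#x", "param_2": "1.0"})
    assert status == 422
    assert any(i["code"] == "dynamic-not-allowed" for i in body["issues"])
    assert log.transcript() == []


def test_device_exception_surfaces_as_error_envelope(live_service):
    client, _, _ = live_service
    status, body = client.post("/api/control/pump/dose", {"volume": "-2.0"})
    assert status == 500 and body["error"]["code"] == "device-error"


def test_run_repeat_over_http_streams_phase_events(live_service, workflows):
    client, _, log = live_service
    save(client, "const", workflows["constant"])
    status, body = client.post("/api/runs", {"workflow": "const", "mode": "repeat",
                                             "payload": {"n": 2}})
    assert status == 201 and body["status"] == "completed"
    assert len(body["records"]) == 2
    # P, E, E, C on the device transcript
    tares = [i for i, (c, m, _) in enumerate(log.transcript())
             if (c, m) == ("balance", "tare")]
    assert tares[0] == 0 and tares[-1] == len(log.transcript()) - 1
    status, body = client.get("/api/status", query="since=0")
    cats = [e["category"] for e in body["events"]]
    assert cats[0] == "run_start" and cats[-1] == "run_end"


def test_adaptive_refused_without_numeric_output(live_service, workflows):
    client, _, _ = live_service
    save(client, "const", workflows["constant"])
    status, body = client.post("/api/runs", {"workflow": "const", "mode": "adaptive",
                                             "payload": {}})
    assert status == 409
    assert body["error"]["available"] == ["repeat"]
    assert "numeric" in body["error"]["message"]


def test_csv_run_over_http(live_service, workflows):
    client, _, _ = live_service
    save(client, "fx", workflows["fixture"])
    status, body = client.post("/api/runs", {
        "workflow": "fx", "mode": "csv",
        "payload": {"csv": "param_1,param_2\n0.5,0.5\n1.0,0.0\n"}})
    assert status == 201
    assert [r["outputs"]["score"] for r in body["records"]] == [0.0, 50.0]


def test_status_replay_from_seq_is_exactly_once(live_service, workflows):
    client, _, _ = live_service
    save(client, "const", workflows["constant"])
    client.post("/api/runs", {"workflow": "const", "mode": "repeat",
                              "payload": {"n": 1}})
    _, all_events = client.get("/api/status", query="since=0")
    k = all_events["events"][2]["seq"]
    _, tail = client.get("/api/status", query=f"since={k}")
    assert [e["seq"] for e in tail["events"]] == \
        [e["seq"] for e in all_events["events"] if e["seq"] > k]


def test_mutation_idempotent_under_request_id_retry(live_service, workflows):
    client, _, _ = live_service
    headers = {"X-Request-Id": "req-1"}
    first = client.post("/api/workflows",
                        {"name": "wf", "document": o.to_document(workflows["constant"])},
                        headers=headers)
    retry = client.post("/api/workflows",
                        {"name": "wf", "document": o.to_document(workflows["constant"])},
                        headers=headers)
    assert first == retry  # replayed, not re-executed
    assert first[0] == 201


def test_offline_service_designs_but_never_executes(workflows, abstraction,
                                                    tmp_path, sdl_platform):
    _, log = sdl_platform
    snap = tmp_path / "snap.json"
    o.save_snapshot(abstraction, snap)
    svc = o.OrchestratorService(o.load_snapshot(snap), registry=None)
    client = Client(svc)
    assert client.get("/api/abstraction")[0] == 200
    save(client, "fx", workflows["fixture"])
    assert client.post("/api/workflows/fx/validate")[1]["ok"]
    assert client.post("/api/workflows/fx/compile")[0] == 200
    status, body = client.post("/api/runs", {"workflow": "fx", "mode": "manual",
                                             "payload": {"rows": []}})
    assert status == 503 and body["error"]["code"] == "offline"
    assert client.post("/api/control/balance/weigh", {})[0] == 503
    assert log.transcript() == []  # provably no live instrument touched


def test_launch_serves_and_stops(sdl_platform, workflows):
    import json
    import urllib.request

    bindings, _ = sdl_platform
    handle = o.launch(bindings, o.ServiceConfig(port=0))
    try:
        with urllib.request.urlopen(handle.url + "/api/abstraction", timeout=5) as r:
            body = json.load(r)
        assert sorted(body["modules"]) == ["balance", "pump", "sdl"]
    finally:
        handle.stop()
    with pytest.raises(Exception):
        urllib.request.urlopen(handle.url + "/api/abstraction", timeout=1)


def test_text2code_disabled_without_client(live_service):
    client, _, _ = live_service
    status, body = client.post("/api/text2code/auto", {"request": "weigh the vial"})
    assert status == 503 and body["error"]["code"] == "feature-disabled"


def test_text2code_with_injected_client(sdl_platform, workflows):
    bindings, _ = sdl_platform

    class CannedLLM:
        def send(self, prompt):
            assert "balance" in prompt and "pump" in prompt
            return ("Here is your workflow:\n```json\n"
                    + o.to_document(workflows["fixture"]) + "\n```")

    svc = o.OrchestratorService(o.capture(bindings), registry=bindings,
                                config=o.ServiceConfig(llm_client=CannedLLM()))
    client = Client(svc)
    status, body = client.post("/api/text2code/auto", {"request": "analyze a sweep"})
    assert status == 201
    assert body["document"]["name"] == "fixture"
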