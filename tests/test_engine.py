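"""Phase semantics, iteration plans, CSV rows, and event streams."""

import pytest

import orchestral as o
from orchestral.errors import CellError, HeaderMismatchError, ModeError, PreRunError


def phases_of(log):
    """Collapse a call transcript into the phase pattern P/E/C.

    prep and cleanup of the shipped fixtures tare the balance; experiment
    steps touch pump/sdl/mixer.
    """
    out = []
    for component, method, _ in log.transcript():
        out.append("P/C" if (component, method) == ("balance", "tare") else "E")
    return out


def compiled(workflows, abstraction, name):
    return o.compile_workflow(workflows[name], abstraction)


def test_repeat_runs_prep_once_main_n_cleanup_once(workflows, abstraction, sdl_platform):
    devices, log = sdl_platform
    plan = compiled(workflows, abstraction, "constant")
    records = o.run(plan, o.Repeat(3), devices)
    assert [r.status for r in records] == ["completed"] * 3
    # transcript: tare | dose,run ×3 | tare
    assert phases_of(log) == ["P/C"] + ["E"] * 6 + ["P/C"]


def test_manual_rows_pass_through_verbatim(workflows, abstraction, sdl_platform):
    devices, log = sdl_platform
    plan = compiled(workflows, abstraction, "fixture")
    rows = [{"param_1": 1.0, "param_2": 2.0}, {"param_1": 3.0, "param_2": 4.0}]
    records = o.run(plan, o.Manual(rows), devices)
    analyze_args = [dict(args) for c, m, args in log.transcript()
                    if (c, m) == ("sdl", "analyze")]
    assert analyze_args == rows
    assert [r.bindings for r in records] == rows
    assert records[0].outputs["score"] == 100 * 0.25 + 100 * 2.25


def test_available_modes_gating(workflows, abstraction):
    assert o.available_modes(compiled(workflows, abstraction, "constant")) == {"repeat"}
    assert o.available_modes(compiled(workflows, abstraction, "fixture")) == \
        {"manual", "csv", "adaptive"}


def test_dynamic_params_with_non_numeric_output_excludes_adaptive(abstraction):
    w = o.WorkflowScript(name="nonnum", phases={
        "prep": (), "cleanup": (),
        "main": (
            o.ActionStep(id="s1", component="pump", method="dose",
                         args={"volume": o.DynamicRef("v")}),
            o.ActionStep(id="s2", component="balance", method="tare",
                         args={}, save_as="mark"),
        ),
    })
    plan = o.compile_workflow(w, abstraction)
    assert o.available_modes(plan) == {"manual", "csv"}


def test_mode_mismatch_rejected(workflows, abstraction, sdl_platform):
    devices, _ = sdl_platform
    with pytest.raises(ModeError):
        o.run(compiled(workflows, abstraction, "fixture"), o.Repeat(2), devices)
    with pytest.raises(ModeError):
        o.run(compiled(workflows, abstraction, "constant"),
              o.Manual([{"x": 1}]), devices)


def test_missing_registry_component_is_pre_run_error(workflows, abstraction,
                                                     sdl_platform):
    devices, log = sdl_platform
    partial = {"balance": devices["balance"]}
    with pytest.raises(PreRunError):
        o.run(compiled(workflows, abstraction, "constant"), o.Repeat(1), partial)
    assert log.transcript() == []  # nothing executed


def test_failing_step_aborts_but_cleanup_still_runs(workflows, abstraction,
                                                    sdl_platform):
    devices, log = sdl_platform
    plan = compiled(workflows, abstraction, "fixture")
    # dose rejects negative volumes -> row 2 fails at the pump step
    w2 = o.edit_args(workflows["fixture"], "s2", {"volume": o.DynamicRef("vol")})
    plan = o.compile_workflow(w2, abstraction)
    rows = [{"param_1": 1.0, "param_2": 1.0, "vol": 1.0},
            {"param_1": 1.0, "param_2": 1.0, "vol": -1.0},
            {"param_1": 1.0, "param_2": 1.0, "vol": 1.0}]
    records = o.run(plan, o.Manual(rows), devices, failure_policy="abort_run")
    assert [r.status for r in records] == ["completed", "failed"]
    assert phases_of(log)[-1] == "P/C"  # cleanup executed after the abort


def test_skip_to_next_policy_continues(workflows, abstraction, sdl_platform):
    devices, _ = sdl_platform
    w2 = o.edit_args(workflows["fixture"], "s2", {"volume": o.DynamicRef("vol")})
    plan = o.compile_workflow(w2, abstraction)
    rows = [{"param_1": 1.0, "param_2": 1.0, "vol": -1.0},
            {"param_1": 1.0, "param_2": 1.0, "vol": 1.0}]
    records = o.run(plan, o.Manual(rows), devices, failure_policy="skip_to_next")
    assert [r.status for r in records] == ["failed", "completed"]


def test_event_stream_invariants(workflows, abstraction, sdl_platform):
    devices, _ = sdl_platform
    events = []
    o.run(compiled(workflows, abstraction, "constant"), o.Repeat(2), devices,
          sink=events.append)
    seqs = [e.seq for e in events]
    assert seqs == sorted(seqs) and len(set(seqs)) == len(seqs)
    cats = [e.category for e in events]
    assert cats[0] == "run_start" and cats[-1] == "run_end"
    assert cats.count("step_start") == cats.count("step_end") + cats.count("step_error")
    # serial execution: every step_start is immediately closed before the next opens
    depth = 0
    for c in cats:
        if c == "step_start":
            depth += 1
            assert depth == 1
        elif c in ("step_end", "step_error"):
            depth -= 1


def test_saved_variables_reset_each_iteration(abstraction, sdl_platform):
    devices, _ = sdl_platform
    w = o.WorkflowScript(name="leak", phases={
        "prep": (), "cleanup": (),
        "main": (
            o.ControlStep(id="s1", kind="define", name="x", value=1.0),
            o.ActionStep(id="s2", component="pump", method="dose",
                         args={"volume": o.VariableRef("x")}),
            o.ActionStep(id="s3", component="sdl", method="analyze",
                         args={"param_1": o.DynamicRef("a"), "param_2": 0.5},
                         save_as="x"),
        ),
    })
    plan = o.compile_workflow(w, abstraction)
    records = o.run(plan, o.Manual([{"a": 0.5}, {"a": 0.5}]), devices)
    doses = [dict(args)["volume"] for c, m, args in
             devices["pump"]._log.transcript() if (c, m) == ("pump", "dose")]
    assert doses == [1.0, 1.0]  # iteration 2 sees the define, not iteration 1's save
    assert all(r.status == "completed" for r in records)


def test_rows_from_csv_parses_in_order():
    sig = [("param_1", "real"), ("param_2", "real")]
    rows = o.rows_from_csv("param_1,param_2\n1.0,2.0\n3.5,4.5\n", sig)
    assert rows == [{"param_1": 1.0, "param_2": 2.0},
                    {"param_1": 3.5, "param_2": 4.5}]


def test_rows_from_csv_header_mismatch():
    with pytest.raises(HeaderMismatchError):
        o.rows_from_csv("param_1,paramX\n1,2\n", [("param_1", "real"),
                                                  ("param_2", "real")])


def test_rows_from_csv_cell_error_names_position():
    with pytest.raises(CellError) as exc:
        o.rows_from_csv("param_1\n1.0\nabc\n", [("param_1", "real")])
    assert exc.value.row == 3 and exc.value.column == "param_1"


def test_rows_from_csv_integer_columns_coerced():
    rows = o.rows_from_csv("n\n3\n4\n", [("n", "integer")])
    assert rows == [{"n": 3}, {"n": 4}] and all(isinstance(r["n"], int) for r in rows)


def test_zero_data_rows_runs_prep_and_cleanup_only(workflows, abstraction,
                                                   sdl_platform):
    devices, log = sdl_platform
    plan = compiled(workflows, abstraction, "fixture")
    rows = o.rows_from_csv("param_1,param_2\n", plan.dynamic_signature)
    records = o.run(plan, o.Manual(rows), devices)
    assert records == []
    assert phases_of(log) == ["P/C", "P/C"]  # prep and cleanup, no experiment


def test_adaptive_budget_one(workflows, abstraction, color_platform):
    devices, _ = color_platform
    colorloop = workflows["colorloop"]
    plan = o.compile_workflow(colorloop, o.capture(devices))
    adaptive = o.Adaptive(
        space=[o.ParameterRange("red", 0.0, 1.0), o.ParameterRange("blue", 0.0, 1.0)],
        objectives=[o.ObjectiveSpec("score", "minimize")], budget=1, seed=3)
    records, trace = o.run_adaptive(plan, adaptive, devices)
    assert len(records) == 1 and len(trace) == 1
    assert trace[0] == records[0].outputs["score"]


def test_adaptive_requires_matching_space(workflows, abstraction, color_platform):
    devices, _ = color_platform
    plan = o.compile_workflow(workflows["colorloop"], o.capture(devices))
    with pytest.raises(ModeError):
        o.run_adaptive(plan, o.Adaptive(
            space=[o.ParameterRange("red", 0.0, 1.0)],
            objectives=[o.ObjectiveSpec("score", "minimize")],
            budget=2, seed=0), devices)


def test_adaptive_rejects_non_numeric_objective(abstraction, sdl_platform):
    devices, _ = sdl_platform
    w = o.WorkflowScript(name="nn", phases={
        "prep": (), "cleanup": (),
        "main": (
            o.ActionStep(id="s1", component="pump", method="dose",
                         args={"volume": o.DynamicRef("v")}),
            o.ActionStep(id="s2", component="sdl", method="analyze",
                         args={"param_1": o.DynamicRef("v"), "param_2": 0.5},
                         save_as="score"),
            o.ActionStep(id="s3", component="balance", method="tare",
                         args={}, save_as="mark"),
        ),
    })
    plan = o.compile_workflow(w, abstraction)
    with pytest.raises(ModeError):
        o.run_adaptive(plan, o.Adaptive(
            space=[o.ParameterRange("v", 0.0, 1.0)],
            objectives=[o.ObjectiveSpec("mark", "minimize")],
            budget=2, seed=0), devices)


def test_failed_iterations_reported_to_optimizer_as_failure(abstraction,
                                                            sdl_platform):
    devices, _ = sdl_platform
    w = o.WorkflowScript(name="fragile", phases={
        "prep": (), "cleanup": (),
        "main": (
            o.ActionStep(id="s1", component="pump", method="dose",
                         args={"volume": o.DynamicRef("v")}),
            o.ActionStep(id="s2", component="sdl", method="analyze",
                         args={"param_1": o.DynamicRef("v"), "param_2": 0.5},
                         save_as="score"),
        ),
    })
    plan = o.compile_workflow(w, abstraction)
    adaptive = o.Adaptive(space=[o.ParameterRange("v", -1.0, 1.0)],
                          objectives=[o.ObjectiveSpec("score", "minimize")],
                          budget=10, seed=0, backend="random")
    opt = o.make_optimizer(adaptive.space, adaptive.objectives, 0, "random")
    records, _ = o.run_adaptive(plan, adaptive, devices, optimizer=opt)
    failed = [r for r in records if r.status == "failed"]
    assert failed  # negative volumes occur in this space and fail the dose step
    markers = [e for e in opt.journal if e.values is o.FAILURE]
    assert len(markers) == len(failed)  # never fabricated objective values
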