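"""Validation against the abstraction and compilation to phase procedures."""

import pytest

import orchestral as o
from orchestral.compiler import errors_of
from orchestral.errors import CompileRefusedError
from orchestral.workflow import Comparison


def run_main(w, abstraction, bindings, platform_factory=o.virtual.make_abstract_sdl):
    """Compile w and run only its main phase, returning the device transcript."""
    devices, log = platform_factory(0)
    plan = o.compile_workflow(w, abstraction)
    from orchestral.compiler import ExecutionContext
    plan.main_proc(ExecutionContext(devices), bindings)
    return log.transcript()


def test_consistent_pair_validates_clean(workflows, abstraction):
    for name in ("constant", "fixture"):
        assert errors_of(o.validate(workflows[name], abstraction)) == []


def test_typo_method_reported_with_step_id(workflows, abstraction):
    w = o.add_step(workflows["constant"], "main", 0, o.ActionStep(
        id="sx", component="sdl", method="analzye",
        args={"param_1": 1.0, "param_2": 2.0}))
    issues = o.validate(w, abstraction)
    assert any(i.code == "unknown-method" and i.step_id == "sx" for i in issues)


def test_unknown_component_and_argument(workflows, abstraction):
    w = o.add_step(workflows["constant"], "main", 0, o.ActionStep(
        id="", component="ghost", method="run"))
    assert any(i.code == "unknown-component" for i in o.validate(w, abstraction))
    w = o.add_step(workflows["constant"], "main", 0, o.ActionStep(
        id="", component="pump", method="dose", args={"pressure": 1.0}))
    assert any(i.code == "unknown-argument" for i in o.validate(w, abstraction))


def test_missing_required_argument(workflows, abstraction):
    w = o.add_step(workflows["constant"], "main", 0, o.ActionStep(
        id="", component="sdl", method="analyze", args={"param_1": 1.0}))
    assert any(i.code == "missing-required-argument"
               for i in o.validate(w, abstraction))


def test_literal_type_mismatch(workflows, abstraction):
    w = o.add_step(workflows["constant"], "main", 0, o.ActionStep(
        id="", component="pump", method="dose", args={"volume": "lots"}))
    assert any(i.code == "literal-type-mismatch" for i in o.validate(w, abstraction))


def test_dynamic_in_cleanup_detected_by_validator(abstraction):
    # construct directly (the editing API would already refuse this)
    w = o.WorkflowScript(name="bad", phases={
        "prep": (), "main": (),
        "cleanup": (o.ActionStep(id="s1", component="pump", method="dose",
                                 args={"volume": o.DynamicRef("v")}),),
    })
    issues = o.validate(w, abstraction)
    assert any(i.code == "dynamic-in-static-phase" for i in issues)


def test_undefined_variable_detected(workflows, abstraction):
    w = o.add_step(workflows["constant"], "main", 0, o.ActionStep(
        id="", component="pump", method="dose",
        args={"volume": o.VariableRef("never_saved")}))
    assert any(i.code == "undefined-variable" for i in o.validate(w, abstraction))


def test_ambiguous_dynamic_type(abstraction):
    class Typed:
        def a(self, x: float):
            pass

        def b(self, y: int):
            pass

    a = o.capture({"dev": Typed()})
    w = o.WorkflowScript(name="amb", phases={
        "prep": (), "cleanup": (),
        "main": (
            o.ActionStep(id="s1", component="dev", method="a",
                         args={"x": o.DynamicRef("q")}),
            o.ActionStep(id="s2", component="dev", method="b",
                         args={"y": o.DynamicRef("q")}),
        ),
    })
    assert any(i.code == "ambiguous-dynamic-type" for i in o.validate(w, a))


def test_duplicate_save_as_is_warning_not_error(workflows, abstraction):
    w = o.add_step(workflows["fixture"], "main", 2, o.ActionStep(
        id="", component="sdl", method="analyze",
        args={"param_1": 0.1, "param_2": 0.2}, save_as="score"))
    issues = o.validate(w, abstraction)
    assert any(i.code == "duplicate-save-as" and i.severity == "warning"
               for i in issues)
    assert errors_of(issues) == []


def test_compile_refused_on_validation_errors(workflows, abstraction):
    w = o.add_step(workflows["constant"], "main", 0, o.ActionStep(
        id="", component="ghost", method="run"))
    with pytest.raises(CompileRefusedError) as exc:
        o.compile_workflow(w, abstraction)
    assert any(i.code == "unknown-component" for i in exc.value.issues)


def test_every_validated_document_compiles(abstraction):
    for seed in range(60):
        w, _ = o.virtual.random_workflow(seed)
        assert errors_of(o.validate(w, abstraction)) == []
        o.compile_workflow(w, abstraction)  # total on validated inputs


def test_fixture_signature_and_empty_signature(workflows, abstraction):
    plan = o.compile_workflow(workflows["fixture"], abstraction)
    assert plan.dynamic_signature == [("param_1", "real"), ("param_2", "real")]
    constant = o.compile_workflow(workflows["constant"], abstraction)
    assert constant.dynamic_signature == []


def test_substitution_equivalence_on_fixture(workflows, abstraction):
    w = workflows["fixture"]
    bindings = {"param_1": 1.0, "param_2": 2.0}
    direct = run_main(w, abstraction, bindings)
    substituted = run_main(o.substitute(w, bindings), abstraction, {})
    assert direct == substituted


@pytest.mark.parametrize("seed", range(25))
def test_substitution_equivalence_randomized(abstraction, seed):
    w, bindings = o.virtual.random_workflow(seed)
    assert run_main(w, abstraction, bindings) == \
        run_main(o.substitute(w, bindings), abstraction, {})


def test_repeat_produces_n_body_transcripts(abstraction):
    body = (o.ActionStep(id="s2", component="pump", method="dose",
                         args={"volume": 0.5}),)
    w = o.WorkflowScript(name="rep", phases={
        "prep": (), "cleanup": (),
        "main": (o.ControlStep(id="s1", kind="repeat", count=3, body=body),),
    })
    transcript = run_main(w, abstraction, {})
    assert transcript == [("pump", "dose", (("volume", 0.5),))] * 3


@pytest.mark.parametrize("flag,expected", [(1, "run"), (0, "tare")])
def test_if_branches_on_condition(abstraction, flag, expected):
    w = o.WorkflowScript(name="cond", phases={
        "prep": (), "cleanup": (),
        "main": (
            o.ControlStep(id="s1", kind="define", name="flag", value=flag),
            o.ControlStep(
                id="s2", kind="if",
                condition=Comparison(o.VariableRef("flag"), "==", 1),
                body=(o.ActionStep(id="s3", component="sdl", method="run"),),
                else_body=(o.ActionStep(id="s4", component="balance",
                                        method="tare"),)),
        ),
    })
    transcript = run_main(w, abstraction, {})
    assert [m for _, m, _ in transcript] == [expected]


def test_while_respects_guard(abstraction):
    w = o.WorkflowScript(name="spin", phases={
        "prep": (), "cleanup": (),
        "main": (o.ControlStep(
            id="s1", kind="while",
            condition=Comparison(1, "==", 1), max_iterations=7,
            body=(o.ActionStep(id="s2", component="sdl", method="run"),)),),
    })
    assert len(run_main(w, abstraction, {})) == 7


def test_wait_emits_events_but_no_device_calls(abstraction):
    w = o.WorkflowScript(name="pause", phases={
        "prep": (), "cleanup": (),
        "main": (o.ControlStep(id="s1", kind="wait", duration_s=120.0),),
    })
    devices, log = o.virtual.make_abstract_sdl(0)
    plan = o.compile_workflow(w, abstraction)
    events = []
    from orchestral.compiler import ExecutionContext
    ctx = ExecutionContext(devices, emit=lambda c, **p: events.append((c, p)))
    plan.main_proc(ctx, {})  # virtual clock: returns instantly
    assert log.transcript() == []
    assert [c for c, _ in events] == ["step_start", "step_end"]
    assert events[0][1]["kind"] == "wait"


def test_saved_value_flows_to_later_step(abstraction):
    w = o.WorkflowScript(name="chain", phases={
        "prep": (), "cleanup": (),
        "main": (
            o.ActionStep(id="s1", component="sdl", method="analyze",
                         args={"param_1": 0.5, "param_2": 0.5}, save_as="score"),
            o.ActionStep(id="s2", component="pump", method="dose",
                         args={"volume": o.VariableRef("score")}),
        ),
    })
    transcript = run_main(w, abstraction, {})
    assert transcript[1] == ("pump", "dose", (("volume", 0.0),))  # analyze(0.5,0.5)=0


def test_export_source_is_cosmetic_but_faithful(workflows):
    src = o.export_source(workflows["fixture"])
    assert "def main(param_1, param_2):" in src
    assert "score = sdl.analyze(param_1=param_1, param_2=param_2)" in src
    assert "pump.dose(volume=1.0)" in src
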