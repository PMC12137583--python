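# Methods

This note documents the models and procedures implemented in `orchestral`,
the defaults that matter, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Platform abstraction by runtime introspection

The orchestrator's core model of a laboratory is a *platform abstraction*:
a mapping from instance names to the public callable surface of each
instrument object. Capture takes an explicit `name -> object` mapping
(typically the control script's `globals()`) rather than inspecting the
caller's stack — explicit data flow is more robust and trivially testable;
the `launch()` convenience forwards a namespace in one call.

An object is treated as an instrument when its type is user-defined: not a
module, function, class, or primitive/collection literal, and its class is
defined outside the standard library (checked against
`sys.stdlib_module_names`). Methods are kept when public (no leading
underscore), non-property, and callable; static and class methods qualify;
inherited methods are included *except* anything defined only on `object`.
Inclusion of inherited user-defined methods is deliberate: instrument drivers
commonly share base classes, and their inherited surface is part of the
device's real capability.

Parameter annotations map to seven type tags: `integer`, `real`, `boolean`,
`text`, `collection`, `custom`, `unspecified`. `bool` is tested before `int`
(it is a subclass); string annotations (postponed evaluation) are resolved by
name. Unannotated parameters are `unspecified` and rendered as free text with
no validation — the deliberate fallback for the many lab APIs without type
hints. A parameter is `required` exactly when it has no default.

Snapshots are plain JSON documents (sorted keys), not binary pickles:
diffable, versionable, and loadable with no live hardware for offline design.
Corrupt or truncated files raise a dedicated snapshot-format error.

## Forms

Each method signature becomes a form: `integer -> integer_input`,
`real -> real_input`, `boolean -> checkbox` (all validated);
`text -> text_input`; `collection`/`custom`/`unspecified -> raw_text`,
passed to the method verbatim and never evaluated — evaluating arbitrary
submitted text against laboratory hardware would be a safety hazard, so
unvalidated values surface any mismatch at call time instead. Checkbox
submissions accept `true/false`, `on/off`, `1/0` case-insensitively because
client conventions vary. Integer fields reject fractional input rather than
truncating. In the design context every field additionally accepts `#name`,
producing a dynamic-parameter reference; a leading `\#` escapes a literal
`#`. A `save_as` field is appended to design forms for capturing return
values. Control-context forms never produce dynamic references.

## Workflow documents

A workflow has exactly three phases. `prep` and `cleanup` execute once per
run with constant inputs; `main` executes once per iteration and is the only
phase that may contain `#name` dynamic parameters — this is enforced at the
schema level, by the editing API, and again by the validator. Step arguments
are literals, dynamic references, or variable references to a value saved
earlier in the same phase (via `save_as` or a `define` step).

Flow control is intentionally minimal: `if`/`while` over a single comparison
`<operand> <op> <operand>` (operands are literals or variables; operators
`== != < <= > >=`), `repeat{n}`, `wait{seconds}`, and `define`. A general
expression grammar was deliberately not built — a comparison language is
auditable and sufficient for gating and looping. `while` carries an implicit
iteration guard (default 1000, configurable per step) so an unattended run
can never spin forever.

Serialization is canonical JSON (sorted keys, compact separators, version
field `schema: 1`); equal documents are byte-identical, so storage and
transport equality reduce to string comparison. The parser reports *all*
schema violations at once with slash-separated positions. Step ids are
generated monotonically (`s1`, `s2`, ...) and derived ids never collide with
existing ones.

Duplicate `save_as` names shadow within a run (single mutable binding) and
raise a validator warning. Saved variables reset at each iteration start: an
iteration never observes state saved by a previous one, which keeps manual
rows and optimizer suggestions independent experiments.

## Validation and compilation

The validator checks, per step: component exists, method exists, argument
names match the signature, required arguments present, literal types match
validated tags, variables defined earlier in the phase, dynamic references
confined to `main`, loop bounds sane, and that one dynamic name never feeds
parameters of conflicting type tags (`ambiguous-dynamic-type`). Errors and
warnings carry machine codes (catalogued in `compiler.py`).

Compilation targets closures over a device registry, not generated source:
a validated document always compiles, and execution never `eval`s text.
`export_source` renders equivalent readable Python for users who want to take
a design back into their own scripts — cosmetic only. The central compiled
guarantee is *substitution equivalence*: running the plan with bindings `B`
yields the identical device-call transcript as literal-substituting `B` into
the document and compiling that. The suite checks this on 200+ seeded random
workflows (generator in `orchestral.virtual.random_workflow`).

## Execution

Every run is strictly serial: prep once, `main` once per iteration, cleanup
exactly once at run end — *including* after failure or abort, because
hardware must be reset; this cleanup-always rule is a deliberate policy
choice, documented here prominently. Failure policy between iterations is
configurable: `abort_run` (default for repeat/manual) or `skip_to_next`
(default for adaptive runs, where one failed experiment should not end a
campaign). Step errors emit `step_error` events and mark the iteration
`failed`; a registry missing a component fails before anything executes.

Status events (`run_start`, `phase_start`, `step_start`, `step_end`,
`step_error`, `iteration_end`, `run_end`) carry strictly increasing sequence
numbers; every `step_start` is closed by `step_end` or `step_error`. `wait`
steps emit their events through an injectable clock (the default test clock
returns instantly, so suites run in milliseconds).

CSV input is RFC 4180 with a mandatory header equal (as a set) to the
dynamic-parameter names; cells are coerced per type tag with row/column
error positions. A CSV with zero data rows runs prep and cleanup only —
least-surprise over erroring.

Mode gating: no dynamic parameters → `{repeat}`; dynamic parameters →
`{manual, csv}`; plus `adaptive` when at least one saved output is numeric
(`integer`/`real` return tag) — only numeric outputs may be optimization
objectives; others must have goal `none`.

## Closed-loop optimization

Adaptive execution drives an *ask–tell* optimizer: per iteration, `ask()`
returns a binding inside the declared space, the main phase runs, the
objective is read from the saved outputs, and `tell()` reports it. Failed
iterations are told as an explicit failure marker — objective values are
never fabricated. The best-so-far trace is monotone non-worsening by
construction. The interface accepts several objective specs, but the shipped
baselines optimize the single objective whose goal is not `none` (others are
recorded only).

Two deterministic seeded baselines ship, so closed-loop behavior is testable
without any external optimization service:

- **random** — uniform sampling of the space;
- **coordinate** (default) — random start, then coordinate search: probe the
  incumbent ± the current step along each dimension in turn (step starts at
  a quarter of each range), keep improvements, and halve all steps after a
  full sweep without improvement. Categorical dimensions resample uniformly
  on their turn.

On the deterministic color platform (quadratic objective, default target
`(0.3, 0.7)`, noise 0) the coordinate baseline at budget 40 and seed 1
reaches the brute-force 101×101-grid-verified optimum within 5×10⁻² (the
acceptance script measures the actual gap, ~2×10⁻⁴). External Bayesian
backends (e.g. an Ax service) plug into the same registry and contract; they
are optional and never a dependency. `tell()` calls are journaled as JSON
lines so a crashed campaign can resume an optimizer deterministically by
replay.

## Virtual platforms

The abstract SDL trio: `balance.weigh() -> real` (seeded pseudo-random
readings), `balance.tare()`, `pump.dose(volume: real = 1.0)` (rejects
negative volumes — the designed failure path), `sdl.run()`, and
`sdl.analyze(param_1: real, param_2: real) -> real`, the fixed quadratic
`100(p₁−0.5)² + 100(p₂−0.5)²`. The color platform doses red/blue fractions
and `measure()` returns `(r−r*)² + (b−b*)² + N(0, σ)` over the fractions
dosed since the previous measurement (each measurement consumes the vial, so
closed-loop iterations are independent); σ defaults to 0. The quadratic
difference score stands in for a computer-vision color comparison: what the
orchestrator exercises is the optimization loop's contract, not image
processing.

These emulators reproduce call sequencing, signatures, failure paths and a
deterministic objective; they do **not** simulate timing, kinematics,
measurement drift, or chemistry. Passing tests therefore demonstrate the
orchestration semantics — capture, compilation, phase order, data flow,
convergence machinery — not the behavior of any physical instrument.

## Web service and storage

The HTTP layer is a plain WSGI application; every route is a thin adapter
over the library API, so all behavior is reachable and tested in-process
without sockets. Workflow storage is an embedded SQLite file (schema
versioned with a migration stamp); names are the human key and a `protected`
flag rejects overwrite/delete. Real-time status uses an in-memory replay
ring: `GET /api/status?since=k` returns events after sequence `k`, giving
reconnecting clients exactly-once resumption; a push transport can layer on
top without changing the contract. Mutation endpoints are idempotent under
retry with an `X-Request-Id` header. Runs started over HTTP execute
synchronously in the request — consistent with the engine's strictly serial
execution model. No authentication is enabled by default (trusted-LAN
deployment) and no chemistry-level safety checking is performed: exposing
only safe operations is the integrator's responsibility.

Offline mode serves design, validation, compilation and storage from a
snapshot alone; execution and direct-control endpoints return a 503 offline
error, and the suite proves no live instrument is ever touched by asserting
the virtual call log stays empty.

## Text-to-code

The prompt bundle concatenates a fixed instruction preamble, the serialized
abstraction (so the model is grounded in the actual modules/methods), one
valid example document, and the user's request — deterministic for fixed
inputs. The model client is injected (`send(prompt) -> text`); tests use
canned transcripts. On the way back, the first parseable JSON (fenced blocks
first, then a balanced-brace scan; multiple candidates raise a warning and
the first wins) goes through `from_document` and then the *same* `validate()`
as human-authored workflows — there is exactly one validation path, and
`parse_and_validate` is total: any string yields a script or diagnostics,
never an exception.

## Problem sizes and tolerances

The suite and acceptance script use: 5 iterations for phase-semantics
counts; 200 random workflows for substitution equivalence and 100 for
round-trips (seeded from the acceptance `--seed`); optimizer budget 40 over
`[0,1]²` with convergence tolerance 0.05 against the grid oracle; 1000
Monte-Carlo draws for the noise-model check (3× standard error band). These
sizes give sub-second module tests and a seconds-scale acceptance run while
leaving each property statistically meaningful.

## Known limitations

- Single-threaded: no scheduling, parallel branches, or resource locking.
- One optimization objective is acted on by shipped baselines.
- The comparison language has no arithmetic; dynamic defaults are forbidden.
- Nested sub-devices (an attribute of a captured instrument) are not
  recursed into; only top-level bindings become modules.
- The HTML surface is minimal; the JSON API is the contract.
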