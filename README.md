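# orchestral

Interoperable orchestration for self-driving laboratories (SDLs).

Research automation platforms in chemistry and drug discovery are rarely
standardized: each lab's robots, pumps, balances and analytical instruments
are driven by a bespoke Python control script. `orchestral` turns such a
script into a full orchestration layer without modifying it. It:

- **introspects** the script's instrument instances into a serializable
  *platform abstraction* — every public, non-property method with its
  parameter names, type tags, defaults and docstrings;
- **generates validating input forms** from those signatures for direct
  instrument control and for low-code workflow design;
- represents experiments as a **three-phase workflow document**
  (`prep` runs once, `main` repeats per iteration, `cleanup` runs once) with
  flow control (`if`/`while`/`repeat`/`wait`/variables) and *dynamic
  parameters* written `#name`, bound per iteration at execution time;
- **validates and compiles** documents against the abstraction into
  executable phase procedures;
- **executes** plans under repeat, human-configured (rows or CSV), or
  **closed-loop adaptive** iteration, where a seeded ask–tell optimizer
  proposes each iteration's parameters from the previous measured objective;
- serves everything over an HTTP + JSON API with a replayable status-event
  stream, persists workflows in an embedded store, and optionally translates
  natural-language task descriptions into workflow documents through an
  injected language-model client — post-validated by the same validator as
  human-authored designs.

Bundled deterministic **virtual instruments** (a balance/pump/SDL trio and a
color-matching platform) make the whole stack testable with no hardware.

## Worked example

```python
import orchestral as o

# a control script's namespace: three instrument instances + clutter
devices, log = o.virtual.make_abstract_sdl(seed=0)
abstraction = o.capture({**devices, "n": 5, "s": "x"})
print(sorted(abstraction.modules))
# ['balance', 'pump', 'sdl']          <- primitives skipped automatically

# the shipped design: sdl.analyze(#param_1, #param_2) saved as `score`
wf = o.virtual.fixture_workflows()["fixture"]
plan = o.compile_workflow(wf, abstraction)
print(plan.dynamic_signature)        # [('param_1', 'real'), ('param_2', 'real')]
print(o.available_modes(plan))       # {'manual', 'csv', 'adaptive'}

records = o.run(plan, o.Manual([{"param_1": 1.0, "param_2": 2.0}]), devices)
print(records[0].outputs)            # {'score': 250.0}
```

`analyze` is the virtual platform's fixed quadratic
`100·(p₁−0.5)² + 100·(p₂−0.5)²`, so `analyze(1, 2) = 25 + 225 = 250`.

Closed-loop optimization on the color-matching platform (objective
`(r−r*)² + (b−b*)²`, hidden target `(0.3, 0.7)`):

```python
devices, _ = o.virtual.make_color_platform(target=(0.3, 0.7))
plan = o.compile_workflow(o.virtual.fixture_workflows()["colorloop"],
                          o.capture(devices))
adaptive = o.Adaptive(
    space=[o.ParameterRange("red", 0.0, 1.0), o.ParameterRange("blue", 0.0, 1.0)],
    objectives=[o.ObjectiveSpec("score", "minimize")],
    budget=40, seed=1, backend="coordinate")
records, trace = o.run_adaptive(plan, adaptive, devices)
print(trace[-1])                     # 0.00016581890797350967
```

After 40 iterations the best difference score is ≈ 1.7 × 10⁻⁴ — the mixing
ratios found are within ~1 % of the hidden target on each channel.

Serving a control script takes one call (or `orchestral serve --script ...`):

```python
handle = o.launch(globals())         # captures instruments, serves the API
handle.stop()
```

Offline design works from a snapshot alone: `o.save_snapshot(abstraction,
path)`, then `launch(None, o.ServiceConfig(offline=True, snapshot_path=path))`
— design/storage endpoints function normally and execution endpoints refuse.

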