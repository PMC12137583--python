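"""Deterministic, call-logging virtual instruments.

Two platforms ship: an abstract self-driving-lab trio (balance / pump / sdl)
exercising introspection, forms, workflow design and execution; and a
color-matching mixer for closed-loop optimization, whose "difference score"
is the closed-form quadratic distance of the dosed red/blue fractions from a
hidden target.  Every method call appends one entry to a shared
:class:`CallLog`, which is the transcript oracle the rest of the test suite
compares against.
"""

from __future__ import annotations

import json
import random
import time as _time
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .refs import DynamicRef
from .workflow import (
    ActionStep,
    Comparison,
    ControlStep,
    WorkflowScript,
    dynamic_parameters,
    from_document,
)


@dataclass(frozen=True)
class CallEntry:
    component: str
    method: str
    args: dict
    result: object
    time: float


@dataclass
class CallLog:
    """Append-only transcript of every virtual-instrument call."""

    entries: list = field(default_factory=list)

    def record(self, component, method, args, result):
        self.entries.append(CallEntry(component, method, dict(args), result, _time.time()))

    def transcript(self) -> list[tuple]:
        """(component, method, args) triples — the comparable part of the log."""
        return [(e.component, e.method, tuple(sorted(e.args.items())))
                for e in self.entries]

    def to_json_lines(self) -> str:
        return "\n".join(
            json.dumps({"component": e.component, "method": e.method,
                        "args": e.args, "result": repr(e.result), "time": e.time})
            for e in self.entries
        )

    def clear(self):
        self.entries.clear()


class Balance:
    """A virtual analytical balance with seeded pseudo-random readings."""

    def __init__(self, log: CallLog, seed: int = 0):
        self._log = log
        self._rng = random.Random(seed)

    def weigh(self) -> float:
        """Return the current mass reading in grams."""
        reading = round(self._rng.uniform(0.0, 10.0), 4)
        self._log.record("balance", "weigh", {}, reading)
        return reading

    def tare(self):
        """Zero the balance."""
        self._log.record("balance", "tare", {}, None)


class Pump:
    """A virtual syringe pump."""

    def __init__(self, log: CallLog):
        self._log = log
        self._dispensed = 0.0

    def dose(self, volume: float = 1.0):
        """Dispense a volume in mL; negative volumes are rejected."""
        if volume < 0:
            raise ValueError(f"invalid volume: {volume} mL (must be nonnegative)")
        self._dispensed += volume
        self._log.record("pump", "dose", {"volume": volume}, None)

    @property
    def total_dispensed(self) -> float:
        return self._dispensed


class AbstractSDL:
    """A virtual platform head: a run action and a two-parameter analysis.

    ``analyze`` is the fixed quadratic 100·(p1−0.5)² + 100·(p2−0.5)², so
    adaptive-mode tests have a known optimum at (0.5, 0.5) with value 0.
    """

    def __init__(self, log: CallLog):
        self._log = log

    def run(self):
        """Execute the platform's hard-coded routine."""
        self._log.record("sdl", "run", {}, None)

    def analyze(self, param_1: float, param_2: float) -> float:
        """Score a condition; lower is better, minimum 0 at (0.5, 0.5)."""
        score = 100.0 * (param_1 - 0.5) ** 2 + 100.0 * (param_2 - 0.5) ** 2
        self._log.record("sdl", "analyze",
                         {"param_1": param_1, "param_2": param_2}, score)
        return score


def make_abstract_sdl(seed: int = 0):
    """Return ({balance, pump, sdl} bindings, shared CallLog)."""
    log = CallLog()
    bindings = {
        "balance": Balance(log, seed=seed),
        "pump": Pump(log),
        "sdl": AbstractSDL(log),
    }
    return bindings, log


class ColorMixer:
    """A virtual color-matching platform.

    ``measure()`` returns the squared distance of the red/blue fractions dosed
    since the previous measurement from a hidden target (r*, b*), plus
    optional Gaussian noise — each measurement consumes the current vial, so
    every iteration of a closed loop scores its own doses.  Deterministic when
    ``noise_sd`` is 0.
    """

    def __init__(self, log: CallLog, target=(0.3, 0.7), noise_sd: float = 0.0,
                 seed: int = 0):
        if not (0.0 <= target[0] <= 1.0 and 0.0 <= target[1] <= 1.0):
            raise ConfigurationError(f"target components must be in [0, 1]: {target}")
        self._log = log
        self._target = (float(target[0]), float(target[1]))
        self._noise_sd = float(noise_sd)
        self._rng = random.Random(seed)
        self._red = 0.0
        self._blue = 0.0

    def dose_red(self, v: float):
        """Add a red fraction to the current vial."""
        self._red += v
        self._log.record("mixer", "dose_red", {"v": v}, None)

    def dose_blue(self, v: float):
        """Add a blue fraction to the current vial."""
        self._blue += v
        self._log.record("mixer", "dose_blue", {"v": v}, None)

    def measure(self) -> float:
        """Difference score vs the target color; 0 at a perfect match."""
        r_star, b_star = self._target
        score = (self._red - r_star) ** 2 + (self._blue - b_star) ** 2
        if self._noise_sd > 0:
            score += self._rng.gauss(0.0, self._noise_sd)
        self._log.record("mixer", "measure", {}, score)
        self._red = 0.0
        self._blue = 0.0
        return score


def make_color_platform(target=(0.3, 0.7), noise_sd: float = 0.0, seed: int = 0):
    """Return ({mixer} bindings, CallLog) for the color-matching fixture."""
    log = CallLog()
    return {"mixer": ColorMixer(log, target=target, noise_sd=noise_sd, seed=seed)}, log


# ---------------------------------------------------------------------------
# fixture workflows (shipped as package data, parsed through the public schema)

try:  # Python >= 3.9
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    _resources = None

_FIXTURE_FILES = {
    "constant": "constant.workflow.json",
    "fixture": "fixture.workflow.json",
    "colorloop": "colorloop.workflow.json",
}


def random_workflow(seed: int):
    """Generate a seeded random workflow over the abstract SDL, with bindings.

    Used to exercise the substitution-equivalence property at scale: the
    returned workflow mixes constant and dynamic arguments, saved outputs and
    flow control; the returned bindings cover exactly its dynamic parameters.
    Always validates against the abstract-SDL abstraction.
    """
    rng = random.Random(seed)
    counter = [0]

    def sid():
        counter[0] += 1
        return f"s{counter[0]}"

    dyn_names = ["p_a", "p_b", "p_c"]

    def real_arg(allow_dynamic):
        if allow_dynamic and rng.random() < 0.5:
            return DynamicRef(rng.choice(dyn_names))
        return round(rng.uniform(0.0, 2.0), 3)

    def action(allow_dynamic):
        kind = rng.randrange(4)
        if kind == 0:
            return ActionStep(id=sid(), component="pump", method="dose",
                              args={"volume": real_arg(allow_dynamic)})
        if kind == 1:
            save = f"v{counter[0]}" if rng.random() < 0.4 else None
            return ActionStep(id=sid(), component="sdl", method="analyze",
                              args={"param_1": real_arg(allow_dynamic),
                                    "param_2": real_arg(allow_dynamic)},
                              save_as=save)
        if kind == 2:
            return ActionStep(id=sid(), component="sdl", method="run", args={})
        return ActionStep(id=sid(), component="balance", method="tare", args={})

    def steps(n, allow_dynamic, allow_control=True):
        out = []
        for _ in range(n):
            r = rng.random()
            if allow_control and r < 0.15:
                out.append(ControlStep(
                    id=sid(), kind="repeat", count=rng.randint(1, 3),
                    body=tuple(steps(rng.randint(1, 2), allow_dynamic, False))))
            elif allow_control and r < 0.25:
                cond = Comparison(rng.randint(0, 1), "==", rng.randint(0, 1))
                out.append(ControlStep(
                    id=sid(), kind="if", condition=cond,
                    body=tuple(steps(1, allow_dynamic, False)),
                    else_body=tuple(steps(1, allow_dynamic, False))
                    if rng.random() < 0.5 else None))
            elif allow_control and r < 0.3:
                out.append(ControlStep(id=sid(), kind="wait",
                                       duration_s=round(rng.uniform(0, 0.2), 3)))
            else:
                out.append(action(allow_dynamic))
        return out

    w = WorkflowScript(name=f"random-{seed}", phases={
        "prep": tuple(steps(rng.randint(0, 2), False)),
        "main": tuple(steps(rng.randint(1, 5), True)),
        "cleanup": tuple(steps(rng.randint(0, 2), False)),
    })
    bindings = {name: round(rng.uniform(0.0, 2.0), 3)
                for name in dynamic_parameters(w)}
    return w, bindings


def fixture_workflows() -> dict[str, WorkflowScript]:
    """The shipped example workflows, parsed through :func:`from_document`.

    - ``constant``: no dynamic parameters (repeat mode only);
    - ``fixture``: ``sdl.analyze(#param_1, #param_2)`` saved as ``score``;
    - ``colorloop``: dose red/blue by ``#red``/``#blue`` then measure,
      saved as ``score`` (the closed-loop demo).
    """
    out = {}
    for name, fname in _FIXTURE_FILES.items():
        text = (_resources.files("orchestral") / "fixtures" / fname).read_text("utf-8")
        out[name] = from_document(text)
    return out
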