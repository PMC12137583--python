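"""Ask–tell optimizer contract and deterministic baseline backends.

Closed-loop runs drive an optimizer through two calls: ``ask()`` returns the
next parameter binding (always inside the declared space), ``tell(bindings,
values)`` reports the measured objective (or the ``FAILURE`` marker).  Calls
must alternate.  Two seeded baselines ship so the loop is fully testable with
no external optimization service:

- ``random`` — uniform sampling of the space;
- ``coordinate`` — random start plus shrinking coordinate search: sweep each
  dimension with ± current step, keep improvements, halve the step after a
  sweep with no improvement.

External Bayesian backends (e.g. an Ax/BoTorch service) attach through the
same registry and contract; they are an optional extra, never a dependency.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass


class _Failure:
    def __repr__(self):
        return "FAILURE"


FAILURE = _Failure()  # sentinel told for a failed experiment


from .errors import CapabilityError, ConfigurationError, ProtocolError


def _single_goal(objectives):
    active = [o for o in objectives if getattr(o, "goal", "none") != "none"]
    if len(active) != 1:
        raise CapabilityError(
            f"shipped baselines optimize exactly one objective, got {len(active)}")
    return active[0]


@dataclass
class JournalEntry:
    bindings: dict
    values: object  # mapping or "failure"


class BaseOptimizer:
    """Common contract plumbing: alternation, range checks, journaling."""

    def __init__(self, space, objectives, seed):
        if not space:
            raise ConfigurationError("parameter space must be nonempty")
        self.space = list(space)
        self.objective = _single_goal(objectives)
        self.sign = 1.0 if self.objective.goal == "minimize" else -1.0
        self.seed = int(seed)
        self.rng = random.Random(self.seed)
        self.journal: list[JournalEntry] = []
        self._pending = None  # bindings awaiting a tell
        self.best_bindings = None
        self.best_value = None

    # -- contract -----------------------------------------------------------

    def ask(self) -> dict:
        if self._pending is not None:
            raise ProtocolError("ask() called twice without an intervening tell()")
        bindings = self._suggest()
        for p in self.space:
            v = bindings[p.name]
            if p.is_continuous:
                assert p.lower <= v <= p.upper, f"{p.name} out of range"
            else:
                assert v in p.choices, f"{p.name} not a declared choice"
        self._pending = bindings
        return dict(bindings)

    def tell(self, bindings: dict, values) -> None:
        if self._pending is None:
            raise ProtocolError("tell() called without a preceding ask()")
        self._pending = None
        self.journal.append(JournalEntry(dict(bindings), values))
        if values is FAILURE:
            self._observe(bindings, None)
            return
        v = float(values[self.objective.output_name])
        if self.best_value is None or self.sign * v < self.sign * self.best_value:
            self.best_value = v
            self.best_bindings = dict(bindings)
        self._observe(bindings, v)

    # -- journal persistence -----------------------------------------------

    def dump_journal(self) -> str:
        """One JSON line per tell(); enables deterministic resume after a crash."""
        lines = []
        for e in self.journal:
            lines.append(json.dumps({
                "bindings": e.bindings,
                "values": "failure" if e.values is FAILURE else e.values,
            }, sort_keys=True))
        return "\n".join(lines)

    def replay(self, journal_text: str) -> None:
        for line in journal_text.splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            self.ask()  # advance internal state deterministically
            values = FAILURE if obj["values"] == "failure" else obj["values"]
            self.tell(obj["bindings"], values)

    # -- backend hooks ------------------------------------------------------

    def _suggest(self) -> dict:
        raise NotImplementedError

    def _observe(self, bindings, value):
        pass

    def _sample(self) -> dict:
        out = {}
        for p in self.space:
            if p.is_continuous:
                out[p.name] = self.rng.uniform(p.lower, p.upper)
            else:
                out[p.name] = self.rng.choice(list(p.choices))
        return out


class RandomSearchOptimizer(BaseOptimizer):
    """Seeded uniform sampling of the space; ignores observations."""

    def _suggest(self):
        return self._sample()


class CoordinateSearchOptimizer(BaseOptimizer):
    """Seeded random start + shrinking coordinate search.

    Proposes the incumbent perturbed by ± the current step along one
    dimension; an improvement moves the incumbent; a full sweep without
    improvement halves the step.  Categorical dimensions are resampled
    uniformly on their turn.
    """

    def __init__(self, space, objectives, seed):
        super().__init__(space, objectives, seed)
        self.center = None
        self.center_value = None
        self.steps = {
            p.name: (p.upper - p.lower) / 4.0 if p.is_continuous else None
            for p in self.space
        }
        self._dims = [p.name for p in self.space]
        self._dim_i = 0
        self._dir = +1
        self._improved_this_sweep = False
        self._last_proposal = None

    def _clip(self, p, v):
        return min(max(v, p.lower), p.upper)

    def _suggest(self):
        if self.center is None:
            self._last_proposal = self._sample()
            return self._last_proposal
        prop = dict(self.center)
        p = self.space[self._dim_i]
        if p.is_continuous:
            prop[p.name] = self._clip(p, self.center[p.name] + self._dir * self.steps[p.name])
        else:
            prop[p.name] = self.rng.choice(list(p.choices))
        self._last_proposal = prop
        return prop

    def _observe(self, bindings, value):
        if self.center is None:
            if value is not None:
                self.center = dict(self._last_proposal)
                self.center_value = value
            return
        improved = value is not None and self.sign * value < self.sign * self.center_value
        if improved:
            self.center = dict(self._last_proposal)
            self.center_value = value
            self._improved_this_sweep = True
            return  # keep probing the same direction
        if self._dir == +1:
            self._dir = -1
            return
        self._dir = +1
        self._dim_i += 1
        if self._dim_i >= len(self._dims):
            self._dim_i = 0
            if not self._improved_this_sweep:
                for p in self.space:
                    if p.is_continuous:
                        self.steps[p.name] /= 2.0
            self._improved_this_sweep = False


BACKENDS = {
    "random": RandomSearchOptimizer,
    "coordinate": CoordinateSearchOptimizer,
}


def make_optimizer(space, objectives, seed, backend: str = "coordinate"):
    """Construct a conforming optimizer from the backend registry."""
    try:
        cls = BACKENDS[backend]
    except KeyError:
        raise ConfigurationError(
            f"unknown optimizer backend {backend!r}; "
            f"available: {sorted(BACKENDS)}") from None
    return cls(space, objectives, seed)
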