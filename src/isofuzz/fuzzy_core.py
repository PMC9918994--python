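"""Single-module Mamdani fuzzy inference over trapezoidal membership functions.

This module implements the generic machinery used by every tier of the
hierarchical dynamometry model: trapezoidal membership evaluation,
fuzzification of a crisp input against a linguistic variable, conjunctive
(min) rule firing, clipped-max consequent aggregation into an explicit
piecewise-linear function, and exact centre-of-gravity (COG) defuzzification.

The operator triple is the standard Mamdani choice: minimum as the AND
t-norm, truncation (min) as the implication, pointwise maximum as the
aggregation operator.  Defuzzification is computed analytically by
decomposing the aggregated piecewise-linear membership function into linear
segments and integrating each segment in closed form, so boundary scores of
exactly 0.0 and exactly 1.0 are attainable when the output variable's
extreme sets are mirrored beyond the nominal domain.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "TrapezoidalSet",
    "LinguisticVariable",
    "FuzzyRule",
    "FuzzyModuleSpec",
    "AggregatedMembership",
    "FuzzyInputError",
    "SpecificationError",
    "ZeroMassError",
    "ClampWarning",
    "membership",
    "fuzzify",
    "fire_rules",
    "aggregate",
    "defuzzify_cog",
    "evaluate_module",
    "module_to_dict",
    "module_from_dict",
    "save_module",
    "load_module",
]


class FuzzyInputError(ValueError):
    """A crisp input is missing, NaN or otherwise unusable."""


class SpecificationError(ValueError):
    """A model specification is internally inconsistent."""


class ZeroMassError(ArithmeticError):
    """Aggregated membership has zero area; defuzzification is undefined.

    With full Cartesian rule bases and covering input partitions this cannot
    happen for in-domain inputs, so it signals a misconfigured model rather
    than bad data.
    """


class ClampWarning(UserWarning):
    """An input fell outside its variable domain and was clamped."""


@dataclass(frozen=True)
class TrapezoidalSet:
    """Trapezoidal fuzzy set ``(l, k1, k2, r)``.

    Membership is 0 outside the support ``[l, r]``, 1 on the kernel
    ``[k1, k2]`` and linear on the flanks.  A degenerate flank (``l == k1``
    or ``k2 == r``) is resolved by the kernel clause, so e.g. the set
    ``(0, 0, 0, 45)`` has membership 1 at ``x = 0``.
    """

    label: str
    l: float
    k1: float
    k2: float
    r: float

    def __post_init__(self) -> None:
        for name in ("l", "k1", "k2", "r"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.l <= self.k1 <= self.k2 <= self.r):
            raise SpecificationError(
                f"set {self.label!r}: require l <= k1 <= k2 <= r, "
                f"got ({self.l}, {self.k1}, {self.k2}, {self.r})"
            )

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.l, self.k1, self.k2, self.r)

    def membership(self, x: float) -> float:
        return membership(self, x)

    def centroid(self) -> float:
        """Centroid of the full (unclipped) trapezoid."""
        return defuzzify_cog(AggregatedMembership.from_clipped(self, 1.0))


def membership(s: TrapezoidalSet, x: float) -> float:
    """Degree of membership of ``x`` in trapezoidal set ``s``, in [0, 1]."""
    if not math.isfinite(x):
        raise FuzzyInputError(f"non-finite input {x!r} for set {s.label!r}")
    # kernel clause first so degenerate flanks (l == k1, k2 == r) give 1
    if s.k1 <= x <= s.k2:
        return 1.0
    if x <= s.l or x >= s.r:
        return 0.0
    if x < s.k1:
        return (x - s.l) / (s.k1 - s.l)
    return (s.r - x) / (s.r - s.k2)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named crisp range with an ordered family of labeled trapezoidal sets.

    ``domain_min``/``domain_max`` give the nominal crisp range; output
    variables may own sets whose supports extend beyond it (mirrored
    boundary sets), which is what lets the centroid reach the domain ends.
    """

    name: str
    units: str
    domain_min: float
    domain_max: float
    sets: tuple[TrapezoidalSet, ...]

    def __post_init__(self) -> None:
        if self.domain_min >= self.domain_max:
            raise SpecificationError(f"variable {self.name!r}: empty domain")
        labels = [s.label for s in self.sets]
        if len(labels) != len(set(labels)):
            raise SpecificationError(f"variable {self.name!r}: duplicate set labels")
        if not self.sets:
            raise SpecificationError(f"variable {self.name!r}: no sets")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sets)

    def get(self, label: str) -> TrapezoidalSet:
        for s in self.sets:
            if s.label == label:
                return s
        raise SpecificationError(f"variable {self.name!r} has no set {label!r}")

    def fuzzify(self, x: float) -> dict[str, float]:
        return fuzzify(self, x)


def fuzzify(variable: LinguisticVariable, x: float) -> dict[str, float]:
    """Map a crisp value to one membership degree per labeled set.

    Out-of-domain values are clamped to ``[domain_min, domain_max]`` with a
    :class:`ClampWarning` (dynamometer exports can slightly exceed nominal
    ranges).  NaN or infinite input raises :class:`FuzzyInputError` — missing
    data is never imputed.
    """
    if x is None or not math.isfinite(x):
        raise FuzzyInputError(f"variable {variable.name!r}: missing or non-finite value {x!r}")
    if x < variable.domain_min or x > variable.domain_max:
        clamped = min(max(x, variable.domain_min), variable.domain_max)
        warnings.warn(
            f"{variable.name}: value {x:g} outside domain "
            f"[{variable.domain_min:g}, {variable.domain_max:g}]; clamped to {clamped:g}",
            ClampWarning,
            stacklevel=2,
        )
        x = clamped
    return {s.label: membership(s, x) for s in variable.sets}


@dataclass(frozen=True)
class FuzzyRule:
    """Conjunctive rule: AND of (variable IS label) antecedents → one consequent."""

    antecedent: Mapping[str, str]
    consequent: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", dict(self.antecedent))

    def key(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.antecedent.items()))


@dataclass(frozen=True)
class FuzzyModuleSpec:
    """One inference unit: input variables, output variable, rule base.

    The rule base must be the full Cartesian product of the antecedent
    labels actually used per input (so every in-domain input fires at least
    one rule) with no duplicated antecedent combination.
    """

    name: str
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]

    def __post_init__(self) -> None:
        input_names = {v.name for v in self.inputs}
        if len(input_names) != len(self.inputs):
            raise SpecificationError(f"module {self.name!r}: duplicate input names")
        out_labels = set(self.output.labels)
        labels_used: dict[str, set[str]] = {n: set() for n in input_names}
        seen: set[tuple[tuple[str, str], ...]] = set()
        for rule in self.rules:
            if set(rule.antecedent) != input_names:
                raise SpecificationError(
                    f"module {self.name!r}: rule antecedent {sorted(rule.antecedent)} "
                    f"does not cover inputs {sorted(input_names)}"
                )
            for var_name, label in rule.antecedent.items():
                variable = self.input(var_name)
                if label not in variable.labels:
                    raise SpecificationError(
                        f"module {self.name!r}: unknown label {label!r} "
                        f"for input {var_name!r}"
                    )
                labels_used[var_name].add(label)
            if rule.consequent not in out_labels:
                raise SpecificationError(
                    f"module {self.name!r}: unknown consequent {rule.consequent!r}"
                )
            k = rule.key()
            if k in seen:
                raise SpecificationError(
                    f"module {self.name!r}: duplicate antecedent combination {k}"
                )
            seen.add(k)
        for v in self.inputs:
            unused = set(v.labels) - labels_used[v.name]
            if unused:
                raise SpecificationError(
                    f"module {self.name!r}: labels {sorted(unused)} of input "
                    f"{v.name!r} appear in no rule"
                )
        expected = math.prod(len(v.labels) for v in self.inputs)
        if len(self.rules) != expected:
            raise SpecificationError(
                f"module {self.name!r}: {len(self.rules)} rules, expected full "
                f"Cartesian product of {expected}"
            )

    def input(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise SpecificationError(f"module {self.name!r} has no input {name!r}")


def fire_rules(
    spec: FuzzyModuleSpec, degrees: Mapping[str, Mapping[str, float]]
) -> list[tuple[str, float]]:
    """Activation of every rule: min over its antecedent degrees.

    Returns ``(consequent_label, activation)`` pairs; rules with zero
    activation are omitted.
    """
    for v in spec.inputs:
        if v.name not in degrees:
            raise SpecificationError(f"module {spec.name!r}: no degrees for input {v.name!r}")
    fired: list[tuple[str, float]] = []
    for rule in spec.rules:
        act = min(degrees[var][label] for var, label in rule.antecedent.items())
        if act > 0.0:
            fired.append((rule.consequent, act))
    return fired


@dataclass
class AggregatedMembership:
    """Piecewise-linear membership function given by ordered breakpoints.

    ``breakpoints`` is a list of ``(x, mu)`` with x strictly increasing and
    mu in [0, 1]; the function is linear between consecutive breakpoints and
    zero outside them.
    """

    breakpoints: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        xs = [x for x, _ in self.breakpoints]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise SpecificationError("breakpoints must have strictly increasing x")
        if any(not (-1e-12 <= mu <= 1.0 + 1e-12) for _, mu in self.breakpoints):
            raise SpecificationError("membership values must lie in [0, 1]")

    @classmethod
    def from_clipped(cls, s: TrapezoidalSet, activation: float) -> "AggregatedMembership":
        return cls(_clip_set(s, activation))

    def __call__(self, x: float) -> float:
        return _piecewise_eval(self.breakpoints, x)

    def centroid(self) -> float:
        return defuzzify_cog(self)


def _clip_set(s: TrapezoidalSet, alpha: float) -> list[tuple[float, float]]:
    """Breakpoints of min(membership, alpha); equal-x points are merged (max)."""
    pts = [
        (s.l, 0.0 if s.l < s.k1 else alpha),
        (s.l + alpha * (s.k1 - s.l), alpha),
        (s.r - alpha * (s.r - s.k2), alpha),
        (s.r, 0.0 if s.r > s.k2 else alpha),
    ]
    merged: list[tuple[float, float]] = []
    for x, mu in pts:
        if merged and x <= merged[-1][0]:
            px, pmu = merged[-1]
            merged[-1] = (px, max(pmu, mu))
        else:
            merged.append((x, mu))
    return merged


def _piecewise_eval(pts: Sequence[tuple[float, float]], x: float) -> float:
    if not pts or x < pts[0][0] or x > pts[-1][0]:
        return 0.0
    for (x0, m0), (x1, m1) in zip(pts, pts[1:]):
        if x0 <= x <= x1:
            if x1 == x0:
                return max(m0, m1)
            return m0 + (m1 - m0) * (x - x0) / (x1 - x0)
    return pts[-1][1] if x == pts[-1][0] else 0.0


def aggregate(
    fired: Iterable[tuple[str, float]], output: LinguisticVariable
) -> AggregatedMembership:
    """Pointwise max of consequent sets clipped at their activations.

    The result is exactly piecewise-linear: candidate breakpoints are every
    clipped-set breakpoint plus every crossing between two clipped segments,
    so on each interval between consecutive result breakpoints a single
    linear piece attains the maximum.
    """
    funcs: list[list[tuple[float, float]]] = []
    for label, act in fired:
        if act <= 0.0:
            continue
        funcs.append(_clip_set(output.get(label), min(act, 1.0)))
    if not funcs:
        raise ZeroMassError(
            f"no active consequent on {output.name!r}; aggregated membership is empty"
        )
    xs = sorted({x for f in funcs for x, _ in f})
    # add crossings between linear pieces inside each base interval
    extra: list[float] = []
    for a, b in zip(xs, xs[1:]):
        vals_a = [_piecewise_eval(f, a) for f in funcs]
        vals_b = [_piecewise_eval(f, b) for f in funcs]
        n = len(funcs)
        for i in range(n):
            for j in range(i + 1, n):
                da = vals_a[i] - vals_a[j]
                db = vals_b[i] - vals_b[j]
                if da * db < 0.0:
                    t = da / (da - db)
                    extra.append(a + t * (b - a))
    all_x = sorted(set(xs) | set(extra))
    pts = [(x, max(_piecewise_eval(f, x) for f in funcs)) for x in all_x]
    return AggregatedMembership(pts)


def defuzzify_cog(agg: AggregatedMembership) -> float:
    """Exact centre-of-gravity of a piecewise-linear membership function.

    Each segment between breakpoints contributes closed-form area and first
    moment; the centroid is total moment / total area.  Zero total area
    raises :class:`ZeroMassError` — there is no silent default.
    """
    area = 0.0
    moment = 0.0
    for (x0, m0), (x1, m1) in zip(agg.breakpoints, agg.breakpoints[1:]):
        dx = x1 - x0
        area += 0.5 * (m0 + m1) * dx
        moment += dx * (x0 * (2.0 * m0 + m1) + x1 * (m0 + 2.0 * m1)) / 6.0
    if area <= 1e-15:
        raise ZeroMassError("aggregated membership has zero area")
    return moment / area


def evaluate_module(spec: FuzzyModuleSpec, crisp_inputs: Mapping[str, float]) -> float:
    """Fuzzify → fire rules → aggregate → defuzzify one module."""
    missing = [v.name for v in spec.inputs if v.name not in crisp_inputs]
    if missing:
        raise FuzzyInputError(f"module {spec.name!r}: missing inputs {missing}")
    degrees = {v.name: fuzzify(v, crisp_inputs[v.name]) for v in spec.inputs}
    fired = fire_rules(spec, degrees)
    return defuzzify_cog(aggregate(fired, spec.output))


# ---------------------------------------------------------------------------
# serialization (JSON / YAML)

def _set_to_dict(s: TrapezoidalSet) -> dict:
    return {"label": s.label, "bounds": [s.l, s.k1, s.k2, s.r]}


def _set_from_dict(d: Mapping) -> TrapezoidalSet:
    l, k1, k2, r = (float(v) for v in d["bounds"])
    return TrapezoidalSet(str(d["label"]), l, k1, k2, r)


def _variable_to_dict(v: LinguisticVariable) -> dict:
    return {
        "name": v.name,
        "units": v.units,
        "domain": [v.domain_min, v.domain_max],
        "sets": [_set_to_dict(s) for s in v.sets],
    }


def _variable_from_dict(d: Mapping) -> LinguisticVariable:
    lo, hi = (float(v) for v in d["domain"])
    return LinguisticVariable(
        name=str(d["name"]),
        units=str(d.get("units", "")),
        domain_min=lo,
        domain_max=hi,
        sets=tuple(_set_from_dict(s) for s in d["sets"]),
    )


def module_to_dict(spec: FuzzyModuleSpec) -> dict:
    return {
        "name": spec.name,
        "inputs": [_variable_to_dict(v) for v in spec.inputs],
        "output": _variable_to_dict(spec.output),
        "rules": [
            {"if": dict(r.antecedent), "then": r.consequent} for r in spec.rules
        ],
    }


def module_from_dict(d: Mapping) -> FuzzyModuleSpec:
    return FuzzyModuleSpec(
        name=str(d["name"]),
        inputs=tuple(_variable_from_dict(v) for v in d["inputs"]),
        output=_variable_from_dict(d["output"]),
        rules=tuple(FuzzyRule(r["if"], r["then"]) for r in d["rules"]),
    )


def save_module(spec: FuzzyModuleSpec, path: str) -> None:
    """Write a module spec as JSON (``.json``) or YAML (anything else)."""
    payload = module_to_dict(spec)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_module(path: str) -> FuzzyModuleSpec:
    with open(path) as fh:
        if str(path).endswith(".json"):
            payload = json.load(fh)
        else:
            payload = yaml.safe_load(fh)
    return module_from_dict(payload)
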