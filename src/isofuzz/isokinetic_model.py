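"""Three-tier hierarchical fuzzy model of lower-limb isokinetic performance.

The model scores a participant's Biodex-style knee dynamometry profile —
18 crisp measurements, six per angular velocity (60, 180 and 300 deg/s) —
as a single normalized value in [0, 1].

Tier 1 (per mode): a *maximal torque* module scores the right/left
agonist–antagonist (hamstring/quadriceps) torque ratios, where mid-range
values indicate muscular balance and score best; a *relative torque* module
scores the four peak-torque-to-body-mass inputs (right/left × away/toward),
where more is better.  Tier 2 combines the two module outputs into one
per-mode score.  Tier 3 aggregates the three per-mode scores into the final
outcome ``o``.

Every module is a Mamdani unit from :mod:`isofuzz.fuzzy_core`; intermediate
crisp scores are re-fuzzified by the next tier, which keeps each rule base
tiny (9, 16, 4 and 8 rules) instead of one combinatorial table over 18
inputs.  All output variables carry mirrored boundary sets so the centroid
can reach exactly 0 and exactly 1 at the extremes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from .fuzzy_core import (
    FuzzyInputError,
    FuzzyModuleSpec,
    FuzzyRule,
    LinguisticVariable,
    TrapezoidalSet,
    evaluate_module,
    module_from_dict,
    module_to_dict,
)

__all__ = [
    "MODES",
    "MEASUREMENT_FIELDS",
    "IntervalTriple",
    "ModeBoundaryConfig",
    "ParticipantMeasurements",
    "EvaluationBreakdown",
    "HierarchicalModel",
    "DEFAULT_BOUNDARIES",
    "build_default_model",
    "generate_mt_rules",
    "generate_rt_rules",
    "generate_mode_rules",
    "generate_final_rules",
    "mt_variable",
    "rt_variable",
    "unit_score_variable",
    "graded_output_variable",
    "extend_boundary_sets",
]

MODES: tuple[int, ...] = (60, 180, 300)

#: per-mode measurement fields, in canonical CSV order
MEASUREMENT_FIELDS: tuple[str, ...] = (
    "ratio_R",
    "ratio_L",
    "away_R",
    "away_L",
    "toward_R",
    "toward_L",
)

_TOL = 1e-9


@dataclass(frozen=True)
class IntervalTriple:
    """Low/medium/high value ranges for one measured parameter.

    The ranges deliberately overlap (each medium range overlaps the adjacent
    low and high ranges), which is what produces the overlapping trapezoids.
    ``domain_max`` equals the upper bound of the high range.
    """

    low: tuple[float, float]
    medium: tuple[float, float]
    high: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (a, b) in (("low", self.low), ("medium", self.medium), ("high", self.high)):
            if a >= b:
                raise ValueError(f"{name} interval must be nondegenerate, got ({a}, {b})")
        if not (self.low[0] < self.medium[0] < self.low[1] <= self.medium[1]):
            raise ValueError("medium range must overlap the low range")
        if not (self.medium[0] <= self.high[0] < self.medium[1] < self.high[1]):
            raise ValueError("high range must overlap the medium range")

    @property
    def domain_max(self) -> float:
        return self.high[1]


@dataclass(frozen=True)
class ModeBoundaryConfig:
    """Interval configuration for one isokinetic mode (deg/s)."""

    mode: int
    agon_antag: IntervalTriple
    peaktq_bm_away: IntervalTriple
    peaktq_bm_toward: IntervalTriple

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode}")


#: measured-parameter ranges per mode, the linguistic basis of the model
DEFAULT_BOUNDARIES: dict[int, ModeBoundaryConfig] = {
    60: ModeBoundaryConfig(
        mode=60,
        agon_antag=IntervalTriple((0, 50), (45, 65), (60, 100)),
        peaktq_bm_away=IntervalTriple((0, 1.2), (1.0, 2.4), (2.3, 4.5)),
        peaktq_bm_toward=IntervalTriple((0, 0.8), (0.7, 1.5), (1.4, 3.0)),
    ),
    180: ModeBoundaryConfig(
        mode=180,
        agon_antag=IntervalTriple((0, 50), (45, 65), (60, 100)),
        peaktq_bm_away=IntervalTriple((0, 0.9), (0.8, 1.7), (1.6, 3.0)),
        peaktq_bm_toward=IntervalTriple((0, 0.7), (0.6, 1.3), (1.2, 3.0)),
    ),
    300: ModeBoundaryConfig(
        mode=300,
        agon_antag=IntervalTriple((0, 60), (55, 90), (85, 150)),
        peaktq_bm_away=IntervalTriple((0, 0.7), (0.6, 1.3), (1.2, 2.8)),
        peaktq_bm_toward=IntervalTriple((0, 0.7), (0.6, 1.3), (1.2, 2.8)),
    ),
}


# ---------------------------------------------------------------------------
# variable builders

def mt_variable(name: str, intervals: IntervalTriple, units: str = "%") -> LinguisticVariable:
    """Three-set (low/med/high) variable for an agonist–antagonist ratio.

    Convention: low = (0, 0, 0, med_lo), med = (0, med_lo, med_hi, max),
    high = (med_hi, max, max, max), where [med_lo, med_hi] is the medium
    range and max the domain maximum.
    """
    med_lo, med_hi = intervals.medium
    top = intervals.domain_max
    return LinguisticVariable(
        name=name,
        units=units,
        domain_min=0.0,
        domain_max=top,
        sets=(
            TrapezoidalSet("low", 0.0, 0.0, 0.0, med_lo),
            TrapezoidalSet("med", 0.0, med_lo, med_hi, top),
            TrapezoidalSet("high", med_hi, top, top, top),
        ),
    )


def rt_variable(
    name: str, intervals: IntervalTriple, units: str = "Nm/kg"
) -> LinguisticVariable:
    """Two-set (low/high) variable for a peak-torque-to-body-mass input.

    Convention: with m_lo the midpoint of the low range and m_hi the midpoint
    of the high range, low = (0, 0, m_lo, m_hi) and
    high = (m_lo, m_hi, max, max).
    """
    m_lo = 0.5 * (intervals.low[0] + intervals.low[1])
    m_hi = 0.5 * (intervals.high[0] + intervals.high[1])
    top = intervals.domain_max
    return LinguisticVariable(
        name=name,
        units=units,
        domain_min=0.0,
        domain_max=top,
        sets=(
            TrapezoidalSet("low", 0.0, 0.0, m_lo, m_hi),
            TrapezoidalSet("high", m_lo, m_hi, top, top),
        ),
    )


def unit_score_variable(name: str) -> LinguisticVariable:
    """Normalized [0, 1] score re-fuzzified as low = (0,0,0,1), high = (0,1,1,1)."""
    return LinguisticVariable(
        name=name,
        units="",
        domain_min=0.0,
        domain_max=1.0,
        sets=(
            TrapezoidalSet("low", 0.0, 0.0, 0.0, 1.0),
            TrapezoidalSet("high", 0.0, 1.0, 1.0, 1.0),
        ),
    )


def graded_output_variable(name: str, n_levels: int) -> LinguisticVariable:
    """Output score variable: n triangular-style levels evenly dividing [0, 1].

    Level i (1-based) is the trapezoid centred on kernel (i-1)/(n-1); the two
    extreme sets are then mirrored outward so COG can hit exactly 0 and 1.
    """
    if n_levels < 2:
        raise ValueError("need at least two output levels")
    step = 1.0 / (n_levels - 1)
    sets = []
    for i in range(n_levels):
        c = i * step
        sets.append(
            TrapezoidalSet(f"Y{i + 1}", max(c - step, 0.0), c, c, min(c + step, 1.0))
        )
    var = LinguisticVariable(
        name=name, units="", domain_min=0.0, domain_max=1.0, sets=tuple(sets)
    )
    return extend_boundary_sets(var)


def extend_boundary_sets(var: LinguisticVariable) -> LinguisticVariable:
    """Mirror the extreme sets of an output variable beyond its domain.

    The lowest set's left support is reflected from its right flank and
    symmetrically for the highest set, e.g. (0,0,0,0.5) → (−0.5,0,0,0.5).
    A full firing of an extreme set then defuzzifies to exactly the domain
    boundary instead of being pulled inward.
    """
    first, last = var.sets[0], var.sets[-1]
    new_first = TrapezoidalSet(
        first.label, first.k1 - (first.r - first.k2), first.k1, first.k2, first.r
    )
    new_last = TrapezoidalSet(
        last.label, last.l, last.k1, last.k2, last.k2 + (last.k1 - last.l)
    )
    return LinguisticVariable(
        name=var.name,
        units=var.units,
        domain_min=var.domain_min,
        domain_max=var.domain_max,
        sets=(new_first, *var.sets[1:-1], new_last),
    )


# ---------------------------------------------------------------------------
# rule generators

def generate_mt_rules() -> tuple[FuzzyRule, ...]:
    """Nine rules of the maximal-torque module (non-monotone: balance is best).

    Consequent level = 1 + number of antecedents at "med": both off-balance
    → Y1, one balanced → Y2, both balanced → Y3.
    """
    labels = ("low", "med", "high")
    rules = []
    for r in labels:
        for l_ in labels:
            level = 1 + (r == "med") + (l_ == "med")
            rules.append(FuzzyRule({"ratio_R": r, "ratio_L": l_}, f"Y{level}"))
    return tuple(rules)


def generate_rt_rules() -> tuple[FuzzyRule, ...]:
    """Sixteen rules of the relative-torque module (monotone: more is better).

    Over the 2^4 low/high combinations the consequent level is
    1 + (count of "high"): Y1 only for all-low, Y5 only for all-high.
    """
    labels = ("low", "high")
    names = ("away_R", "away_L", "toward_R", "toward_L")
    rules = []
    for a in labels:
        for b in labels:
            for c in labels:
                for d in labels:
                    combo = (a, b, c, d)
                    level = 1 + sum(x == "high" for x in combo)
                    rules.append(FuzzyRule(dict(zip(names, combo)), f"Y{level}"))
    return tuple(rules)


def generate_mode_rules() -> tuple[FuzzyRule, ...]:
    """Four rules combining per-mode maximal- and relative-torque scores."""
    rules = []
    for a in ("low", "high"):
        for b in ("low", "high"):
            level = 1 + (a == "high") + (b == "high")
            rules.append(FuzzyRule({"e_MT": a, "e_RT": b}, f"Y{level}"))
    return tuple(rules)


def generate_final_rules() -> tuple[FuzzyRule, ...]:
    """Eight rules aggregating the three per-mode scores into the outcome."""
    rules = []
    for a in ("low", "high"):
        for b in ("low", "high"):
            for c in ("low", "high"):
                level = 1 + (a == "high") + (b == "high") + (c == "high")
                rules.append(
                    FuzzyRule({"e_K60": a, "e_K180": b, "e_K300": c}, f"Y{level}")
                )
    return tuple(rules)


# ---------------------------------------------------------------------------
# data containers

@dataclass(frozen=True)
class ParticipantMeasurements:
    """The 18 crisp inputs for one participant.

    ``values[mode][field]`` with mode in {60, 180, 300} and field one of
    ``ratio_R, ratio_L`` (agonist/antagonist ratio, %) and
    ``away_R, away_L, toward_R, toward_L`` (peak torque / body mass, Nm/kg).
    """

    participant_id: str
    values: Mapping[int, Mapping[str, float]]

    def __post_init__(self) -> None:
        vals = {}
        for mode in MODES:
            if mode not in self.values:
                raise FuzzyInputError(
                    f"participant {self.participant_id!r}: missing mode {mode}"
                )
            row = dict(self.values[mode])
            for f in MEASUREMENT_FIELDS:
                if f not in row:
                    raise FuzzyInputError(
                        f"participant {self.participant_id!r}: missing {f}_{mode}"
                    )
                v = row[f]
                if v is None or not math.isfinite(v):
                    raise FuzzyInputError(
                        f"participant {self.participant_id!r}: "
                        f"non-finite value for {f}_{mode}: {v!r}"
                    )
            vals[mode] = row
        object.__setattr__(self, "values", vals)

    def flat(self) -> dict[str, float]:
        """Flatten to ``{field_mode: value}`` in canonical column order."""
        return {
            f"{f}_{m}": self.values[m][f] for m in MODES for f in MEASUREMENT_FIELDS
        }

    @classmethod
    def from_flat(cls, participant_id: str, row: Mapping[str, float]) -> "ParticipantMeasurements":
        values = {
            m: {f: float(row[f"{f}_{m}"]) for f in MEASUREMENT_FIELDS} for m in MODES
        }
        return cls(participant_id=participant_id, values=values)


@dataclass(frozen=True)
class EvaluationBreakdown:
    """All intermediate crisp scores plus the final outcome, each in [0, 1]."""

    participant_id: str
    e_MT: Mapping[int, float]
    e_RT: Mapping[int, float]
    e_K: Mapping[int, float]
    final_score: float

    def flat(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for m in MODES:
            out[f"e_MT_{m}"] = self.e_MT[m]
            out[f"e_RT_{m}"] = self.e_RT[m]
            out[f"e_K{m}"] = self.e_K[m]
        out["final_score"] = self.final_score
        return out


# ---------------------------------------------------------------------------
# the hierarchical model

def _check_unit(name: str, value: float) -> float:
    if value is None or not math.isfinite(value):
        raise FuzzyInputError(f"{name}: non-finite value {value!r}")
    if value < -_TOL or value > 1.0 + _TOL:
        raise FuzzyInputError(f"{name}: expected a [0, 1] score, got {value!r}")
    return min(max(value, 0.0), 1.0)


class HierarchicalModel:
    """Seven wired Mamdani modules scoring one participant end to end.

    Per mode: ``mt`` (ratios → e_MT), ``rt`` (torque/body-mass → e_RT) and
    ``combiner`` (e_MT, e_RT → e_K); one ``final`` module (e_K60, e_K180,
    e_K300 → o).  Build the study configuration with
    :func:`build_default_model`, or load a customized one from JSON/YAML via
    :meth:`from_config_file`.
    """

    def __init__(
        self,
        mt: Mapping[int, FuzzyModuleSpec],
        rt: Mapping[int, FuzzyModuleSpec],
        combiner: Mapping[int, FuzzyModuleSpec],
        final: FuzzyModuleSpec,
    ) -> None:
        self.mt = dict(mt)
        self.rt = dict(rt)
        self.combiner = dict(combiner)
        self.final = final
        for m in MODES:
            if m not in self.mt or m not in self.rt or m not in self.combiner:
                raise ValueError(f"missing modules for mode {m}")

    # -- tier evaluations ---------------------------------------------------
    def evaluate_mt(self, mode: int, ratio_R: float, ratio_L: float) -> float:
        """Score the agonist–antagonist balance of both legs for one mode."""
        return evaluate_module(
            self.mt[mode], {"ratio_R": ratio_R, "ratio_L": ratio_L}
        )

    def evaluate_rt(
        self, mode: int, away_R: float, away_L: float, toward_R: float, toward_L: float
    ) -> float:
        """Score the four relative-torque inputs for one mode."""
        return evaluate_module(
            self.rt[mode],
            {
                "away_R": away_R,
                "away_L": away_L,
                "toward_R": toward_R,
                "toward_L": toward_L,
            },
        )

    def evaluate_mode(self, mode: int, e_MT: float, e_RT: float) -> float:
        """Combine the two tier-1 scores of one mode into e_K."""
        return evaluate_module(
            self.combiner[mode],
            {"e_MT": _check_unit("e_MT", e_MT), "e_RT": _check_unit("e_RT", e_RT)},
        )

    def evaluate_final(self, e_K60: float, e_K180: float, e_K300: float) -> float:
        """Aggregate the three per-mode scores into the final outcome."""
        return evaluate_module(
            self.final,
            {
                "e_K60": _check_unit("e_K60", e_K60),
                "e_K180": _check_unit("e_K180", e_K180),
                "e_K300": _check_unit("e_K300", e_K300),
            },
        )

    def evaluate_participant(self, m: ParticipantMeasurements) -> EvaluationBreakdown:
        """Run all three tiers and return every intermediate crisp score."""
        e_mt, e_rt, e_k = {}, {}, {}
        for mode in MODES:
            row = m.values[mode]
            e_mt[mode] = self.evaluate_mt(mode, row["ratio_R"], row["ratio_L"])
            e_rt[mode] = self.evaluate_rt(
                mode, row["away_R"], row["away_L"], row["toward_R"], row["toward_L"]
            )
            e_k[mode] = self.evaluate_mode(mode, e_mt[mode], e_rt[mode])
        o = self.evaluate_final(e_k[60], e_k[180], e_k[300])
        return EvaluationBreakdown(
            participant_id=m.participant_id,
            e_MT=e_mt,
            e_RT=e_rt,
            e_K=e_k,
            final_score=o,
        )

    # -- (de)serialization --------------------------------------------------
    def modules(self) -> list[FuzzyModuleSpec]:
        out = []
        for m in MODES:
            out.extend([self.mt[m], self.rt[m], self.combiner[m]])
        out.append(self.final)
        return out

    def to_config(self) -> dict:
        return {
            "format": "isofuzz-model/1",
            "modules": {
                **{f"mt_{m}": module_to_dict(self.mt[m]) for m in MODES},
                **{f"rt_{m}": module_to_dict(self.rt[m]) for m in MODES},
                **{f"combiner_{m}": module_to_dict(self.combiner[m]) for m in MODES},
                "final": module_to_dict(self.final),
            },
        }

    @classmethod
    def from_config(cls, config: Mapping) -> "HierarchicalModel":
        mods = config["modules"]
        return cls(
            mt={m: module_from_dict(mods[f"mt_{m}"]) for m in MODES},
            rt={m: module_from_dict(mods[f"rt_{m}"]) for m in MODES},
            combiner={m: module_from_dict(mods[f"combiner_{m}"]) for m in MODES},
            final=module_from_dict(mods["final"]),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_config(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_config_file(cls, path: str) -> "HierarchicalModel":
        with open(path) as fh:
            if str(path).endswith(".json"):
                config = json.load(fh)
            else:
                config = yaml.safe_load(fh)
        return cls.from_config(config)


def build_default_model(
    boundaries: Mapping[int, ModeBoundaryConfig] | None = None,
) -> HierarchicalModel:
    """Assemble the default seven-module hierarchy.

    Mode-60 input sets follow the published system definition verbatim;
    modes 180 and 300 apply the same set-shape conventions to their own
    measured ranges.  Pass ``boundaries`` to override any mode's ranges.
    """
    bounds = dict(DEFAULT_BOUNDARIES)
    if boundaries:
        bounds.update(boundaries)

    mt, rt, combiner = {}, {}, {}
    mt_rules = generate_mt_rules()
    rt_rules = generate_rt_rules()
    mode_rules = generate_mode_rules()
    for m in MODES:
        cfg = bounds[m]
        mt[m] = FuzzyModuleSpec(
            name=f"maximal_torque_{m}",
            inputs=(
                mt_variable("ratio_R", cfg.agon_antag),
                mt_variable("ratio_L", cfg.agon_antag),
            ),
            output=graded_output_variable("e_MT", 3),
            rules=mt_rules,
        )
        rt[m] = FuzzyModuleSpec(
            name=f"relative_torque_{m}",
            inputs=(
                rt_variable("away_R", cfg.peaktq_bm_away),
                rt_variable("away_L", cfg.peaktq_bm_away),
                rt_variable("toward_R", cfg.peaktq_bm_toward),
                rt_variable("toward_L", cfg.peaktq_bm_toward),
            ),
            output=graded_output_variable("e_RT", 5),
            rules=rt_rules,
        )
        combiner[m] = FuzzyModuleSpec(
            name=f"isokinetics_{m}",
            inputs=(unit_score_variable("e_MT"), unit_score_variable("e_RT")),
            output=graded_output_variable(f"e_K{m}", 3),
            rules=mode_rules,
        )
    final = FuzzyModuleSpec(
        name="final",
        inputs=(
            unit_score_variable("e_K60"),
            unit_score_variable("e_K180"),
            unit_score_variable("e_K300"),
        ),
        output=graded_output_variable("o", 4),
        rules=generate_final_rules(),
    )
    return HierarchicalModel(mt=mt, rt=rt, combiner=combiner, final=final)


def load_bundled_model() -> HierarchicalModel:
    """Load the bundled default configuration (identical to build_default_model())."""
    ref = resources.files("isofuzz.data") / "default_model.json"
    with ref.open() as fh:
        return HierarchicalModel.from_config(json.load(fh))
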