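"""Seeded generator of Biodex-like measurement cohorts.

The study's raw dynamometer measurements were never deposited, so end-to-end
runs use synthetic cohorts.  Each measured input is drawn from a normal
distribution truncated to its variable domain; the three default group
profiles (deaf soccer players, hearing soccer players, deaf untrained) are
honest inventions with typical knee-dynamometry locations, separated so that
scored group medians order as deaf untrained > deaf players > hearing
players, matching the ordering reported for the real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort_pipeline import CohortTable
from .isokinetic_model import (
    DEFAULT_BOUNDARIES,
    MEASUREMENT_FIELDS,
    MODES,
    ModeBoundaryConfig,
    ParticipantMeasurements,
)

__all__ = ["GroupProfile", "generate_group", "generate_cohort", "default_profiles"]


@dataclass(frozen=True)
class GroupProfile:
    """Truncated-normal sampler settings for one participant group.

    ``params[mode][field]`` is ``(loc, scale)`` in the field's own units
    (% for ratios, Nm/kg for torque inputs).  Sampling is truncated to the
    field's variable domain ``[0, domain_max]``; ``scale`` may be 0 for a
    degenerate (constant) profile.
    """

    name: str
    n_default: int
    params: Mapping[int, Mapping[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        if self.n_default < 1:
            raise ValueError("n_default must be >= 1")
        for mode in MODES:
            if mode not in self.params:
                raise ValueError(f"profile {self.name!r}: missing mode {mode}")
            for f in MEASUREMENT_FIELDS:
                if f not in self.params[mode]:
                    raise ValueError(f"profile {self.name!r}: missing {f}_{mode}")
                loc, scale = self.params[mode][f]
                lo, hi = _domain(mode, f)
                if scale < 0:
                    raise ValueError(f"profile {self.name!r}: negative spread for {f}_{mode}")
                if not (lo <= loc <= hi):
                    raise ValueError(
                        f"profile {self.name!r}: location {loc} for {f}_{mode} "
                        f"outside domain [{lo}, {hi}]"
                    )


def _domain(mode: int, field: str, boundaries: Mapping[int, ModeBoundaryConfig] = DEFAULT_BOUNDARIES) -> tuple[float, float]:
    cfg = boundaries[mode]
    if field.startswith("ratio"):
        return (0.0, cfg.agon_antag.domain_max)
    if field.startswith("away"):
        return (0.0, cfg.peaktq_bm_away.domain_max)
    return (0.0, cfg.peaktq_bm_toward.domain_max)


def generate_group(
    profile: GroupProfile, n: int | None = None, seed: int | None = None, *, id_prefix: str | None = None
) -> CohortTable:
    """Sample ``n`` participants from a group profile.

    Deterministic for identical ``(profile, n, seed)``; every sampled value
    lies inside its variable domain by construction (truncation).
    """
    if n is None:
        n = profile.n_default
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else profile.name
    participants = []
    for i in range(n):
        values: dict[int, dict[str, float]] = {}
        for mode in MODES:
            row = {}
            for f in MEASUREMENT_FIELDS:
                loc, scale = profile.params[mode][f]
                lo, hi = _domain(mode, f)
                if scale == 0.0:
                    row[f] = float(loc)
                else:
                    a, b = (lo - loc) / scale, (hi - loc) / scale
                    row[f] = float(
                        stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)
                    )
            values[mode] = row
        participants.append(
            ParticipantMeasurements(participant_id=f"{prefix}_{i + 1:03d}", values=values)
        )
    groups = {p.participant_id: profile.name for p in participants}
    return CohortTable(participants=participants, groups=groups)


def generate_cohort(
    profiles: Mapping[str, GroupProfile] | None = None, seed: int = 0
) -> CohortTable:
    """Concatenate one default-size sample per profile (distinct substreams)."""
    if profiles is None:
        profiles = default_profiles()
    ss = np.random.SeedSequence(seed).spawn(len(profiles))
    participants, groups = [], {}
    for sub, (key, prof) in zip(ss, sorted(profiles.items())):
        tbl = generate_group(prof, seed=int(sub.generate_state(1)[0] % (2**31)))
        participants.extend(tbl.participants)
        groups.update(tbl.groups)
    return CohortTable(participants=participants, groups=groups)


def _profile(
    name: str,
    n: int,
    ratio: tuple[float, float, float],  # loc at 60, 180, 300
    away: tuple[float, float, float],
    toward: tuple[float, float, float],
    ratio_sd: float = 8.0,
    torque_sd: float = 0.35,
) -> GroupProfile:
    params: dict[int, dict[str, tuple[float, float]]] = {}
    for i, mode in enumerate(MODES):
        params[mode] = {
            "ratio_R": (ratio[i], ratio_sd),
            "ratio_L": (ratio[i], ratio_sd),
            "away_R": (away[i], torque_sd),
            "away_L": (away[i], torque_sd),
            "toward_R": (toward[i], torque_sd),
            "toward_L": (toward[i], torque_sd),
        }
    return GroupProfile(name=name, n_default=n, params=params)


def default_profiles() -> dict[str, GroupProfile]:
    """Three invented group profiles mirroring the study's cohort structure.

    Group sizes follow the real cohorts (28 / 19 / 46).  Ratio locations sit
    near the balanced mid-kernel for the stronger groups and drift upward
    (quadriceps-dominant imbalance) for the weakest; relative-torque
    locations are ordered deaf untrained > deaf players > hearing players,
    which propagates to the same ordering of scored medians.
    """
    return {
        "deaf_players": _profile(
            "deaf_players",
            n=28,
            ratio=(56.0, 57.0, 70.0),
            away=(3.00, 2.00, 1.70),
            toward=(1.90, 1.80, 1.70),
        ),
        "hearing_players": _profile(
            "hearing_players",
            n=19,
            ratio=(62.0, 63.0, 64.0),
            away=(2.55, 1.70, 1.45),
            toward=(1.60, 1.50, 1.45),
        ),
        "deaf_untrained": _profile(
            "deaf_untrained",
            n=46,
            ratio=(55.0, 56.0, 72.0),
            away=(3.20, 2.15, 1.85),
            toward=(2.05, 1.95, 1.85),
        ),
    }
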