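"""Tests of the three-tier hierarchical dynamometry model."""

import itertools

import numpy as np
import pytest

from isofuzz.fuzzy_core import ClampWarning, FuzzyInputError
from isofuzz.isokinetic_model import (
    DEFAULT_BOUNDARIES,
    MEASUREMENT_FIELDS,
    MODES,
    HierarchicalModel,
    IntervalTriple,
    ParticipantMeasurements,
    build_default_model,
    generate_final_rules,
    generate_mode_rules,
    generate_mt_rules,
    generate_rt_rules,
    load_bundled_model,
    mt_variable,
    rt_variable,
)

from conftest import make_participant, optimal_inputs

ATOL = 1e-9


# hand transcriptions of the published rule lists, written out literally so
# the generators are checked against an independent encoding
MT_RULES = {
    ("low", "low"): "Y1", ("low", "med"): "Y2", ("low", "high"): "Y1",
    ("med", "low"): "Y2", ("med", "med"): "Y3", ("med", "high"): "Y2",
    ("high", "low"): "Y1", ("high", "med"): "Y2", ("high", "high"): "Y1",
}
RT_RULES = {
    ("low", "low", "low", "low"): "Y1",
    ("low", "low", "low", "high"): "Y2",
    ("low", "low", "high", "low"): "Y2",
    ("low", "low", "high", "high"): "Y3",
    ("low", "high", "low", "low"): "Y2",
    ("low", "high", "low", "high"): "Y3",
    ("low", "high", "high", "low"): "Y3",
    ("low", "high", "high", "high"): "Y4",
    ("high", "low", "low", "low"): "Y2",
    ("high", "low", "low", "high"): "Y3",
    ("high", "low", "high", "low"): "Y3",
    ("high", "low", "high", "high"): "Y4",
    ("high", "high", "low", "low"): "Y3",
    ("high", "high", "low", "high"): "Y4",
    ("high", "high", "high", "low"): "Y4",
    ("high", "high", "high", "high"): "Y5",
}
MODE_RULES = {
    ("low", "low"): "Y1", ("low", "high"): "Y2",
    ("high", "low"): "Y2", ("high", "high"): "Y3",
}
FINAL_RULES = {
    ("low", "low", "low"): "Y1",
    ("high", "low", "low"): "Y2",
    ("low", "high", "low"): "Y2",
    ("low", "low", "high"): "Y2",
    ("high", "high", "low"): "Y3",
    ("low", "high", "high"): "Y3",
    ("high", "low", "high"): "Y3",
    ("high", "high", "high"): "Y4",
}


class TestRuleGenerators:
    def test_mt_rules_match_transcription(self):
        rules = generate_mt_rules()
        assert len(rules) == 9
        table = {(r.antecedent["ratio_R"], r.antecedent["ratio_L"]): r.consequent for r in rules}
        assert table == MT_RULES

    def test_rt_rules_match_transcription(self):
        rules = generate_rt_rules()
        assert len(rules) == 16
        table = {
            tuple(r.antecedent[k] for k in ("away_R", "away_L", "toward_R", "toward_L")): r.consequent
            for r in rules
        }
        assert table == RT_RULES

    def test_mode_rules_match_transcription(self):
        rules = generate_mode_rules()
        assert len(rules) == 4
        table = {(r.antecedent["e_MT"], r.antecedent["e_RT"]): r.consequent for r in rules}
        assert table == MODE_RULES

    def test_final_rules_match_transcription(self):
        rules = generate_final_rules()
        assert len(rules) == 8
        table = {
            tuple(r.antecedent[k] for k in ("e_K60", "e_K180", "e_K300")): r.consequent
            for r in rules
        }
        assert table == FINAL_RULES


class TestDefaultBoundaries:
    """The set-shape conventions must regenerate the published mode-60 sets
    exactly before being trusted for modes 180 and 300."""

    def test_mode60_ratio_sets_verbatim(self):
        var = mt_variable("ratio_R", DEFAULT_BOUNDARIES[60].agon_antag)
        assert [s.bounds for s in var.sets] == [
            (0, 0, 0, 45), (0, 45, 65, 100), (65, 100, 100, 100)
        ]

    def test_mode60_away_sets_verbatim(self):
        var = rt_variable("away_R", DEFAULT_BOUNDARIES[60].peaktq_bm_away)
        assert [s.bounds for s in var.sets] == [(0, 0, 0.6, 3.4), (0.6, 3.4, 4.5, 4.5)]

    def test_mode60_toward_sets_verbatim(self):
        var = rt_variable("toward_R", DEFAULT_BOUNDARIES[60].peaktq_bm_toward)
        assert [s.bounds for s in var.sets] == [(0, 0, 0.4, 2.2), (0.4, 2.2, 3.0, 3.0)]

    def test_mode180_derived_sets(self, model):
        away = model.rt[180].input("away_R")
        assert [s.bounds for s in away.sets] == [(0, 0, 0.45, 2.3), (0.45, 2.3, 3.0, 3.0)]
        toward = model.rt[180].input("toward_L")
        assert [s.bounds for s in toward.sets] == [(0, 0, 0.35, 2.1), (0.35, 2.1, 3.0, 3.0)]

    def test_mode300_derived_sets(self, model):
        ratio = model.mt[300].input("ratio_R")
        assert [s.bounds for s in ratio.sets] == [
            (0, 0, 0, 55), (0, 55, 90, 150), (90, 150, 150, 150)
        ]

    def test_output_sets_with_mirrored_boundaries(self, model):
        third = 1.0 / 3.0
        assert [s.bounds for s in model.final.output.sets] == [
            pytest.approx((-third, 0, 0, third)),
            pytest.approx((0, third, third, 2 * third)),
            pytest.approx((third, 2 * third, 2 * third, 1)),
            pytest.approx((2 * third, 1, 1, 1 + third)),
        ]
        assert [s.bounds for s in model.mt[60].output.sets] == [
            (-0.5, 0, 0, 0.5), (0, 0.5, 0.5, 1), (0.5, 1, 1, 1.5)
        ]
        assert [s.bounds for s in model.rt[60].output.sets] == [
            (-0.25, 0, 0, 0.25), (0, 0.25, 0.25, 0.5),
            (0.25, 0.5, 0.5, 0.75), (0.5, 0.75, 0.75, 1), (0.75, 1, 1, 1.25)
        ]

    def test_interval_overlap_validation(self):
        with pytest.raises(ValueError):
            IntervalTriple((0, 40), (50, 65), (60, 100))  # medium does not overlap low

    def test_bundled_config_equals_builder(self, model):
        assert load_bundled_model().to_config() == model.to_config()


class TestTierEvaluations:
    @pytest.mark.parametrize("mode, balanced", [(60, 55.0), (180, 55.0), (300, 72.5)])
    def test_mt_boundary_scores(self, model, mode, balanced):
        assert model.evaluate_mt(mode, balanced, balanced) == pytest.approx(1.0, abs=ATOL)
        assert model.evaluate_mt(mode, 0.0, 0.0) == pytest.approx(0.0, abs=ATOL)
        assert model.evaluate_mt(mode, balanced, 0.0) == pytest.approx(0.5, abs=ATOL)

    def test_rt_boundary_scores(self, model):
        assert model.evaluate_rt(60, 4.5, 4.5, 3.0, 3.0) == pytest.approx(1.0, abs=ATOL)
        assert model.evaluate_rt(60, 0, 0, 0, 0) == pytest.approx(0.0, abs=ATOL)
        # exactly one 'high' input: second output level, symmetric centroid
        assert model.evaluate_rt(60, 0, 0, 0, 3.0) == pytest.approx(0.25, abs=ATOL)

    @pytest.mark.parametrize(
        "e_mt, e_rt, expected",
        [(0, 0, 0.0), (1, 1, 1.0), (0.5, 0.5, 0.5), (1, 0, 0.5), (0, 1, 0.5)],
    )
    def test_mode_combiner(self, model, e_mt, e_rt, expected):
        assert model.evaluate_mode(60, e_mt, e_rt) == pytest.approx(expected, abs=ATOL)

    def test_mode_combiner_rejects_out_of_range(self, model):
        with pytest.raises(FuzzyInputError):
            model.evaluate_mode(60, 1.2, 0.5)

    @pytest.mark.parametrize(
        "ek, expected",
        [
            ((0, 0, 0), 0.0),
            ((1, 1, 1), 1.0),
            ((1, 0, 0), 1 / 3),
            ((1, 1, 0), 2 / 3),
        ],
    )
    def test_final_tier(self, model, ek, expected):
        assert model.evaluate_final(*ek) == pytest.approx(expected, abs=1e-9)

    def test_final_tier_rejects_out_of_range(self, model):
        with pytest.raises(FuzzyInputError):
            model.evaluate_final(0.5, -0.2, 0.5)


class TestParticipantEvaluation:
    def test_all_minimum_scores_zero(self, model):
        assert model.evaluate_participant(make_participant()).final_score == pytest.approx(0.0, abs=ATOL)

    def test_all_optimal_scores_one(self, model):
        p = ParticipantMeasurements("opt", optimal_inputs())
        b = model.evaluate_participant(p)
        assert b.final_score == pytest.approx(1.0, abs=ATOL)
        for m in MODES:
            assert b.e_MT[m] == pytest.approx(1.0, abs=ATOL)
            assert b.e_RT[m] == pytest.approx(1.0, abs=ATOL)
            assert b.e_K[m] == pytest.approx(1.0, abs=ATOL)

    def test_one_optimal_mode_scores_one_third(self, model):
        vals = {m: {f: 0.0 for f in MEASUREMENT_FIELDS} for m in MODES}
        vals[60] = optimal_inputs()[60]
        p = ParticipantMeasurements("mixed", vals)
        b = model.evaluate_participant(p)
        assert b.e_K[60] == pytest.approx(1.0, abs=ATOL)
        assert b.e_K[180] == pytest.approx(0.0, abs=ATOL)
        assert b.final_score == pytest.approx(1 / 3, abs=1e-9)

    def test_breakdown_composes_tier_operations(self, model):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = {}
            for m in MODES:
                cfg = DEFAULT_BOUNDARIES[m]
                vals[m] = {
                    "ratio_R": rng.uniform(0, cfg.agon_antag.domain_max),
                    "ratio_L": rng.uniform(0, cfg.agon_antag.domain_max),
                    "away_R": rng.uniform(0, cfg.peaktq_bm_away.domain_max),
                    "away_L": rng.uniform(0, cfg.peaktq_bm_away.domain_max),
                    "toward_R": rng.uniform(0, cfg.peaktq_bm_toward.domain_max),
                    "toward_L": rng.uniform(0, cfg.peaktq_bm_toward.domain_max),
                }
            p = ParticipantMeasurements("r", vals)
            b = model.evaluate_participant(p)
            for m in MODES:
                assert b.e_MT[m] == model.evaluate_mt(m, vals[m]["ratio_R"], vals[m]["ratio_L"])
                assert b.e_RT[m] == model.evaluate_rt(
                    m, vals[m]["away_R"], vals[m]["away_L"],
                    vals[m]["toward_R"], vals[m]["toward_L"],
                )
                assert b.e_K[m] == model.evaluate_mode(m, b.e_MT[m], b.e_RT[m])
            assert b.final_score == model.evaluate_final(b.e_K[60], b.e_K[180], b.e_K[300])
            assert 0.0 <= b.final_score <= 1.0

    def test_missing_field_names_the_field(self):
        vals = {m: {f: 0.0 for f in MEASUREMENT_FIELDS} for m in MODES}
        del vals[180]["toward_L"]
        with pytest.raises(FuzzyInputError, match="toward_L_180"):
            ParticipantMeasurements("p", vals)

    def test_nan_measurement_is_error(self):
        with pytest.raises(FuzzyInputError, match="away_R_60"):
            make_participant(away_R_60=float("nan"))

    def test_out_of_domain_measurement_clamps_with_warning(self, model):
        p = make_participant(ratio_R_60=103.0)
        with pytest.warns(ClampWarning):
            b = model.evaluate_participant(p)
        assert 0.0 <= b.final_score <= 1.0

    def test_flat_round_trip(self):
        p = make_participant(ratio_R_60=55.0, toward_L_300=1.5)
        q = ParticipantMeasurements.from_flat(p.participant_id, p.flat())
        assert q == p


class TestStructuralProperties:
    def test_mt_left_right_symmetry(self, model):
        grid = np.linspace(0, 100, 15)
        for a in grid:
            for b in grid:
                assert model.evaluate_mt(60, float(a), float(b)) == pytest.approx(
                    model.evaluate_mt(60, float(b), float(a)), abs=ATOL
                )

    def test_mt_unimodality_in_one_ratio(self, model):
        # with the other leg balanced, a balanced ratio beats both extremes
        mid = model.evaluate_mt(60, 55.0, 55.0)
        assert mid >= model.evaluate_mt(60, 0.0, 55.0)
        assert mid >= model.evaluate_mt(60, 100.0, 55.0)

    def test_rt_monotone_in_each_input(self, model):
        base = [2.0, 2.0, 1.5, 1.5]
        grids = [np.linspace(0, 4.5, 5), np.linspace(0, 4.5, 5),
                 np.linspace(0, 3.0, 5), np.linspace(0, 3.0, 5)]
        for i, grid in enumerate(grids):
            prev = -1.0
            for v in grid:
                args = list(base)
                args[i] = float(v)
                e = model.evaluate_rt(60, *args)
                assert e >= prev - ATOL
                prev = e

    def test_mode_combiner_monotone(self, model):
        grid = np.linspace(0, 1, 9)
        for fixed in (0.0, 0.3, 0.7, 1.0):
            row = [model.evaluate_mode(60, float(x), fixed) for x in grid]
            assert all(b >= a - ATOL for a, b in zip(row, row[1:]))
            col = [model.evaluate_mode(60, fixed, float(x)) for x in grid]
            assert all(b >= a - ATOL for a, b in zip(col, col[1:]))

    def test_final_tier_permutation_invariance(self, model):
        grid = np.linspace(0, 1, 5)
        for trio in itertools.product(grid, repeat=3):
            ref = model.evaluate_final(*map(float, trio))
            for perm in itertools.permutations(trio):
                assert model.evaluate_final(*map(float, perm)) == pytest.approx(ref, abs=ATOL)

    def test_final_tier_monotone(self, model):
        grid = np.linspace(0, 1, 7)
        for a in (0.0, 0.5, 1.0):
            for b in (0.0, 0.5, 1.0):
                row = [model.evaluate_final(float(x), a, b) for x in grid]
                assert all(y >= x - ATOL for x, y in zip(row, row[1:]))


class TestModelSerialization:
    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_model_config_round_trip(self, tmp_path, model, ext):
        path = tmp_path / f"model.{ext}"
        model.save(str(path))
        loaded = HierarchicalModel.from_config_file(str(path))
        assert loaded.to_config() == model.to_config()

    def test_loaded_model_evaluates_identically(self, tmp_path, model):
        path = tmp_path / "model.json"
        model.save(str(path))
        loaded = HierarchicalModel.from_config_file(str(path))
        p = make_participant(ratio_R_60=70.0, ratio_L_60=55.0, away_R_60=3.0)
        assert loaded.evaluate_participant(p) == model.evaluate_participant(p)
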