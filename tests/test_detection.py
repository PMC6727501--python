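"""Residual Z-scores, outfit person fit, and the up-coding flag."""

import math

import numpy as np
import pytest

from drgrasch import (
    ClaimRecord,
    ClaimSet,
    NormModel,
    SimConfig,
    expected_score,
    flag_items,
    inject_upcoding,
    outfit_mnsq,
    residual_z,
    score_case,
    score_claimset,
    simulate_claimset,
    simulate_study,
    fit_norm_model,
)
from drgrasch.claims import NormalizationBounds
from drgrasch.detection import (
    ResidualCell,
    case_score_from_dict,
    case_score_to_dict,
    case_scores_to_frame,
    read_case_scores,
    write_case_scores,
)
from drgrasch.rasch import ConvergenceReport, ItemCalibration


def _cell(z, item="X"):
    return ResidualCell(item_id=item, O=0.5, E=0.5, var=0.25, z=z, raw_fee=1.0)


class TestResidualZ:
    def test_zero_residual(self):
        assert residual_z(0.5, 0.5) == 0.0

    def test_closed_form(self):
        assert residual_z(0.9, 0.1) == pytest.approx(0.8 / 0.3)

    def test_antisymmetry(self):
        assert residual_z(0.1, 0.9) == pytest.approx(-residual_z(0.9, 0.1))

    def test_degenerate_expected_rejected(self):
        with pytest.raises(ValueError):
            residual_z(0.5, 1.0)


class TestOutfit:
    def test_all_zero_residuals(self):
        assert outfit_mnsq([_cell(0.0), _cell(0.0), _cell(0.0)]) == 0.0

    def test_mean_of_squares(self):
        assert outfit_mnsq([_cell(1.0), _cell(-1.0), _cell(2.0)]) == pytest.approx(2.0)

    def test_singleton(self):
        assert outfit_mnsq([_cell(3.62)]) == pytest.approx(13.1044)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            outfit_mnsq([])


class TestFlagItems:
    def test_exceeding_cell_flagged(self):
        assert flag_items([_cell(3.62, "plasma")]) == {"plasma"}

    def test_boundary_is_strict(self):
        assert flag_items([_cell(2.0)]) == frozenset()

    def test_sides(self):
        cells = [_cell(-3.0, "low")]
        assert flag_items(cells, side="upper") == frozenset()
        assert flag_items(cells, side="two") == {"low"}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            flag_items([_cell(1.0)], threshold=0.0)


def _toy_model(deltas: dict[str, float], hi: float = 1000.0) -> NormModel:
    """Hand-built model: bounds [0, hi] per item, given centered deltas."""
    items = [
        ItemCalibration(item_id=i, delta=d, se=0.1, n_obs=10)
        for i, d in deltas.items()
    ]
    return NormModel(
        drg_code="D1",
        bounds=NormalizationBounds({i: (0.0, hi) for i in deltas}),
        items=items,
        convergence=ConvergenceReport(1, 0.0, True, 1e-4, 100),
    )


class TestScoreCase:
    def test_self_consistent_case_has_zero_residuals(self):
        deltas = {"a": -1.0, "b": 0.0, "c": 1.0}
        model = _toy_model(deltas)
        theta = 0.3
        fees = {
            i: float(expected_score(theta, d)) * 1000.0
            for i, d in deltas.items()
        }
        rec = ClaimRecord("C1", "D1", 2015, fees)
        score = score_case(rec, model)
        for cell in score.cells:
            assert cell.z == pytest.approx(0.0, abs=1e-3)
        assert score.outfit_mnsq == pytest.approx(0.0, abs=1e-6)
        assert not score.case_flagged

    def test_inflated_item_is_case_maximum_and_flagged(self):
        """A low-fee case claiming one item near the norm maximum gets
        that item flagged: the up-coded cell dominates the residuals."""
        deltas = {"a": -1.0, "b": -1.0, "c": 0.0, "d": 2.0}
        model = _toy_model(deltas)
        fees = {"a": 30.0, "b": 20.0, "c": 10.0, "d": 950.0}
        score = score_case(ClaimRecord("C2", "D1", 2015, fees), model)
        z = score.z_by_item()
        assert max(z, key=z.get) == "d"
        assert z["d"] > 2.0
        assert score.flagged_items == {"d"}
        assert score.case_flagged

    def test_drg_mismatch_rejected(self):
        model = _toy_model({"a": 0.0, "b": 0.0})
        rec = ClaimRecord("C1", "OTHER", 2015, {"a": 10.0})
        with pytest.raises(ValueError, match="OTHER"):
            score_case(rec, model)

    def test_all_missing_yields_unscorable(self):
        model = _toy_model({"a": 0.0, "b": 0.0})
        rec = ClaimRecord("C1", "D1", 2015, {"a": 0.0, "b": 0.0})
        score = score_case(rec, model)
        assert score.status == "unscorable"
        assert score.cells == [] and not score.case_flagged

    def test_residual_conservation_at_fixed_point(self, study):
        """At the estimated ability the raw residuals sum to ~0, hence
        sum(z * sqrt(var)) vanishes over each case's observed cells."""
        for s in study["result"].scored()[:50]:
            total = sum(c.z * math.sqrt(c.var) for c in s.cells)
            var_sum = sum(c.var for c in s.cells)
            assert abs(total) < 1e-3 * var_sum + 1e-6


class TestInjectionEffect:
    def test_upcoding_strictly_increases_target_z(self):
        """Paired comparison: scoring the same case before and after
        injection, every injected cell whose normalized value actually
        moved (was not already saturated at the clamp cap) gets a
        strictly larger z."""
        cfg = SimConfig(seed=19, n_norm=80, n_exp=25, n_items=8, p_miss=0.0)
        norm_set, _ = simulate_claimset(cfg, role="norm")
        exp_clean, truth_clean = simulate_claimset(cfg, role="experimental")
        exp_up, truth_up = inject_upcoding(exp_clean, truth_clean, cfg)
        model = fit_norm_model(norm_set, cfg.drg_code)
        def by_case(claims):
            scores = score_claimset(claims, {cfg.drg_code: model}).scores
            return {
                s.case_id: {c.item_id: c for c in s.cells} for s in scores
            }

        before = by_case(exp_clean)
        after = by_case(exp_up)
        assert truth_up.upcoded
        moved = 0
        for case_id, item in truth_up.upcoded:
            b, a = before[case_id][item], after[case_id][item]
            if a.O - b.O >= 0.1:  # injection not swallowed by the clamp
                assert a.z > b.z
                moved += 1
        assert moved >= len(truth_up.upcoded) // 2


class TestScoreClaimset:
    def test_complete_data_cell_count(self):
        """With no missing cells, residual cells = cases x items."""
        cfg = SimConfig(seed=5, n_norm=60, n_exp=20, n_items=17, p_miss=0.0)
        norm_set, _, exp_set, _ = simulate_study(cfg)
        model = fit_norm_model(norm_set, cfg.drg_code)
        result = score_claimset(exp_set, {cfg.drg_code: model})
        assert result.n_cells() == 20 * 17

    def test_unknown_drg_skipped_others_scored(self, small_study):
        exp = small_study["exp_set"]
        stray = ClaimRecord("STRAY", "NO-MODEL", 2015, {"DRUG01": 10.0})
        claims = ClaimSet(
            schema=exp.schema, records=exp.records + [stray], role="experimental"
        )
        result = score_claimset(
            claims, {small_study["config"].drg_code: small_study["model"]}
        )
        assert ("STRAY", "no model for DRG NO-MODEL") in result.skipped
        assert len(result.scores) == len(exp.records)

    def test_empty_claimset(self, small_study):
        empty = ClaimSet(schema=small_study["exp_set"].schema, records=[])
        result = score_claimset(empty, {})
        assert result.scores == [] and result.skipped == []


class TestSerialization:
    def test_json_round_trip(self, small_study, tmp_path):
        path = tmp_path / "scores.json"
        scores = small_study["result"].scores
        write_case_scores(scores, path)
        back = read_case_scores(path)
        assert back == scores

    def test_dict_round_trip_unscorable(self):
        model = _toy_model({"a": 0.0, "b": 0.0})
        score = score_case(ClaimRecord("C1", "D1", 2015, {}), model)
        assert case_score_from_dict(case_score_to_dict(score)) == score

    def test_flat_frame_columns(self, small_study):
        df = case_scores_to_frame(small_study["result"].scores)
        assert list(df.columns) == [
            "case_id", "drg", "year", "item", "fee", "O", "E", "var", "z",
            "flagged",
        ]
        assert len(df) == small_study["result"].n_cells()
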