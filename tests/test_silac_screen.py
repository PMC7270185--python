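"""Label-swap SILAC screen: parsing, orientation, calling, QC, pulsed SILAC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import run_stringent_screen
from foldscreen.silac_screen import (
    DEFAULT_COLUMNS,
    call_interactors_flexible,
    call_interactors_stringent,
    enrichment_value,
    pair_orientations,
    parse_protein_groups,
    plan_screen,
    pulsed_silac_compare,
    qc_control_binders,
)
from foldscreen.synthetic_data import SimConfig, evaluate_calls, simulate_screen


def mq_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            DEFAULT_COLUMNS["id"],
            DEFAULT_COLUMNS["ratio"],
            DEFAULT_COLUMNS["ratio_count"],
            DEFAULT_COLUMNS["contaminant"],
            DEFAULT_COLUMNS["reverse"],
        ],
    )


class TestParse:
    def test_contaminant_and_decoy_rows_removed(self):
        table = mq_table(
            [["A", 2.0, 5, "+", ""], ["B", 2.0, 5, "", "+"], ["C", 2.0, 5, "", ""]]
        )
        out = parse_protein_groups(table, "forward")
        assert [m.protein_id for m in out] == ["C"]

    def test_low_ratio_count_dropped(self):
        table = mq_table([["A", 2.0, 1, "", ""], ["B", 2.0, 2, "", ""]])
        out = parse_protein_groups(table, "forward")
        assert [m.protein_id for m in out] == ["B"]

    def test_reverse_orientation_negated(self):
        table = mq_table([["A", 2.0 ** -1.5, 5, "", ""]])
        (m,) = parse_protein_groups(table, "reverse")
        assert m.log2_ratio == pytest.approx(1.5)

    def test_unparseable_ratio_dropped_with_warning(self):
        table = mq_table([["A", "NaN", 5, "", ""], ["B", 4.0, 5, "", ""]])
        with pytest.warns(UserWarning, match="dropped 1"):
            out = parse_protein_groups(table, "forward")
        assert [m.protein_id for m in out] == ["B"]

    def test_missing_column_fatal(self):
        with pytest.raises(KeyError):
            parse_protein_groups(pd.DataFrame({"x": [1]}), "forward")


class TestEnrichmentValue:
    @pytest.mark.parametrize(
        "fwd,rev,expected",
        [(1, 1, 0.5), (3, 4, math.log2(5)), (4, 3, math.log2(5))],
    )
    def test_closed_forms(self, fwd, rev, expected):
        assert enrichment_value(fwd, rev) == pytest.approx(expected)

    def test_origin_reported_missing(self):
        assert math.isnan(enrichment_value(0.0, 0.0))

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=100)
    def test_symmetric_in_arguments(self, a, b):
        if a == 0 and b == 0:
            return
        assert enrichment_value(a, b) == pytest.approx(enrichment_value(b, a))


def pairs_frame(points):
    return pd.DataFrame(
        [{"protein_id": p, "fwd": f, "rev": r} for p, (f, r) in points.items()]
    )


class TestStringentCaller:
    @pytest.mark.parametrize(
        "fwd,rev,called",
        [(1.5, 1.2, True), (1.5, 0.8, False), (1.0, 2.0, False), (2.0, 1.0, False)],
    )
    def test_both_orientations_strictly_above_cutoff(self, fwd, rev, called):
        (rec,) = call_interactors_stringent(pairs_frame({"A": (fwd, rev)}))
        assert rec.called is called

    def test_single_orientation_never_called(self):
        fwd = parse_protein_groups(mq_table([["A", 8.0, 5, "", ""]]), "forward")
        rev = parse_protein_groups(mq_table([["B", 0.1, 5, "", ""]]), "reverse")
        pairs = pair_orientations(fwd, rev)
        assert pairs.empty
        assert set(pairs.attrs["single_orientation"]) == {"A", "B"}

    def test_matches_bruteforce_on_small_instance(self):
        rng = np.random.default_rng(0)
        points = {f"P{i}": (rng.normal(1, 1), rng.normal(1, 1)) for i in range(50)}
        records = call_interactors_stringent(pairs_frame(points))
        expected = {p for p, (f, r) in points.items() if f > 1 and r > 1}
        assert {r.protein_id for r in records if r.called} == expected

    @given(
        st.dictionaries(
            st.text(alphabet="ABCDEFGH", min_size=1, max_size=3),
            st.tuples(st.floats(-4, 4), st.floats(-4, 4)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100)
    def test_label_swap_symmetry_and_monotonicity(self, points):
        base = {r.protein_id for r in call_interactors_stringent(pairs_frame(points)) if r.called}
        swapped_pts = {p: (r, f) for p, (f, r) in points.items()}
        swapped = {
            r.protein_id
            for r in call_interactors_stringent(pairs_frame(swapped_pts))
            if r.called
        }
        assert base == swapped
        raised_pts = {p: (f + 0.5, r + 0.5) for p, (f, r) in points.items()}
        raised = {
            r.protein_id
            for r in call_interactors_stringent(pairs_frame(raised_pts))
            if r.called
        }
        assert base <= raised


class TestFlexibleCaller:
    def test_distance_beyond_puf3_called(self):
        (rec,) = call_interactors_flexible(pairs_frame({"A": (2, 2)}), (-1, -1))
        assert rec.called

    def test_distance_below_puf3_not_called(self):
        (rec,) = call_interactors_flexible(pairs_frame({"A": (0.5, 0.5)}), (-1, -1))
        assert not rec.called

    def test_control_side_quadrant_never_called(self):
        (rec,) = call_interactors_flexible(pairs_frame({"A": (-3, -3)}), (-1, -1))
        assert not rec.called

    def test_missing_puf3_instructs_fallback(self):
        with pytest.raises(ValueError, match="stringent"):
            call_interactors_flexible(pairs_frame({"A": (2, 2)}), None)


class TestQc:
    def test_planted_control_passes_everywhere(self):
        exps = {f"e{i}": pairs_frame({"Puf3": (-2, -2)}) for i in range(5)}
        report = qc_control_binders(exps)
        puf3 = report.set_index("control").loc["Puf3"]
        assert puf3["pass_fraction"] == 1.0
        assert report.attrs["flagged_experiments"] == []

    def test_failing_experiment_flagged(self):
        exps = {"ok": pairs_frame({"Puf3": (-2, -2)}), "bad": pairs_frame({"Puf3": (0, 0)})}
        report = qc_control_binders(exps)
        assert report.attrs["flagged_experiments"] == ["bad"]

    def test_empty_control_list(self):
        report = qc_control_binders({"e": pairs_frame({"Puf3": (-2, -2)})}, controls=())
        assert report.empty


class TestPlanScreen:
    def test_full_screen_pulldown_count(self):
        assert plan_screen(186).total_pulldowns == 744

    def test_single_fold(self):
        assert plan_screen(1).total_pulldowns == 4

    def test_zero_folds_rejected(self):
        with pytest.raises(ValueError):
            plan_screen(0)


class TestPulsedSilac:
    def test_normal_sample_upper_tail_fraction(self):
        # oracle: normal mass beyond Q3 + 1.5*IQR is ~0.35% (one-sided)
        rng = np.random.default_rng(123)
        vals = {f"P{i}": v for i, v in enumerate(rng.normal(size=20000))}
        records = pulsed_silac_compare(vals)
        frac = np.mean([r.flagged_up for r in records])
        assert 0.001 < frac < 0.015

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(1)
        vals = {f"P{i}": v for i, v in enumerate(rng.normal(0, 0.3, 200))}
        vals["HIT"] = 5.0
        flags = {r.protein_id for r in pulsed_silac_compare(vals) if r.flagged_up}
        assert "HIT" in flags

    def test_constant_distribution_no_flags(self):
        with pytest.warns(UserWarning, match="degenerate"):
            records = pulsed_silac_compare({f"P{i}": 1.0 for i in range(10)})
        assert not any(r.flagged_up for r in records)


class TestPlantedRecovery:
    def test_noiseless_screen_recovered_exactly(self):
        cfg = SimConfig(background_sd=1e-9, missing_rate=0.0, seed=3)
        tables, truth = simulate_screen(cfg)
        called, _ = run_stringent_screen(tables)
        assert called == truth.planted_binders

    def test_default_conditions_sensitive_and_specific(self):
        cfg = SimConfig(seed=9)
        tables, truth = simulate_screen(cfg)
        called, evaluable = run_stringent_screen(tables)
        metrics = evaluate_calls(truth, called, evaluable)
        assert metrics["sensitivity"] >= 0.9
        assert metrics["fdp"] <= 0.1

    def test_same_seed_reproducible(self):
        t1, _ = simulate_screen(SimConfig(seed=5))
        t2, _ = simulate_screen(SimConfig(seed=5))
        for fold in t1:
            for orient in ("forward", "reverse"):
                pd.testing.assert_frame_equal(t1[fold][orient], t2[fold][orient])
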