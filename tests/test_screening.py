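"""Well aggregation, standard curves, hit calling and synergy scoring."""

import numpy as np
import pandas as pd
import pytest

from yapscreen import (
    call_hits,
    density_standard_curve,
    generate_screen,
    summarize_wells,
    synergy_score,
)
from yapscreen.screening import score_screen

from conftest import make_screen_spec


def _well_summaries(rows):
    return pd.DataFrame(rows)


def _ctrl_rows(n=12, sd_seed=0, diff_sd=0.03, total_mean=1e6, total_sd=5e4):
    rng = np.random.default_rng(sd_seed)
    diffs = rng.normal(0.0, diff_sd, n)
    diffs = (diffs - diffs.mean()) / diffs.std(ddof=1) * diff_sd  # exact SD
    return [
        dict(
            well_id=f"C{i}", plate_id="P1", treatment="mock", replicate_index=i,
            is_control=True, n_cells=500,
            mean_yap_diff=float(diffs[i]), mean_yap_total=float(
                total_mean + rng.normal(0, total_sd)
            ),
        )
        for i in range(n)
    ]


def _target_rows(name, diffs, totals=None, n_cells=500):
    totals = totals if totals is not None else [1e6] * len(diffs)
    return [
        dict(
            well_id=f"{name}_{i}", plate_id="P1", treatment=name, replicate_index=i,
            is_control=False, n_cells=n_cells,
            mean_yap_diff=float(d), mean_yap_total=float(t),
        )
        for i, (d, t) in enumerate(zip(diffs, totals))
    ]


class TestSummarizeWells:
    def test_identical_cells_give_their_value(self):
        records = pd.DataFrame(
            dict(
                well_id=["A1"] * 4, yap_ratio=[0.2] * 4, yap_diff=[0.05] * 4,
                yap_pred=[0.15] * 4, yap_total=[1e5] * 4, NF=[0.4] * 4,
                LCD=[20.0] * 4, cellA=[3000.0] * 4, qc_flags=[""] * 4,
            )
        )
        layout = pd.DataFrame(
            dict(plate=["P1"], well=["A1"], treatment=["t"], replicate=[0],
                 is_control=[False])
        )
        s = summarize_wells(records, layout)
        assert s.loc[0, "n_cells"] == 4
        assert s.loc[0, "mean_yap_diff"] == 0.05
        assert s.loc[0, "mean_cellA"] == 3000.0

    def test_empty_well_has_absent_means(self):
        records = pd.DataFrame(
            dict(well_id=["A1"], yap_ratio=[0.1], qc_flags=[""])
        )
        layout = pd.DataFrame(
            dict(plate=["P1", "P1"], well=["A1", "B2"], treatment=["t", "u"],
                 replicate=[0, 0], is_control=[False, False])
        )
        s = summarize_wells(records, layout).set_index("well_id")
        assert s.loc["B2", "n_cells"] == 0
        assert np.isnan(s.loc["B2", "mean_yap_ratio"])

    def test_orphan_wells_rejected(self):
        records = pd.DataFrame(dict(well_id=["Z9"], yap_ratio=[0.1], qc_flags=[""]))
        layout = pd.DataFrame(
            dict(plate=["P1"], well=["A1"], treatment=["t"], replicate=[0],
                 is_control=[False])
        )
        with pytest.raises(ValueError, match="Z9"):
            summarize_wells(records, layout)

    def test_qc_flagged_cells_excluded_from_means(self):
        records = pd.DataFrame(
            dict(
                well_id=["A1"] * 3, yap_ratio=[0.1, 0.1, 9.9],
                qc_flags=["", "", "mitotic"],
            )
        )
        layout = pd.DataFrame(
            dict(plate=["P1"], well=["A1"], treatment=["t"], replicate=[0],
                 is_control=[False])
        )
        s = summarize_wells(records, layout)
        assert s.loc[0, "n_cells"] == 2
        assert s.loc[0, "mean_yap_ratio"] == pytest.approx(0.1)

    def test_control_screen_grand_mean_diff_near_zero(self):
        ds = generate_screen(make_screen_spec(seed=14))
        _, summaries, _ = score_screen(
            ds.cells, ds.layout, replicate_rule=ds.replicate_rule
        )
        # training wells: OLS residuals average zero over cells, so the
        # cell-weighted well means stay near zero
        grand = np.average(
            summaries["mean_yap_diff"], weights=summaries["n_cells"]
        )
        assert abs(grand) < 1e-10


class TestStandardCurve:
    def test_exactly_log_linear_controls_normalize_to_zero(self):
        n = np.geomspace(100, 400, 8).astype(int)
        rows = [
            dict(well_id=f"C{i}", treatment="mock", is_control=True,
                 n_cells=int(v), mean_cellA=5000.0 - 800.0 * np.log(v))
            for i, v in enumerate(n)
        ]
        s = _well_summaries(rows)
        curve = density_standard_curve("mean_cellA", s)
        np.testing.assert_allclose(curve.normalize(s), 0.0, atol=1e-9)

    def test_well_on_the_curve_normalizes_to_zero(self):
        n = np.geomspace(100, 400, 8).astype(int)
        s = _well_summaries(
            [
                dict(n_cells=int(v), mean_cellA=5000.0 - 800.0 * np.log(v))
                for v in n
            ]
        )
        curve = density_standard_curve("mean_cellA", s)
        kd = pd.DataFrame([dict(n_cells=200, mean_cellA=5000.0 - 800.0 * np.log(200))])
        assert curve.normalize(kd).iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_additive_shape_shift_recovered(self):
        n = np.geomspace(100, 400, 10).astype(int)
        s = _well_summaries(
            [dict(n_cells=int(v), mean_cellA=5000.0 - 800.0 * np.log(v)) for v in n]
        )
        curve = density_standard_curve("mean_cellA", s)
        kd = pd.DataFrame(
            [dict(n_cells=250, mean_cellA=5000.0 - 800.0 * np.log(250) + 500.0)]
        )
        assert curve.normalize(kd).iloc[0] == pytest.approx(500.0, abs=1e-6)

    def test_narrow_density_span_warns(self):
        s = _well_summaries(
            [dict(n_cells=300 + i, mean_cellA=3000.0 + i) for i in range(6)]
        )
        with pytest.warns(UserWarning, match="2-fold"):
            density_standard_curve("mean_cellA", s)


class TestCallHits:
    def test_two_sd_of_controls_sets_threshold(self):
        ctrl = _well_summaries(_ctrl_rows(diff_sd=0.03))
        calls = call_hits(
            pd.concat(
                [ctrl, _well_summaries(_target_rows("t1", [0.0, 0.0]))],
                ignore_index=True,
            ),
            replicate_rule="2of2",
        )
        assert calls.loc[0, "threshold_used"] == pytest.approx(0.06, abs=1e-12)

    def test_direct_activator_called_on_both_replicates(self):
        rows = _ctrl_rows(diff_sd=0.03) + _target_rows("act", [-0.1, -0.11])
        calls = call_hits(_well_summaries(rows), replicate_rule="2of2").set_index("target")
        assert calls.loc["act", "direction"] == "activator_candidate"
        assert calls.loc["act", "wells_passing"] == 2

    def test_single_outlier_well_insufficient(self):
        rows = _ctrl_rows(diff_sd=0.03) + _target_rows("weak", [-0.1, 0.0])
        calls = call_hits(_well_summaries(rows), replicate_rule="2of2").set_index("target")
        assert calls.loc["weak", "direction"] == "none"

    def test_three_of_four_rule(self):
        rows = _ctrl_rows(diff_sd=0.03) + _target_rows("inh", [0.1, 0.12, 0.09, 0.0])
        calls = call_hits(_well_summaries(rows), replicate_rule="3of4").set_index("target")
        assert calls.loc["inh", "direction"] == "inhibitor_candidate"
        assert calls.loc["inh", "wells_passing"] == 3

    def test_tie_at_threshold_is_not_a_hit(self):
        ctrl = _well_summaries(_ctrl_rows(diff_sd=0.03))
        rows = _target_rows("edge", [0.06, 0.06])
        calls = call_hits(
            pd.concat([ctrl, _well_summaries(rows)], ignore_index=True),
            replicate_rule="2of2",
        ).set_index("target")
        assert calls.loc["edge", "direction"] == "none"

    def test_low_total_gate_blocks_activator_calls(self):
        ctrl = _ctrl_rows(diff_sd=0.03)
        low_total = 1e6 - 10 * 5e4  # far below the -2 SD gate
        rows = ctrl + _target_rows("deg", [-0.2, -0.2], totals=[low_total] * 2)
        calls = call_hits(_well_summaries(rows), replicate_rule="2of2").set_index("target")
        assert calls.loc["deg", "direction"] == "none"
        assert calls.loc["deg", "intensity_gate"] == "low_total_excluded"

    def test_high_total_gate_blocks_inhibitor_calls(self):
        ctrl = _ctrl_rows(diff_sd=0.03)
        rows = ctrl + _target_rows("amp", [0.2, 0.2], totals=[1e6 + 10 * 5e4] * 2)
        calls = call_hits(_well_summaries(rows), replicate_rule="2of2").set_index("target")
        assert calls.loc["amp", "direction"] == "none"
        assert calls.loc["amp", "intensity_gate"] == "high_total_excluded"

    def test_gates_are_directional_not_global(self):
        # a low-total well can still support an inhibitor call
        ctrl = _ctrl_rows(diff_sd=0.03)
        rows = ctrl + _target_rows("inh", [0.2, 0.2], totals=[1e6 - 10 * 5e4] * 2)
        calls = call_hits(_well_summaries(rows), replicate_rule="2of2").set_index("target")
        assert calls.loc["inh", "direction"] == "inhibitor_candidate"

    def test_unknown_replicate_rule_rejected(self):
        with pytest.raises(ValueError, match="replicate_rule"):
            call_hits(_well_summaries(_ctrl_rows()), replicate_rule="4of5")

    def test_null_indirect_target_not_called(self):
        spec = make_screen_spec(
            seed=23,
            targets=[dict(name="shape_only", feature_means={"cellA": 1800.0})],
        )
        ds = generate_screen(spec)
        _, _, calls = score_screen(ds.cells, ds.layout, replicate_rule="2of2")
        assert calls.set_index("target").loc["shape_only", "direction"] == "none"

    def test_direct_delta_called_in_right_direction(self):
        spec = make_screen_spec(
            seed=24,
            targets=[
                dict(name="act", delta=-0.1),
                dict(name="inh", delta=0.1),
            ],
        )
        ds = generate_screen(spec)
        _, _, calls = score_screen(ds.cells, ds.layout, replicate_rule="2of2")
        c = calls.set_index("target")
        assert c.loc["act", "direction"] == "activator_candidate"
        assert c.loc["inh", "direction"] == "inhibitor_candidate"


class TestDetectionMonotonicity:
    def test_detection_rate_never_decreases_with_effect_size(self):
        """Larger direct offsets cannot become harder to detect.

        Small wells (100 cells) keep the threshold high enough that the
        weakest offsets are genuinely borderline.
        """
        deltas = (0.0, 0.02, 0.05, 0.15)
        rates = []
        for delta in deltas:
            hits = 0
            for seed in range(10):
                spec = make_screen_spec(
                    seed=300 + seed,
                    targets=[dict(name="t", delta=delta, density=100.0)],
                    control_densities=tuple(np.geomspace(50, 200, 12)),
                )
                ds = generate_screen(spec)
                _, _, calls = score_screen(ds.cells, ds.layout, replicate_rule="2of2")
                direction = calls.set_index("target").loc["t", "direction"]
                hits += int(direction == "inhibitor_candidate")
            rates.append(hits / 10)
        # allow one-seed wobble between adjacent grid points
        for lo, hi in zip(rates, rates[1:]):
            assert hi >= lo - 0.1
        assert rates[-1] >= 0.9


class TestSynergy:
    def _paired_summaries(self, effects, n_cells):
        dmso, drug = [], []
        for i, (target, eff, n) in enumerate(effects):
            dmso.extend(_target_rows(target, [0.0, 0.0], n_cells=n))
            drug.extend(_target_rows(target, [eff, eff], n_cells=n))
        return _well_summaries(dmso), _well_summaries(drug)

    def test_on_line_target_scores_zero_and_wt_mean_zero(self):
        # wild-type drug effect is linear in cell number
        wt = [(f"wt{i}", -0.02 - 1e-4 * n, n) for i, n in enumerate((200, 400, 600, 800))]
        probe = [("probe", -0.02 - 1e-4 * 500, 500)]
        dmso, drug = self._paired_summaries(wt + probe, None)
        table = synergy_score(dmso, drug, [t for t, _, _ in wt]).set_index("target")
        assert table.loc["probe", "synergy"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc[[t for t, _, _ in wt], "synergy"].mean() == pytest.approx(
            0.0, abs=1e-9
        )

    def test_injected_extra_effect_recovered(self):
        wt = [(f"wt{i}", -0.02 - 1e-4 * n, n) for i, n in enumerate((200, 400, 600, 800))]
        hit = [("bpix", -0.02 - 1e-4 * 500 - 0.05, 500)]
        dmso, drug = self._paired_summaries(wt + hit, None)
        table = synergy_score(dmso, drug, [t for t, _, _ in wt]).set_index("target")
        assert table.loc["bpix", "synergy"] == pytest.approx(-0.05, abs=1e-9)

    def test_missing_vehicle_partner_skipped_with_warning(self):
        wt = [(f"wt{i}", -0.02, n) for i, n in enumerate((200, 400, 600))]
        dmso, drug = self._paired_summaries(wt, None)
        drug = pd.concat(
            [drug, _well_summaries(_target_rows("orphan", [0.1, 0.1]))],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="orphan"):
            table = synergy_score(dmso, drug, [t for t, _, _ in wt])
        assert "orphan" not in set(table["target"])

    def test_too_few_wildtype_pairs_rejected(self):
        wt = [("wt0", -0.02, 300), ("wt1", -0.03, 500)]
        dmso, drug = self._paired_summaries(wt, None)
        with pytest.raises(ValueError, match="wild-type"):
            synergy_score(dmso, drug, ["wt0", "wt1"])
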