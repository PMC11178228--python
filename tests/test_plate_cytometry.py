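"""Plate simulation, hierarchical gating, well summaries, hit calling."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from splicescreen.cytometry import (
    GateConfig,
    call_hits,
    correct_autofluorescence,
    gate_events,
    summarize_well,
)
from splicescreen.simulate import CytometrySimParams, default_plate_layout, simulate_plate


def _layout(entries):
    return pd.DataFrame(entries, columns=["well", "strain", "reporter", "role"])


def _events(rows):
    return pd.DataFrame(rows, columns=["FSC-A", "FSC-H", "SSC-A", "FITC-A", "PETexasRed-A"])


class TestPlateSimulation:
    def test_zero_coupling_zero_autofluor_gives_zero_yfp(self):
        params = CytometrySimParams(
            n_events_per_well=200,
            autofluor_yfp_mu=0.0,
            autofluor_yfp_sigma=0.0,
            reporter_se_map={("s1", "dmut"): 0.0},
        )
        tables = simulate_plate(_layout([("A1", "s1", "dmut", "sample")]), params, seed=1)
        assert (tables["A1"]["FITC-A"] == 0).all()

    def test_corrected_ratio_scales_with_true_se(self):
        params = CytometrySimParams(
            n_events_per_well=15_000,
            noise_cv=0.02,
            reporter_se_map={("hi", "dmut"): 1.0, ("lo", "dmut"): 0.5},
        )
        layout = _layout(
            [
                ("A1", "hi", "dmut", "sample"),
                ("A2", "lo", "dmut", "sample"),
                ("H12", "WT", "none", "autofluor_control"),
            ]
        )
        tables = simulate_plate(layout, params, seed=8)
        gates = GateConfig().resolve(tables["A1"])
        wells = [
            summarize_well(gate_events(tables[w], gates), {"well": w, "strain": w}, 1000)
            for w in ("A1", "A2")
        ]
        ctrl = summarize_well(gate_events(tables["H12"], gates), {"well": "H12"}, 1000)
        hi, lo = correct_autofluorescence(wells, ctrl)
        assert abs(hi.ratio / lo.ratio - 2.0) < 0.1

    def test_same_seed_identical_tables_and_unknown_strain_rejected(self):
        params = CytometrySimParams(
            n_events_per_well=100, reporter_se_map={("s1", "dmut"): 0.5}
        )
        layout = _layout([("A1", "s1", "dmut", "sample")])
        t1 = simulate_plate(layout, params, seed=3)
        t2 = simulate_plate(layout, params, seed=3)
        pd.testing.assert_frame_equal(t1["A1"], t2["A1"])
        with pytest.raises(KeyError):
            simulate_plate(_layout([("A1", "sX", "dmut", "sample")]), params, seed=3)

    def test_default_layout_places_controls(self):
        layout = default_plate_layout(["a", "b"], n_replicate_wells=3)
        assert set(layout.loc[layout["role"] == "autofluor_control", "well"]) == {
            "H2", "H3", "H12",
        }
        assert (layout["role"] == "sample").sum() == 6


class TestGating:
    BOUNDS = GateConfig(
        scatter_bounds=((50.0, 150.0), (10.0, 90.0)),
        singlet_slope=1.0,
        singlet_tol=0.25,
    )

    def test_empty_table_passes_through(self):
        out = gate_events(_events([]), self.BOUNDS)
        assert out.empty

    def test_full_range_gate_is_identity(self):
        events = _events([(100, 100, 50, 5, 5), (120, 118, 60, 2, 3)])
        wide = GateConfig(
            scatter_bounds=((-1e9, 1e9), (-1e9, 1e9)), singlet_slope=1.0, singlet_tol=1e9
        )
        pd.testing.assert_frame_equal(gate_events(events, wide), events)

    def test_manual_membership_of_hand_written_events(self):
        # six events against explicit rectangular bounds: four in-bounds
        events = _events(
            [
                (100, 100, 50, 1, 1),   # in
                (149, 140, 89, 1, 1),   # in
                (151, 151, 50, 1, 1),   # out: FSC-A above bound
                (100, 100, 95, 1, 1),   # out: SSC-A above bound
                (60, 58, 30, 1, 1),     # in
                (51, 52, 11, 1, 1),     # in
            ]
        )
        out = gate_events(events, self.BOUNDS)
        assert list(out.index) == [0, 1, 4, 5]

    def test_singlet_band_rejects_doublets(self):
        events = _events([(100, 100, 50, 1, 1), (100, 60, 50, 1, 1)])
        out = gate_events(events, self.BOUNDS)
        assert list(out.index) == [0]

    def test_resolved_gate_is_idempotent(self):
        rng = np.random.default_rng(0)
        events = _events(
            np.column_stack(
                [
                    rng.normal(100, 10, 500),
                    rng.normal(100, 10, 500),
                    rng.normal(50, 5, 500),
                    rng.random(500),
                    rng.random(500),
                ]
            )
        )
        cfg = GateConfig().resolve(events)
        once = gate_events(events, cfg)
        twice = gate_events(once, cfg)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_channel_is_input_error(self):
        with pytest.raises(ValueError, match="channel"):
            gate_events(pd.DataFrame({"FSC-A": [1.0]}), self.BOUNDS)


class TestWellSummary:
    def test_qc_threshold_at_exactly_1000_events(self):
        base = {"FSC-A": 1.0, "FSC-H": 1.0, "SSC-A": 1.0, "FITC-A": 2.0, "PETexasRed-A": 1.0}
        df999 = pd.DataFrame([base] * 999)
        df1000 = pd.DataFrame([base] * 1000)
        assert not summarize_well(df999, {}).qc_pass
        assert summarize_well(df1000, {}).qc_pass

    def test_singleton_and_sorted_oracle_medians(self):
        one = _events([(1, 1, 1, 7.0, 3.0)])
        s = summarize_well(one, {}, min_events=1)
        assert (s.median_yfp, s.median_red) == (7.0, 3.0)
        reds = [1.0, 9.0, 2.0, 8.0, 5.0]
        five = _events([(1, 1, 1, 0.0, r) for r in reds])
        assert summarize_well(five, {}, min_events=1).median_red == sorted(reds)[2]

    def test_zero_events_gives_na_summary(self):
        s = summarize_well(_events([]), {"well": "A1"})
        assert s.n_gated == 0 and not s.qc_pass
        assert math.isnan(s.median_yfp) and math.isnan(s.ratio)


class TestAutofluorescenceCorrection:
    @staticmethod
    def _well(yfp, red, n=2000):
        df = _events([(1, 1, 1, yfp, red)] * n)
        return summarize_well(df, {"well": "w"}, min_events=1000)

    def test_zero_control_is_identity_on_red(self):
        wells = [self._well(800.0, 500.0)]
        ctrl = self._well(0.0, 0.0)
        (out,) = correct_autofluorescence(wells, ctrl)
        assert out.corrected_red == 500.0

    def test_direct_arithmetic(self):
        (out,) = correct_autofluorescence([self._well(800.0, 500.0)], self._well(0.0, 100.0))
        assert out.corrected_red == 400.0 and out.ratio == 2.0

    def test_control_equal_red_gives_na_ratio(self):
        (out,) = correct_autofluorescence([self._well(800.0, 100.0)], self._well(0.0, 100.0))
        assert out.corrected_red == 0.0 and math.isnan(out.ratio)

    def test_failing_control_raises_naming_the_well(self):
        bad = summarize_well(_events([(1, 1, 1, 0.0, 1.0)] * 10), {"well": "H12"})
        with pytest.raises(ValueError, match="H12"):
            correct_autofluorescence([self._well(1.0, 1.0)], bad)

    def test_both_channels_option_subtracts_yfp_too(self):
        (out,) = correct_autofluorescence(
            [self._well(800.0, 500.0)], self._well(50.0, 100.0), channels="both"
        )
        assert out.median_yfp == 750.0 and out.ratio == 750.0 / 400.0


class TestHitCalling:
    def test_no_effect_strain_is_not_significant(self):
        ratios = pd.DataFrame(
            {"strain": ["a"] * 3 + ["ref"] * 3, "ratio": [2.0] * 6}
        )
        res = call_hits(ratios, "ref")
        row = res[res["strain"] == "a"].iloc[0]
        assert row["log2fc"] == 0.0 and not row["significant"]

    def test_welch_t_matches_textbook_formula(self, toy_ratio_table):
        res = call_hits(toy_ratio_table, "ref")
        row = res[res["strain"] == "mut"].iloc[0]
        a = np.array([1.0, 1.1, 0.9])
        b = np.array([2.0, 2.1, 1.9])
        se2 = a.var(ddof=1) / 3 + b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2
        )
        p = 2 * sstats.t.sf(abs(t), df)
        assert row["p_value"] == pytest.approx(p, rel=1e-9)
        assert row["log2fc"] == pytest.approx(np.log2(1.0 / 2.0), rel=1e-9)

    def test_single_replicate_gets_na_p_and_never_significant(self):
        ratios = pd.DataFrame(
            {"strain": ["solo"] + ["ref"] * 3, "ratio": [0.1, 2.0, 2.1, 1.9]}
        )
        res = call_hits(ratios, "ref")
        row = res[res["strain"] == "solo"].iloc[0]
        assert math.isnan(row["p_value"]) and not row["significant"]

    def test_reference_needs_two_replicates(self):
        ratios = pd.DataFrame({"strain": ["a", "ref"], "ratio": [1.0, 1.0]})
        with pytest.raises(ValueError, match="reference"):
            call_hits(ratios, "ref")

    def test_bh_option_reduces_hits_under_null(self):
        rng = np.random.default_rng(12)
        strains = [f"s{k}" for k in range(30)]
        rows = [("ref", r) for r in rng.normal(1, 0.05, 4)]
        for s in strains:
            rows += [(s, r) for r in rng.normal(1, 0.05, 3)]
        ratios = pd.DataFrame(rows, columns=["strain", "ratio"])
        raw = call_hits(ratios, "ref", bh_correct=False)
        adj = call_hits(ratios, "ref", bh_correct=True)
        assert adj["significant"].sum() <= raw["significant"].sum()
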