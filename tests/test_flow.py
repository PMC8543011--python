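"""Gating, reactivity definitions, combination profiling and paired tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tilreact import flow, synthetic
from tilreact.flow import ConfigurationError

from conftest import random_positivity


def _event_table(data, condition="alone", inhibitor="none", sample_id="S"):
    for ch in flow.ALL_CHANNELS:
        data.setdefault(ch, np.zeros(len(next(iter(data.values())))))
    return flow.EventTable(pd.DataFrame(data), sample_id, condition, inhibitor)


class TestThresholds:
    def test_quantile_bounds_control_positivity(self):
        rng = np.random.default_rng(0)
        table = _event_table({flow.TNF: rng.normal(0, 1, 1000)})
        thr = flow.set_thresholds(table, quantile=0.999)
        pos_rate = (table.data[flow.TNF] > thr.cutoffs[flow.TNF]).mean()
        assert pos_rate <= 0.001

    def test_median_quantile_rejected(self):
        # quantile must exceed 0.5: a median cut calls half the control positive
        table = _event_table({flow.TNF: np.random.default_rng(0).normal(0, 1, 200)})
        with pytest.raises(ConfigurationError):
            flow.set_thresholds(table, quantile=0.5)

    def test_sensitivity_exceeds_component_overlap_bound(self, small_flow_dataset):
        """Gate sensitivity on true positives matches the analytic overlap
        of the positive intensity component above the realized cutoff."""
        config, tables, truth = small_flow_dataset
        thr = flow.set_thresholds(tables[("alone", "none")])
        stim = tables[("autologous", "none")]
        labels = truth.labels[("autologous", "none")]
        tnf_true = labels["class"].str.contains("TNF\\+").to_numpy()
        called = (stim.data[flow.TNF] > thr.cutoffs[flow.TNF]).to_numpy()
        sensitivity = called[tnf_true].mean()
        model = config.channel_params[flow.TNF]
        analytic = stats.norm.sf(thr.cutoffs[flow.TNF], model.pos_loc, model.pos_scale)
        n_true = tnf_true.sum()
        se = np.sqrt(analytic * (1 - analytic) / n_true)
        assert sensitivity >= analytic - 3 * se

    def test_empty_control_errors(self):
        table = _event_table({flow.TNF: np.zeros(1)})
        table.data = table.data.iloc[:0]
        with pytest.raises(ConfigurationError):
            flow.set_thresholds(table)


class TestPositivity:
    def test_boundary_is_strictly_greater(self):
        thr = flow.GateThresholds({ch: 1.0 for ch in flow.ACTIVATION_CHANNELS}, "c", 0.999)
        data = pd.DataFrame({ch: [1.0, 1.0 + 1e-9] for ch in flow.ACTIVATION_CHANNELS})
        pos = flow.call_positivity(data, thr)
        assert not pos.iloc[0].any()
        assert pos.iloc[1][list(flow.ACTIVATION_CHANNELS)].all()

    def test_total_cd137_is_or_of_forms(self):
        thr = flow.GateThresholds({ch: 1.0 for ch in flow.ACTIVATION_CHANNELS}, "c", 0.999)
        data = pd.DataFrame(
            {ch: [0.0, 0.0, 2.0, 2.0] for ch in flow.ACTIVATION_CHANNELS}
        )
        data[flow.S_CD137] = [2.0, 0.0, 2.0, 0.0]
        data[flow.IC_CD137] = [0.0, 2.0, 2.0, 0.0]
        pos = flow.call_positivity(data, thr)
        assert pos[flow.T_CD137].tolist() == [True, True, True, False]
        assert (pos[flow.T_CD137] == (pos[flow.S_CD137] | pos[flow.IC_CD137])).all()

    def test_missing_channel_named(self):
        thr = flow.GateThresholds({flow.TNF: 1.0}, "c", 0.999)
        with pytest.raises(flow.ChannelError, match="S_CD137"):
            flow.call_positivity(pd.DataFrame({flow.TNF: [0.0]}), thr)


class TestBackgroundSubtraction:
    @pytest.mark.parametrize(
        "stim, ctrl, expected",
        [(3.0, 1.0, 2.0), (1.0, 3.0, 0.01), (0.0, 0.0, 0.01), (100.0, 0.0, 100.0)],
    )
    def test_subtraction_with_floor(self, stim, ctrl, expected):
        assert flow.subtract_background(stim, ctrl) == expected

    def test_over_normalized_values_capped(self):
        assert flow.clamp_percent(104.0) == 100.0
        assert flow.clamp_percent(-5.0) == 0.01

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            flow.subtract_background(101.0, 0.0)
        with pytest.raises(ConfigurationError):
            flow.subtract_background(5.0, -1.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(derandomize=True, max_examples=100)
    def test_result_always_in_reporting_range(self, stim, ctrl):
        value = flow.clamp_percent(flow.subtract_background(stim, ctrl))
        assert 0.01 <= value <= 100.0


class TestReactivityMetrics:
    def test_cd107a_only_counts_as_antitumor_function(self):
        pos = random_positivity(np.random.default_rng(0), n=100, p=0.0)
        pos.loc[:29, flow.CD107A] = True
        ctrl = random_positivity(np.random.default_rng(1), n=100, p=0.0)
        res = flow.reactivity_metrics(pos, ctrl, "CD8")
        assert res.unions["AF"] == res.unions["TotalReactive"] == 30.0
        assert res.subtracted_unions["CD137"] == flow.PERCENT_FLOOR

    def test_fully_positive_sample_reports_100(self):
        pos = random_positivity(np.random.default_rng(0), n=50, p=0.0)
        pos.loc[:, :] = True
        ctrl = random_positivity(np.random.default_rng(1), n=50, p=0.0)
        res = flow.reactivity_metrics(pos, ctrl, "CD8")
        assert all(v == 100.0 for v in res.subtracted_unions.values())

    def test_union_monotonicity(self):
        pos = random_positivity(np.random.default_rng(2), n=2000, p=0.2)
        ctrl = random_positivity(np.random.default_rng(3), n=2000, p=0.0)
        res = flow.reactivity_metrics(pos, ctrl, "CD8")
        assert res.unions["TotalReactive"] >= res.unions["AF"]
        assert res.unions["TotalReactive"] >= res.unions["CD137"]
        for m in (flow.TNF, flow.IFNG, flow.CD107A):
            assert res.unions["AF"] >= res.markers[m]

    def test_total_reactive_recovers_truth_fraction(self, small_flow_dataset):
        """The estimated Total Reactive percentage matches the latent
        reactive fraction counted from truth labels (CD8, within 3x SE)."""
        _config, tables, truth = small_flow_dataset
        thr = flow.set_thresholds(tables[("alone", "none")])
        stim = flow.split_subsets(tables[("autologous", "none")], thr)
        ctrl = flow.split_subsets(tables[("alone", "none")], thr)
        pos = flow.call_positivity(stim["CD8"], thr)
        ctrl_pos = flow.call_positivity(ctrl["CD8"], thr)
        res = flow.reactivity_metrics(pos, ctrl_pos, "CD8")
        labels = truth.labels[("autologous", "none")]
        cd8 = labels[(labels["subset"] == "CD8") & labels["live"]]
        p_true = (cd8["n_positive"] > 0).mean()
        se = np.sqrt(p_true * (1 - p_true) / len(cd8))
        assert abs(res.subtracted_unions["TotalReactive"] / 100 - p_true) < 3 * se


class TestCombinationProfile:
    def test_seven_reactive_combinations(self, gated):
        _thr, pos, ctrl_pos = gated
        profile = flow.combination_profile(pos, ctrl_pos)
        assert len(profile.fractions) == 7
        assert "CD137-TNF-IFNG-" not in profile.fractions
        assert sum(profile.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(profile.grouping.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_populated_combination_takes_all_mass(self):
        pos = random_positivity(np.random.default_rng(0), n=100, p=0.0)
        pos.loc[:19, [flow.S_CD137, flow.T_CD137]] = True
        ctrl = random_positivity(np.random.default_rng(1), n=100, p=0.0)
        profile = flow.combination_profile(pos, ctrl)
        assert profile.fractions["CD137+TNF-IFNG-"] == 1.0
        assert all(
            v == 0.0 for k, v in profile.fractions.items() if k != "CD137+TNF-IFNG-"
        )

    def test_partition_counts_sum_to_events(self, gated):
        _thr, pos, _ = gated
        counts = flow.combination_counts(pos)
        assert counts.sum() == len(pos)
        assert len(counts) == 8

    def test_matches_per_event_loop(self):
        """Bit-mask combination assignment equals a per-event reference loop."""
        pos = random_positivity(np.random.default_rng(42), n=10_000, p=0.3)
        counts = flow.combination_counts(pos)
        expected = {label: 0 for label in counts.index}
        for _, row in pos.iterrows():
            state = tuple(bool(row[m]) for m in flow.COMBO_MARKERS)
            expected[flow.combo_label(state)] += 1
        assert dict(counts) == expected


class TestContributionOrder:
    def test_disjoint_marker_sets(self):
        pos = random_positivity(np.random.default_rng(0), n=100, p=0.0)
        pos.loc[0:39, [flow.IC_CD137, flow.T_CD137]] = True
        pos.loc[40:69, flow.TNF] = True
        pos.loc[70:89, flow.IFNG] = True
        pos.loc[90:99, flow.CD107A] = True
        dec = flow.contribution_order(pos)
        assert dec.order == (flow.T_CD137, flow.TNF, flow.IFNG, flow.CD107A)
        assert [round(dec.gains[m]) for m in dec.order] == [40, 30, 20, 10]

    def test_nested_sets_give_single_gain(self):
        pos = random_positivity(np.random.default_rng(0), n=100, p=0.0)
        pos.loc[0:49, [flow.IC_CD137, flow.T_CD137]] = True
        pos.loc[0:29, flow.TNF] = True
        pos.loc[0:9, flow.IFNG] = True
        dec = flow.contribution_order(pos)
        assert [round(dec.gains[m]) for m in dec.order] == [100, 0, 0, 0]

    def test_tie_break_uses_panel_order(self):
        pos = random_positivity(np.random.default_rng(0), n=10, p=0.0)
        pos.loc[0:4, flow.IFNG] = True
        pos.loc[5:9, flow.TNF] = True
        dec = flow.contribution_order(pos)
        assert dec.order.index(flow.TNF) < dec.order.index(flow.IFNG)

    def test_gains_match_exhaustive_set_cover(self):
        """Greedy incremental gains equal union sizes computed from
        exhaustive per-event set enumeration."""
        rng = np.random.default_rng(7)
        pos = random_positivity(rng, n=500, p=0.25)
        dec = flow.contribution_order(pos)
        events = [
            {m for m in flow.MARKER_PANEL if row[m]} for _, row in pos.iterrows()
        ]
        union_total = sum(1 for e in events if e)
        covered: set[str] = set()
        for m in dec.order:
            with_m = covered | {m}
            gain = sum(1 for e in events if e & with_m) - sum(
                1 for e in events if e & covered
            )
            assert dec.gains[m] == pytest.approx(100 * gain / union_total)
            covered = with_m
        assert sum(dec.gains.values()) == pytest.approx(100.0)


class TestInhibitorModulation:
    @pytest.mark.parametrize(
        "cond, ref, expected",
        [(10.0, 10.0, 0.0), (8.2, 10.0, -18.0), (20.9, 10.0, 109.0)],
    )
    def test_percent_modulation(self, cond, ref, expected):
        res = flow.inhibitor_modulation(cond, ref)
        assert res.percent_modulation == pytest.approx(expected)
        assert res.percent_modulation == pytest.approx((res.normalized - 1) * 100)

    def test_zero_reference_is_undefined(self):
        with pytest.raises(ConfigurationError):
            flow.inhibitor_modulation(5.0, 0.0)

    def test_simulated_inhibitors_shift_surface_into_intracellular(self):
        """BFA suppresses surface CD137 detection while intracellular
        detection rises and total CD137 is conserved."""
        config = synthetic.FlowSimConfig(n_events=20_000, seed=5)
        tables, _ = synthetic.generate_flow_events(
            config, conditions=("autologous", "alone"), inhibitors=("none", "BFA")
        )
        thr = flow.set_thresholds(tables[("alone", "none")])

        def pct(table, channel_or_derived):
            pos = flow.call_positivity(table, thr)
            return 100 * pos[channel_or_derived].mean()

        ref = tables[("autologous", "none")]
        bfa = tables[("autologous", "BFA")]
        surface = flow.inhibitor_modulation(pct(bfa, flow.S_CD137), pct(ref, flow.S_CD137))
        total = flow.inhibitor_modulation(pct(bfa, flow.T_CD137), pct(ref, flow.T_CD137))
        ic = flow.inhibitor_modulation(pct(bfa, flow.IC_CD137), pct(ref, flow.IC_CD137))
        assert surface.percent_modulation < -50
        assert ic.percent_modulation > 10
        assert abs(total.percent_modulation) < 10


class TestPairedWilcoxon:
    def test_identical_vectors_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert flow.paired_marker_test(a, a) == 1.0

    def test_constant_shift_n8_exact(self):
        """A constant positive shift over 8 pairs puts all signed ranks on
        one side: exact two-sided p = 2/2^8 = 0.0078125."""
        a = np.array([1.0, 2.5, 3.0, 4.7, 5.1, 6.0, 7.2, 8.9])
        assert flow.paired_marker_test(a, a + 1.0) == pytest.approx(0.0078125)

    def test_matches_sign_enumeration_oracle(self):
        """Exact p equals full enumeration of the 2^n sign assignments."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 11))
            a = rng.normal(size=n)
            b = a + rng.normal(0.4, 1.0, size=n)
            d = b - a
            if np.any(d == 0):
                continue
            ranks = stats.rankdata(np.abs(d))
            w = ranks[d > 0].sum()
            total = 0
            le = ge = 0
            for signs in itertools.product([0, 1], repeat=n):
                ws = sum(r for r, s in zip(ranks, signs) if s)
                total += 1
                le += ws <= w
                ge += ws >= w
            p_oracle = min(1.0, 2 * min(le / total, ge / total))
            assert flow.paired_marker_test(a, b) == pytest.approx(p_oracle)

    def test_short_vectors_rejected(self):
        with pytest.raises(ConfigurationError):
            flow.paired_marker_test([1, 2, 3], [2, 3, 4])
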