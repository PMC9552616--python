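"""Feature extraction: AUC, peaks, response fractions, rescaling, populations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from jakstat_memory import features
from jakstat_memory.model import single_pulse_protocol, two_pulse_protocol
from jakstat_memory.simulate import simulate


class TestAuc:
    def test_constant_series_at_baseline_is_zero(self):
        t = np.arange(0.0, 101.0, 5.0)
        assert features.auc(t, np.full_like(t, 7.0), baseline=7.0) == 0.0

    def test_linear_ramp_gives_triangle_area(self):
        t = np.arange(0.0, 101.0, 1.0)
        series = 3.0 + t
        assert features.auc(t, series, (0.0, 100.0), baseline=3.0) == pytest.approx(5000.0)

    def test_empty_or_unsupported_window_rejected(self):
        t = np.arange(0.0, 50.0, 5.0)
        with pytest.raises(ValueError):
            features.auc(t, t, (30.0, 30.0))
        with pytest.raises(ValueError):
            features.auc(t, t, (0.0, 500.0))

    def test_matches_fine_grid_quadrature_on_pulse_response(self, params):
        protocol = single_pulse_protocol("IFN-gamma", 100.0, horizon=600.0)
        coarse = simulate(params, protocol, dt_out=5.0)
        fine = simulate(params, protocol, dt_out=0.5)
        b = coarse.nuclear_stat1[0]
        a_coarse = features.auc(coarse.time, coarse.nuclear_stat1, baseline=b)
        a_fine = features.auc(fine.time, fine.nuclear_stat1, baseline=b)
        assert a_coarse == pytest.approx(a_fine, rel=5e-3)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1e5), min_size=5, max_size=40),
           st.floats(0.0, 1e4))
    def test_additive_over_adjacent_windows(self, values, baseline):
        t = np.arange(len(values), dtype=float) * 5.0
        series = np.asarray(values)
        mid = t[len(t) // 2]
        whole = features.auc(t, series, (t[0], t[-1]), baseline=baseline)
        left = features.auc(t, series, (t[0], mid), baseline=baseline)
        right = features.auc(t, series, (mid, t[-1]), baseline=baseline)
        assert whole == pytest.approx(left + right, rel=1e-9, abs=1e-6)


class TestPeaks:
    def test_flat_series_has_zero_amplitudes(self):
        t = np.arange(0.0, 800.0, 5.0)
        pk = features.peaks(t, np.full_like(t, 4.0), [0.0, 420.0])
        assert pk[0].amplitude == 0.0 and pk[1].amplitude == 0.0

    def test_ties_broken_by_earliest_time(self):
        t = np.arange(0.0, 100.0, 5.0)
        series = np.zeros_like(t)
        series[4] = series[8] = 10.0
        pk = features.peaks(t, series, [0.0])
        assert pk[0].time_to_peak == 20.0

    def test_requires_at_least_one_onset(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            features.peaks(t, t, [])

    def test_saturating_two_pulse_protocol_is_refractory(
        self, two_pulse_100_6h
    ):
        pk = features.peaks(two_pulse_100_6h.time, two_pulse_100_6h.nuclear_stat1,
                            [0.0, 420.0])
        assert pk[1].amplitude < 0.1 * pk[0].amplitude

    def test_low_dose_priming_halves_saturated_response(
        self, params, reference_peak
    ):
        traj = simulate(params, two_pulse_protocol("IFN-gamma", 1, "IFN-gamma", 100,
                                                   360.0))
        pk = features.peaks(traj.time, traj.nuclear_stat1, [0.0, 420.0])
        assert pk[1].amplitude == pytest.approx(0.5 * reference_peak,
                                                abs=0.1 * reference_peak)


class TestResponseFraction:
    def test_reference_maps_to_100_percent(self):
        assert features.response_fraction(3.0, 3.0) == 100.0
        assert features.response_fraction(0.0, 3.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            features.response_fraction(1.0, 0.0)

    def test_invariant_to_global_scaling(self):
        assert features.response_fraction(2.0, 8.0) == \
            features.response_fraction(2.0e4, 8.0e4)

    def test_subsaturating_dose_gives_partial_response(self, params, reference_peak):
        traj = simulate(params, single_pulse_protocol("IFN-gamma", 1.0, horizon=360.0))
        series = traj.nuclear_stat1
        frac = features.response_fraction(series.max() - series[0], reference_peak)
        assert 0.0 < frac < 100.0


class TestScaleExperimental:
    def test_identity_for_molecule_scale_data_with_zero_min(self, reference_pulse):
        df = reference_pulse.to_frame()
        nuc = df[df["channel"] == "nuclear_stat1"].copy()
        nuc["value"] -= nuc["value"].min()
        ref_max = nuc["value"].max()
        scaled, offset, factor = features.scale_experimental(nuc, ref_max)
        assert factor == pytest.approx(1.0)
        np.testing.assert_allclose(scaled["value"], nuc["value"], rtol=1e-12)

    def test_affine_transform_round_trip(self, reference_pulse):
        df = reference_pulse.to_frame()
        nuc = df[df["channel"] == "nuclear_stat1"].copy()
        molecules = nuc["value"].to_numpy()
        nuc["value"] = 3.7e-4 * molecules + 12.5
        sim_max = molecules.max() - molecules.min()
        scaled, offset, factor = features.scale_experimental(nuc, sim_max)
        recovered = scaled["value"].to_numpy()
        target = molecules - molecules.min()
        assert np.max(np.abs(recovered - target)) < 0.01 * target.max()

    def test_constant_dataset_rejected(self):
        df = pd.DataFrame({
            "cell_id": "c0", "protocol_id": "p", "time_min": [0.0, 5.0],
            "channel": "nuclear_stat1", "value": [4.0, 4.0],
        })
        with pytest.raises(ValueError):
            features.scale_experimental(df, 1.0)

    def test_joint_scaling_shares_one_factor(self, params, reference_pulse):
        # two protocols rescaled together must use a single gain
        other = simulate(params, two_pulse_protocol("IFN-gamma", 1, "IFN-gamma", 100,
                                                    360.0))
        df = pd.concat([
            reference_pulse.to_frame(cell_id="a"),
            other.to_frame(cell_id="b"),
        ])
        nuc = df[df["channel"] == "nuclear_stat1"].copy()
        nuc["value"] = 2e-4 * nuc["value"] + 3.0
        scaled, offset, factor = features.scale_experimental(nuc, 1.0)
        by_cell_max = scaled.groupby("cell_id")["value"].max()
        # cell b peaks lower than the reference cell; a shared factor
        # preserves their ratio
        ratio_raw = (nuc.groupby("cell_id")["value"].max() - offset)
        assert by_cell_max["b"] / by_cell_max["a"] == pytest.approx(
            ratio_raw["b"] / ratio_raw["a"], rel=1e-9
        )


class TestPopulationSummary:
    def _population(self, n, amp_factors, params, protocol, rng):
        frames = []
        traj = simulate(params, protocol)
        for i, s in enumerate(amp_factors):
            values = s * (traj.nuclear_stat1 - traj.nuclear_stat1[0]) \
                + traj.nuclear_stat1[0] + rng.normal(0, 1.0, traj.time.size)
            frames.append(pd.DataFrame({
                "cell_id": f"c{i}", "protocol_id": "two_pulse",
                "time_min": traj.time, "channel": "nuclear_stat1",
                "value": values,
            }))
        return pd.concat(frames, ignore_index=True)

    def test_identical_cells_report_undefined_correlations(
        self, params, two_pulse_100_6h
    ):
        traj = two_pulse_100_6h
        frames = [
            pd.DataFrame({"cell_id": f"c{i}", "protocol_id": "p",
                          "time_min": traj.time, "channel": "nuclear_stat1",
                          "value": traj.nuclear_stat1})
            for i in range(4)
        ]
        table, report = features.summarize_population(
            pd.concat(frames), [0.0, 420.0], reference_peak=1.0
        )
        assert report["correlations"]["p1_auc_vs_p2_auc"]["r"] is None

    def test_shared_amplitude_factor_couples_pulse_aucs(self, params):
        rng = np.random.default_rng(7)
        protocol = two_pulse_protocol("IFN-gamma", 1, "IFN-gamma", 100, 360.0)
        cells = self._population(30, rng.lognormal(0, 0.4, 30), params, protocol, rng)
        table, report = features.summarize_population(
            cells, [0.0, 420.0], reference_peak=1e5
        )
        assert report["correlations"]["p1_auc_vs_p2_auc"]["r"] > 0.5
        assert report["correlations"]["resting_vs_auc"]["n"] == 30

    def test_cells_with_missing_samples_are_excluded(self, params, two_pulse_100_6h):
        traj = two_pulse_100_6h
        frames = [
            pd.DataFrame({"cell_id": f"c{i}", "protocol_id": "p",
                          "time_min": traj.time, "channel": "nuclear_stat1",
                          "value": traj.nuclear_stat1 * (1 + 0.1 * i)})
            for i in range(4)
        ]
        frames.append(pd.DataFrame({
            "cell_id": "short", "protocol_id": "p",
            "time_min": traj.time[:10], "channel": "nuclear_stat1",
            "value": traj.nuclear_stat1[:10],
        }))
        table, report = features.summarize_population(
            pd.concat(frames), [0.0, 420.0], reference_peak=1e5
        )
        assert report["excluded_cells"] == ["short"]
        assert len(table) == 4

    def test_too_few_cells_rejected(self, two_pulse_100_6h):
        traj = two_pulse_100_6h
        df = pd.DataFrame({"cell_id": "only", "protocol_id": "p",
                           "time_min": traj.time, "channel": "nuclear_stat1",
                           "value": traj.nuclear_stat1})
        with pytest.raises(ValueError):
            features.summarize_population(df, [0.0], reference_peak=1.0)
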