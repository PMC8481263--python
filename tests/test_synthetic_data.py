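import numpy as np
import pytest

from pgsrange.range_prediction import silicon_peak_area
from pgsrange.silicon_detection import test_record as detect_record
from pgsrange.synthetic_data import (
    CampaignRun,
    PhantomGeometry,
    SpectrumModel,
    SpillStructure,
    expected_layer_spectrum,
    expected_raw_counts,
    make_campaign_table,
    silicon_signal_strength,
    simulate_event_stream,
    simulate_spectrum_record,
    simulate_trace,
)
from dataclasses import replace


class TestCampaignTable:
    def test_counts_and_flags(self, campaign_table):
        assert len(campaign_table) == 24
        n_main = sum(r.in_main for r in campaign_table)
        n_refval = sum(r.in_refval for r in campaign_table)
        assert (n_main, n_refval) == (23, 10)
        assert n_main + 2 * n_refval == 43

    def test_tabulated_rows(self, campaign_table):
        by_energy = {r.beam_energy: r for r in campaign_table}
        assert by_energy[105.43].d_end == 4.9
        assert by_energy[105.43].target_region == "ERB"
        assert by_energy[118.78].target_region == "handle"

    def test_dend_strictly_decreasing_with_energy(self, campaign_table):
        ordered = sorted(campaign_table, key=lambda r: r.beam_energy)
        dends = [r.d_end for r in ordered]
        assert all(a > b for a, b in zip(dends, dends[1:]))
        assert (min(dends), max(dends)) == (0.4, 7.4)


class TestSiliconSignalStrength:
    def test_zero_before_balloon_and_in_handle(self, geometry, runs_by_dend):
        for d in (7.4, 5.4, 4.9, 4.6, 2.9, 2.4, 0.4):
            assert silicon_signal_strength(runs_by_dend[d], geometry) == 0.0

    def test_linear_ramp_endpoints_and_midpoint(self, geometry):
        mid = CampaignRun(110.0, 4.0, "ERB", True, False)
        full = CampaignRun(115.55, 3.4, "ERB", True, True)
        assert silicon_signal_strength(mid, geometry) == pytest.approx(0.5)
        assert silicon_signal_strength(full, geometry) == pytest.approx(1.0)

    def test_monotone_non_increasing_outside_handle(self, geometry):
        lo, hi = geometry.handle_interval
        grid = [d for d in np.arange(0.4, 4.81, 0.05) if not lo <= d <= hi]
        vals = [
            silicon_signal_strength(CampaignRun(100.0, d, "ERB", True, False), geometry)
            for d in grid
        ]
        diffs = np.diff(vals)  # grid ascends in d_end -> strength descends
        assert np.all(diffs <= 1e-12)


class TestSpectrumRecords:
    def test_determinism_under_fixed_seed(self, runs_by_dend):
        run = runs_by_dend[3.4]
        a = simulate_spectrum_record(run, seed=9)
        b = simulate_spectrum_record(run, seed=9)
        for layer in ("Raw", "TOF", "BGO", "All"):
            np.testing.assert_array_equal(a.layers[layer].counts, b.layers[layer].counts)
        c = simulate_spectrum_record(run, seed=10)
        assert not np.array_equal(a.layers["Raw"].counts, c.layers["Raw"].counts)

    def test_total_counts_conservation(self, prostate_record, model):
        expected = expected_raw_counts(prostate_record.beam_energy)
        total = prostate_record.layers["Raw"].counts.sum()
        assert abs(total - expected) < 3.0 * np.sqrt(expected)

    def test_prostate_window_contains_only_the_oxygen_line(self, model, runs_by_dend):
        mu_null = expected_layer_spectrum(
            model, expected_raw_counts(94.54), "Raw", silicon_strength=0.0
        )
        mu_si = expected_layer_spectrum(
            model, expected_raw_counts(94.54), "Raw", silicon_strength=1.0
        )
        centers = model.bin_centers()
        window = (centers >= 1.58) & (centers < 1.84)
        near_si = np.abs(centers - 1.78) < 0.02
        # silicon adds structure at 1.78; without it the only peaked
        # excess over the smooth continuum sits at the oxygen line
        assert (mu_si - mu_null)[near_si].sum() > 0
        continuum = expected_layer_spectrum(
            replace(model, lines=(), silicon_area_fraction=0.0),
            expected_raw_counts(94.54),
            "Raw",
        )
        excess = (mu_null - continuum * mu_null.sum() / continuum.sum())[window]
        assert centers[window][np.argmax(excess)] == pytest.approx(1.635, abs=0.01)

    def test_silicon_area_doubles_with_intensity(self, model, runs_by_dend):
        run = runs_by_dend[3.4]
        double = replace(model, silicon_area_fraction=2 * model.silicon_area_fraction)
        rec1 = simulate_spectrum_record(run, model, seed=3)
        rec2 = simulate_spectrum_record(run, double, seed=3)
        a1, _ = silicon_peak_area(detect_record(rec1, "Raw").unrestricted)
        a2, _ = silicon_peak_area(detect_record(rec2, "Raw").unrestricted)
        assert a2 / a1 == pytest.approx(2.0, rel=0.10)


class TestTraces:
    def test_zero_pulses_zero_noise_gives_zero_trace(self):
        out = simulate_trace([], noise_sd=0.0, length=64)
        assert np.all(out["trace"] == 0.0)
        assert not out["pileup"] and not out["overflow"]

    def test_single_pulse_peaks_at_mode_with_height(self):
        out = simulate_trace([(500.0, 100.0, 40.0)], noise_sd=0.0, length=256)
        trace = out["trace"]
        assert trace.max() == pytest.approx(40.0, rel=1e-3)
        assert np.argmax(trace) == pytest.approx(100, abs=1)

    def test_pileup_flag_for_overlapping_pulses(self):
        close = simulate_trace(
            [(500.0, 100.0, 40.0), (500.0, 101.0, 40.0)], length=256
        )
        far = simulate_trace([(500.0, 60.0, 40.0), (500.0, 200.0, 40.0)], length=256)
        assert close["pileup"] and not far["pileup"]

    def test_more_than_three_pulses_rejected(self):
        with pytest.raises(ValueError, match="at most 3"):
            simulate_trace([(1, 10, 1)] * 4)


class TestEventStreams:
    def test_empty_stream(self):
        events = simulate_event_stream(0)
        assert len(events) == 0

    def test_all_prompt_when_background_fraction_zero(self):
        events = simulate_event_stream(5000, tof_model={"prompt_fraction": 1.0}, seed=1)
        lo, hi = 0.0, 10.0
        assert ((events.tof_ns >= lo) & (events.tof_ns <= hi)).all()

    def test_configured_retentions_recovered(self):
        n = 200_000
        events = simulate_event_stream(n, seed=2)
        p_tof = events.is_prompt.mean()
        p_bgo = 1.0 - (
            events.ac_after_primary & (events.ac_energy_kev > 225.0)
        ).mean()
        assert p_tof == pytest.approx(0.13, abs=3 * np.sqrt(0.13 * 0.87 / n))
        assert p_bgo == pytest.approx(0.32, abs=3 * np.sqrt(0.32 * 0.68 / n))

    def test_joint_retention_knob_matches_deposited_fractions(self):
        n = 200_000
        events = simulate_event_stream(
            n, ac_model={"joint_retention": 0.06}, seed=3
        )
        survives_tof = events.is_prompt
        survives_bgo = ~(events.ac_after_primary & (events.ac_energy_kev > 225.0))
        joint = (survives_tof & survives_bgo).mean()
        assert joint == pytest.approx(0.06, abs=3 * np.sqrt(0.06 * 0.94 / n))

    def test_spill_structure_duty_cycle(self):
        spill = SpillStructure(n_spills=10, spill_length_s=1.0, period_s=2.0)
        events = simulate_event_stream(50_000, spill_structure=spill, seed=4)
        assert events.in_spill.mean() == pytest.approx(0.5, abs=0.01)
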