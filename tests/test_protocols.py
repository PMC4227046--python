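"""Rheobase search, pattern classification, ramp analysis, MMO detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motophys import (FICurve, GroupSpec, analyze_ramp, classify_pattern,
                      detect_mmos, detect_spikes, measure_cell,
                      rheobase_search, sample_population, search_grid,
                      segment_ranges, synthesize_protocol)
from motophys.errors import NoSpikeError
from motophys.protocols import MMOResult

from conftest import make_cell, make_delayed_cell


def expected_grid_point(true_rheo):
    grid = search_grid()
    return float(grid[np.searchsorted(grid, true_rheo - 1e-12)])


class TestRheobaseSearch:
    @pytest.mark.parametrize("true,expected", [
        (0.58, 0.60),   # fine 50 pA regime
        (0.93, 1.00),   # coarse 100 pA regime above 0.9 nA
        (0.05, 0.05),   # exactly on the first grid point
        (1.61, 1.70),
    ])
    def test_grid_arithmetic(self, true, expected):
        cell = make_cell(rheobase_true=true, noise_sd=0.0)
        rheo, sweep = rheobase_search(cell, dt=5e-4)
        assert rheo == pytest.approx(expected)
        assert len(detect_spikes(sweep)) >= 1

    def test_silent_cell_errors(self):
        # a high-conductance cell whose rheobase sits above the 5 nA ceiling
        cell = make_cell(G_in=120.0, V_th=-15.0, delta_V=50.0, rheobase_true=6.0)
        with pytest.raises(NoSpikeError):
            rheobase_search(cell, dt=5e-4)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.06, max_value=2.5))
    def test_grid_dominance(self, true_rheo):
        """Measured rheobase >= true, and < true + one step size."""
        cell = make_cell(G_in=1000.0 * true_rheo / 25.0, V_th=-40.0,
                         delta_V=25.0, rheobase_true=true_rheo, noise_sd=0.0)
        rheo, _ = rheobase_search(cell, dt=5e-4)
        step = 0.05 if true_rheo <= 0.9 else 0.1
        assert true_rheo - 1e-9 <= rheo < true_rheo + step + 1e-9
        assert rheo == pytest.approx(expected_grid_point(true_rheo))

    def test_search_on_recorded_protocol(self):
        cell = make_cell(rheobase_true=0.58, noise_sd=0.0)
        proto = synthesize_protocol(cell, "RHEO_STEPS", dt=5e-4)
        rheo, _ = rheobase_search(proto)
        assert rheo == pytest.approx(0.60)


class TestClassifyPattern:
    def test_delayed_example(self):
        cell = make_delayed_cell(delay_scale=2.9)
        _, sweep = rheobase_search(cell)
        assert classify_pattern(sweep) == "delayed"

    def test_immediate_example(self):
        cell = make_cell()
        _, sweep = rheobase_search(cell)
        assert classify_pattern(sweep) == "immediate"

    def test_short_latency_accelerating_train_is_delayed(self):
        # latency only ~0.45 s (< 0.5 s cutoff) but clearly accelerating
        cell = make_delayed_cell(delay_scale=0.52, noise_sd=0.0)
        sweep = synthesize_protocol(
            cell, "RHEO_STEPS", amplitudes=[cell.rheobase_true + 0.04]).sweeps[0]
        assert classify_pattern(sweep) == "delayed"

    def test_agreement_with_generator_labels(self):
        hits, total = 0, 0
        for genotype, pattern in (("WT", "immediate"), ("WT", "delayed")):
            cells = sample_population(GroupSpec.from_tables(genotype, pattern),
                                      30, seed=21)
            for cell in cells:
                _, sweep = rheobase_search(cell, dt=2e-4)
                hits += classify_pattern(sweep) == pattern
                total += 1
        assert hits == total

    def test_needs_spikes(self):
        cell = make_cell(noise_sd=0.0)
        sweep = synthesize_protocol(cell, "RHEO_STEPS",
                                    amplitudes=[0.5 * cell.rheobase_true]).sweeps[0]
        with pytest.raises(NoSpikeError):
            classify_pattern(sweep)


class TestAnalyzeRamp:
    def test_recruitment_matches_rheobase(self):
        cell = make_cell(G_in=15.0, V_th=-45.0, noise_sd=0.0)  # rheobase 0.30
        res = analyze_ramp(synthesize_protocol(cell, "RAMP"))
        assert res.recruitment_current == pytest.approx(0.30, abs=0.01)

    def test_gain_recovered(self):
        cell = make_cell(gain_true=29.0, mmo_present=False)
        res = analyze_ramp(synthesize_protocol(cell, "RAMP"))
        assert res.ficurve.gain == pytest.approx(29.0, abs=2.0)
        assert np.isnan(res.ficurve.boundary_current)  # no MMOs: all primary

    def test_f_half_second_recovered(self):
        cell = make_delayed_cell(f_half_second_true=30.0)
        res = analyze_ramp(synthesize_protocol(cell, "RAMP"))
        assert res.f_half_second == pytest.approx(30.0, rel=0.05)

    def test_hysteresis_and_recruitment_rheobase_agreement(self):
        for factory, seed in ((make_cell, 1), (make_delayed_cell, 2)):
            cell = factory(noise_sd=0.0, seed=seed)
            res = analyze_ramp(synthesize_protocol(cell, "RAMP"))
            assert res.derecruitment_current <= res.recruitment_current + 1e-9
            assert abs(res.recruitment_current - cell.rheobase_true) <= 0.1

    def test_no_ascending_spikes_errors(self):
        cell = make_cell(noise_sd=0.0)
        proto = synthesize_protocol(cell, "RAMP", peak=0.5 * cell.rheobase_true)
        with pytest.raises(NoSpikeError):
            analyze_ramp(proto)

    def test_fewer_than_three_trials_warns_but_proceeds(self):
        cell = make_cell(mmo_present=False)
        proto = synthesize_protocol(cell, "RAMP", trials=2)
        with pytest.warns(UserWarning):
            res = analyze_ramp(proto)
        assert np.isfinite(res.recruitment_current)


class TestDetectMmos:
    def test_mmo_cell_flagged(self):
        cell = make_cell(mmo_present=True, mmo_amplitude=2.0)
        _, sweep = rheobase_search(cell)
        spikes = detect_spikes(sweep, with_thresholds=True)
        assert detect_mmos(sweep, spikes).present

    def test_clean_cell_not_flagged(self):
        cell = make_cell(mmo_present=False, noise_sd=0.0)
        _, sweep = rheobase_search(cell)
        spikes = detect_spikes(sweep, with_thresholds=True)
        res = detect_mmos(sweep, spikes)
        assert not res.present and res.count == 0

    def test_too_few_spikes_is_flag_false(self):
        cell = make_cell(noise_sd=0.0)
        sweep = synthesize_protocol(cell, "RHEO_STEPS",
                                    amplitudes=[0.5 * cell.rheobase_true]).sweeps[0]
        assert not detect_mmos(sweep).present


class TestSegmentRanges:
    def _fic(self, currents, phases):
        return FICurve(currents=np.asarray(currents, float),
                       frequencies=np.full(len(currents), 20.0),
                       phases=np.asarray(phases))

    def test_boundary_at_last_mmo_isi(self):
        fic = self._fic([0.8, 1.0, 1.2, 1.4, 1.6], ["ascending"] * 5)
        mmo = MMOResult(True, 6, per_isi=[3, 2, 2, 0, 0],
                        isi_end_currents=[0.8, 1.0, 1.2, 1.4, 1.6])
        assert segment_ranges(fic, mmo) == pytest.approx(1.2)

    def test_no_mmos_means_all_primary(self):
        fic = self._fic([0.8, 1.0], ["ascending"] * 2)
        mmo = MMOResult(False, 0, per_isi=[0, 0], isi_end_currents=[0.8, 1.0])
        assert np.isnan(segment_ranges(fic, mmo))

    def test_mmos_everywhere_leave_no_primary_range(self):
        # a delayed cell with persistent MMOs along the whole ascending ramp
        cell = make_delayed_cell(f_half_second_true=15.0, mmo_present=True)
        res = analyze_ramp(synthesize_protocol(cell, "RAMP"))
        assert np.isnan(res.ficurve.gain)


def test_measure_cell_assembles_full_feature_vector():
    cell = make_cell(seed=77)
    feats = measure_cell(cell)
    assert feats.pattern == "immediate"
    assert feats.rheobase == pytest.approx(expected_grid_point(cell.rheobase_true))
    assert feats.G_in == pytest.approx(cell.G_in, rel=0.02)
    assert feats.V_threshold == pytest.approx(cell.V_th, abs=1.5)
    assert feats.ahp_tau == pytest.approx(cell.ahp_tau, rel=0.06)
    assert abs(feats.recruitment_current - feats.rheobase) <= 0.1
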