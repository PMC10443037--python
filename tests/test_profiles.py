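"""XIC extraction, matrix-effect ratios and region detection."""

from dataclasses import replace

import numpy as np
import pytest

from pciqc.masses import panel_targets, ppm_window
from pciqc.msdata_io import Channel, ChannelRuleError, Run, Spectrum
from pciqc.profiles import (MatrixEffectProfile, Trace, detect_regions,
                            extract_xic, matrix_effect_percent, profile_ratio,
                            resample, smooth)
from pciqc.simulate import simulate_run

from conftest import make_box_config, random_run


def brute_force_xic(run, mz, tol, channel):
    """Independent oracle: scan every peak of every spectrum."""
    lo, hi = ppm_window(mz, tol)
    times, vals = [], []
    for sp in run.spectra:
        if sp.channel != channel:
            continue
        total = 0.0
        for m, i in zip(sp.mz, sp.intensity):
            if lo <= m <= hi:
                total += i
        times.append(sp.rt)
        vals.append(total)
    return np.array(times), np.array(vals)


class TestExtractXic:
    def test_single_peak_exact_match(self):
        run = Run([Spectrum(1.0, Channel.LOW_ENERGY, [500.0], [123.0])])
        tr = extract_xic(run, 500.0, tol=10.0)
        assert tr.times.tolist() == [1.0]
        assert tr.intensities.tolist() == [123.0]

    def test_matches_brute_force_oracle_on_random_runs(self):
        """Exact equivalence with the all-peaks scan on 100 random fixtures."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            run = random_run(rng, n_spectra=10)
            mz = float(rng.uniform(60, 840))
            tol = float(rng.uniform(0, 5e4))  # include huge windows
            chan = Channel.LOW_ENERGY if rng.random() < 0.5 else Channel.HIGH_ENERGY
            t_o, v_o = brute_force_xic(run, mz, tol, chan)
            tr = extract_xic(run, mz, tol=tol, channel=chan)
            np.testing.assert_array_equal(tr.times, t_o)
            np.testing.assert_array_equal(tr.intensities, v_o)

    def test_simulated_constant_standard(self, clean_config):
        run = simulate_run(clean_config, 5)
        mz = panel_targets(clean_config.standards)["atenolol-d7"]
        tr = extract_xic(run, mz)
        np.testing.assert_allclose(
            tr.intensities, clean_config.standards[0].baseline_intensity,
            rtol=1e-12)

    def test_absent_channel_errors(self):
        run = Run([Spectrum(0.0, Channel.LOW_ENERGY, [100.0], [1.0])])
        with pytest.raises(ChannelRuleError, match="lockmass"):
            extract_xic(run, 100.0, channel=Channel.LOCKMASS)

    def test_absolute_da_window(self):
        run = Run([Spectrum(0.0, Channel.LOW_ENERGY,
                            [184.0733, 184.2], [5.0, 7.0])])
        tr = extract_xic(run, 184.075, tol_da=0.025)
        assert tr.intensities[0] == 5.0


class TestResample:
    def test_identity_grid(self):
        tr = Trace(times=[0.0, 1.0, 2.0], intensities=[1.0, 2.0, 3.0])
        out = resample(tr, [0.0, 1.0, 2.0])
        np.testing.assert_array_equal(out.intensities, tr.intensities)
        assert out.mask.all()

    def test_midpoint_is_arithmetic_mean(self):
        tr = Trace(times=[0.0, 1.0], intensities=[10.0, 20.0])
        out = resample(tr, [0.5])
        assert out.intensities[0] == pytest.approx(15.0)

    def test_point_beyond_span_masked(self):
        tr = Trace(times=[0.0, 1.0], intensities=[10.0, 20.0])
        out = resample(tr, [0.5, 1.5])
        assert out.mask.tolist() == [True, False]

    def test_empty_grid_rejected(self):
        tr = Trace(times=[0.0, 1.0], intensities=[1.0, 1.0])
        with pytest.raises(ValueError):
            resample(tr, [])


class TestSmooth:
    def test_window_one_is_identity(self):
        tr = Trace(times=np.arange(5.0), intensities=[5, 1, 9, 2, 7])
        np.testing.assert_array_equal(smooth(tr, 1).intensities,
                                      tr.intensities)

    def test_single_spike_removed(self):
        inten = np.full(21, 10.0)
        inten[10] = 1000.0
        tr = Trace(times=np.arange(21.0), intensities=inten)
        out = smooth(tr, 5)
        np.testing.assert_allclose(out.intensities, 10.0)

    def test_monotone_preserved(self):
        tr = Trace(times=np.arange(30.0),
                   intensities=np.linspace(1, 60, 30) ** 1.5)
        out = smooth(tr, 5)
        assert np.all(np.diff(out.intensities) >= 0)

    def test_even_window_rejected(self):
        tr = Trace(times=np.arange(5.0), intensities=np.ones(5))
        with pytest.raises(ValueError):
            smooth(tr, 4)


class TestProfileRatio:
    def test_identity(self, small_config):
        run = simulate_run(small_config, 9)
        mz = panel_targets(small_config.standards)["atenolol-d7"]
        tr = extract_xic(run, mz)
        prof = profile_ratio(tr, tr)
        assert prof.mask.any()
        np.testing.assert_array_equal(prof.ratio[prof.mask], 1.0)

    def test_scaling(self):
        t = np.arange(10.0)
        ref = Trace(times=t, intensities=np.full(10, 100.0))
        samp = Trace(times=t, intensities=np.full(10, 50.0))
        prof = profile_ratio(samp, ref)
        np.testing.assert_allclose(prof.ratio[prof.mask], 0.5)

    def test_reference_below_floor_masked_not_infinite(self):
        t = np.arange(6.0)
        ref = Trace(times=t, intensities=[100, 100, 0, 0, 100, 100])
        samp = Trace(times=t, intensities=np.full(6, 50.0))
        prof = profile_ratio(samp, ref, floor=5.0)
        assert prof.mask.tolist() == [True, True, False, False, True, True]
        assert np.all(np.isfinite(prof.ratio))

    def test_disjoint_spans_rejected(self):
        a = Trace(times=[0.0, 1.0], intensities=[1.0, 1.0])
        b = Trace(times=[5.0, 6.0], intensities=[1.0, 1.0])
        with pytest.raises(ValueError, match="overlap"):
            profile_ratio(a, b)

    def test_different_standards_rejected(self):
        a = Trace(times=[0.0, 1.0], intensities=[1.0, 1.0], standard_id="x")
        b = Trace(times=[0.0, 1.0], intensities=[1.0, 1.0], standard_id="y")
        with pytest.raises(ValueError, match="different standards"):
            profile_ratio(a, b)


def _profile_from_arrays(ratio, times=None, mask=None):
    ratio = np.asarray(ratio, dtype=float)
    t = np.arange(ratio.size) / 100.0 if times is None else np.asarray(times)
    tr = Trace(times=t, intensities=np.ones_like(ratio))
    m = np.ones(ratio.size, bool) if mask is None else np.asarray(mask)
    return MatrixEffectProfile(sample=tr, reference=tr, ratio=ratio, mask=m)


class TestDetectRegions:
    def test_flat_ratio_yields_nothing(self):
        prof = _profile_from_arrays(np.ones(200))
        assert detect_regions(prof) == []

    def test_box_event_bounds_recovered_over_seeds(self, panel1):
        """Detected region edges land within 2 scan intervals of the
        simulated box event truth, for 20 independent noise seeds."""
        mz = panel_targets(panel1)["atenolol-d7"]
        cfg = make_box_config(panel1, depth=0.8, start=2.75, end=3.25)
        ref_cfg = make_box_config(panel1, depth=0.0, start=2.75, end=3.25)
        scan_iv = 2 * cfg.scan_interval / 60.0
        for seed in range(1, 21):
            run = simulate_run(cfg, seed)
            ref = simulate_run(ref_cfg, 1000 + seed)
            prof = profile_ratio(extract_xic(run, mz), extract_xic(ref, mz))
            regions = [r for r in detect_regions(prof)
                       if r.kind == "suppression"]
            assert len(regions) == 1, f"seed {seed}"
            r = regions[0]
            assert abs(r.start - 2.75) <= 2 * scan_iv + 1e-9, f"seed {seed}"
            assert abs(r.end - 3.25) <= 2 * scan_iv + 1e-9, f"seed {seed}"
            assert r.extreme_ratio < 0.3

    def test_deepening_never_shrinks_region(self, panel1):
        """Monotonicity: a deeper event yields a region at least as wide."""
        mz = panel_targets(panel1)["atenolol-d7"]
        ref = simulate_run(make_box_config(panel1, depth=0.0, cv=0.0), 1)
        widths = []
        for depth in (0.4, 0.6, 0.8, 0.95):
            run = simulate_run(make_box_config(panel1, depth=depth, cv=0.0), 1)
            prof = profile_ratio(extract_xic(run, mz), extract_xic(ref, mz))
            regs = [r for r in detect_regions(prof) if r.kind == "suppression"]
            widths.append(sum(r.width for r in regs))
        assert all(b >= a - 1e-12 for a, b in zip(widths, widths[1:]))

    def test_nearby_dips_merged(self):
        ratio = np.ones(300)
        ratio[100:110] = 0.3
        ratio[112:122] = 0.3  # 2-sample gap = 0.02 min < merge_gap
        prof = _profile_from_arrays(ratio)
        regs = detect_regions(prof, min_width=0.05, merge_gap=0.03,
                              smooth_window=1)
        assert len(regs) == 1
        assert regs[0].start == pytest.approx(1.00)
        assert regs[0].end == pytest.approx(1.21)

    def test_masked_points_break_intervals(self):
        ratio = np.full(300, 0.3)
        mask = np.ones(300, bool)
        mask[140:160] = False
        prof = _profile_from_arrays(ratio, mask=mask)
        regs = detect_regions(prof, min_width=0.05, merge_gap=0.03,
                              smooth_window=1)
        assert len(regs) == 2

    def test_short_regions_dropped(self):
        ratio = np.ones(300)
        ratio[100:103] = 0.3  # 0.02 min < min_width
        prof = _profile_from_arrays(ratio)
        assert detect_regions(prof, min_width=0.05, smooth_window=1) == []

    def test_enhancement_detected(self):
        ratio = np.ones(300)
        ratio[50:100] = 2.0
        prof = _profile_from_arrays(ratio)
        regs = detect_regions(prof, smooth_window=1)
        assert len(regs) == 1
        assert regs[0].kind == "enhancement"
        assert regs[0].extreme_ratio == pytest.approx(2.0)

    def test_threshold_order_enforced(self):
        prof = _profile_from_arrays(np.ones(50))
        with pytest.raises(ValueError):
            detect_regions(prof, low=1.2, high=1.4)


class TestMatrixEffectPercent:
    def test_closed_form(self):
        assert matrix_effect_percent(100.0, 100.0) == 100.0
        assert matrix_effect_percent(50.0, 100.0) == 50.0

    def test_zero_solvent_rejected(self):
        with pytest.raises(ValueError):
            matrix_effect_percent(1.0, 0.0)

    def test_spiked_response_under_event(self, panel1):
        """A depth-0.4 suppression event gives ME% ~ 60%."""
        mz = panel_targets(panel1)["atenolol-d7"]
        mat = simulate_run(make_box_config(panel1, depth=0.4, cv=0.0), 1)
        sol = simulate_run(make_box_config(panel1, depth=0.0, cv=0.0), 1)
        t_mat = extract_xic(mat, mz)
        t_sol = extract_xic(sol, mz)
        inside = np.abs(t_mat.times - 3.0) <= 0.2
        me = matrix_effect_percent(t_mat.intensities[inside].mean(),
                                   t_sol.intensities[inside].mean())
        assert me == pytest.approx(60.0, rel=0.02)
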