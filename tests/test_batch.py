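"""RSD, buildup/drift detection and batch QC verdicts."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pciqc.batch import (BuildupEvent, QCThresholds, batch_report,
                         detect_buildup, injection_metrics, qc_evaluate, rsd)
from pciqc.masses import default_panel, panel_targets
from pciqc.simulate import (BatchModulation, NoiseModel, ScenarioConfig,
                            SuppressionEvent, simulate_batch, simulate_run)

from conftest import make_box_config


class TestRsd:
    @pytest.mark.parametrize("values, expected", [
        ((5, 5, 5), 0.0),
        ((1, 2, 3), 50.0),
        ((10, 10, 10, 20), 40.0),
    ])
    def test_closed_form(self, values, expected):
        assert rsd(values) == pytest.approx(expected)

    @given(st.lists(st.floats(0.1, 1e6), min_size=2, max_size=30),
           st.floats(1e-3, 1e3))
    @settings(deadline=None)
    def test_scale_invariance(self, values, c):
        assert rsd(np.asarray(values) * c) == pytest.approx(
            rsd(values), rel=1e-6, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            rsd([1.0])
        with pytest.raises(ValueError):
            rsd([-2.0, 2.0])


class TestDetectBuildup:
    def test_constant_series_no_events(self):
        res = detect_buildup([1.0] * 8)
        assert res.events == () and not res.drift

    def test_dip_recovery_event_localized(self):
        res = detect_buildup([1, 1, 0.5, 0.5, 0.5, 1, 1, 1],
                             drop=0.25, k=2)
        assert res.events == (BuildupEvent(3, 5),)
        assert not res.drift

    def test_single_injection_dip_below_k_ignored(self):
        res = detect_buildup([1, 1, 0.5, 1, 1, 1], drop=0.25, k=2)
        assert res.events == ()

    def test_strictly_decreasing_is_drift_not_buildup(self):
        res = detect_buildup([10, 9, 8, 7, 6, 5, 4, 3], drop=0.25, k=2)
        assert res.drift
        assert res.events == ()

    def test_unrecovered_dip_at_end_is_drift(self):
        res = detect_buildup([1, 1, 1, 1, 0.4, 0.4, 0.4, 0.4],
                             drop=0.25, k=2)
        assert res.drift
        assert res.events == ()

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_buildup([1.0, 0.5, 1.0], k=2)

    def test_sensitivity_and_false_positives_over_seeds(self, panel1):
        """Dip batches (event depth 0.5 at dipped injections) are caught in
        >= 18/20 seeds; null batches (5% noise) raise <= 2/20 false events."""
        mz = panel_targets(panel1)["atenolol-d7"]
        dip_cfg = ScenarioConfig(
            standards=panel1, scan_interval=0.5,
            events=(SuppressionEvent(center=3.0, width=0.5, depth=0.5,
                                     shape="box", modulated=True),))
        null_cfg = ScenarioConfig(standards=panel1, scan_interval=0.5)
        ref = simulate_run(ScenarioConfig(standards=panel1, scan_interval=0.5),
                           99991)
        pattern = (0, 0, 1, 1, 1, 0, 0, 0)

        def trough_series(runs):
            out = []
            for r in runs:
                m = injection_metrics(r, panel1, ref)
                out.append(m.standards["atenolol-d7"].trough_ratio)
            return out

        detected = 0
        for seed in range(1, 21):
            runs = simulate_batch(dip_cfg, BatchModulation(pattern, 8), seed)
            if detect_buildup(trough_series(runs), drop=0.25, k=2).events:
                detected += 1
        assert detected >= 18

        false_events = 0
        for seed in range(1, 21):
            runs = simulate_batch(null_cfg,
                                  BatchModulation((1.0,) * 8, 8), seed)
            false_events += len(
                detect_buildup(trough_series(runs), drop=0.25, k=2).events)
        assert false_events <= 2


class TestInjectionMetrics:
    def test_null_run_vs_reference(self, panel1, small_config):
        run = simulate_run(small_config, 5, sample_id="s", group="g")
        ref = simulate_run(small_config, 6)
        m = injection_metrics(run, panel1, ref)
        sm = m.standards["atenolol-d7"]
        assert sm.suppressed_fraction == 0.0
        assert sm.n_regions == 0
        assert sm.median_ratio == pytest.approx(1.0, abs=0.05)

    def test_run_against_itself_median_ratio_one(self, panel1, small_config):
        run = simulate_run(small_config, 5)
        m = injection_metrics(run, panel1, run)
        assert m.standards["atenolol-d7"].median_ratio == pytest.approx(1.0)

    def test_suppressed_fraction_reflects_event_width(self, panel1):
        run = simulate_run(make_box_config(panel1, depth=0.8), 5)
        ref = simulate_run(make_box_config(panel1, depth=0.0), 6)
        m = injection_metrics(run, panel1, ref)
        sm = m.standards["atenolol-d7"]
        # event covers 0.5 min of the 5-min run
        assert sm.suppressed_fraction == pytest.approx(0.1, abs=0.02)
        assert sm.n_regions == 1


class TestBatchQC:
    def _batch(self, panel, cfg, pattern, seed):
        runs = simulate_batch(cfg, BatchModulation(pattern, len(pattern)),
                              seed, group="urine")
        ref = simulate_run(
            ScenarioConfig(standards=panel,
                           scan_interval=cfg.scan_interval), 4242)
        return runs, ref

    def test_all_null_batch_passes(self, panel1):
        cfg = ScenarioConfig(standards=panel1, scan_interval=0.5)
        runs, ref = self._batch(panel1, cfg, (1.0,) * 6, 3)
        report = batch_report(runs, ref, panel1)
        assert set(report.verdicts.values()) == {"pass"}

    def test_dipped_injections_fail(self, panel1):
        cfg = ScenarioConfig(
            standards=panel1, scan_interval=0.5,
            events=(SuppressionEvent(center=3.2, width=0.4, depth=0.2,
                                     modulated=True),))
        runs, ref = self._batch(panel1, cfg, (1, 1, 3, 3, 3, 1, 1, 1), 3)
        report = batch_report(runs, ref, panel1)
        by_order = {m.injection_order: report.verdicts[m.sample_id]
                    for m in report.metrics}
        assert by_order[3] == by_order[4] == by_order[5] == "fail"
        assert by_order[1] == by_order[8] == "pass"
        res = report.buildup["atenolol-d7"]
        assert res.events and res.events[0].start_injection == 3

    def test_high_run_to_run_noise_warns_via_rsd(self, panel1):
        cfg = ScenarioConfig(standards=panel1, scan_interval=0.5,
                             noise=NoiseModel(cv=0.05, run_cv=0.30))
        runs, ref = self._batch(panel1, cfg, (1.0,) * 6, 12)
        report = batch_report(runs, ref, panel1)
        g_rsd = report.intragroup_rsd["urine"]["atenolol-d7"]
        assert g_rsd > 20.0
        # every injection not already failing outright is downgraded to warn
        assert "warn" in report.verdicts.values()
        warned = [sid for sid, v in report.verdicts.items() if v == "warn"]
        assert all(any("RSD" in r for r in report.verdict_reasons[sid])
                   for sid in warned)

    def test_intergroup_rsd_range_reported(self, panel1):
        cfg = ScenarioConfig(standards=panel1, scan_interval=0.5,
                             noise=NoiseModel(cv=0.05, run_cv=0.10))
        runs_a, ref = self._batch(panel1, cfg, (1.0,) * 3, 1)
        runs_b, _ = self._batch(panel1, cfg, (1.0,) * 3, 2)
        for i, r in enumerate(runs_b):
            r.group = "plasma"
            r.injection_order = 4 + i
            r.sample_id = f"b{i}"
        report = batch_report(runs_a + runs_b, ref, panel1)
        lo, hi = report.intergroup_rsd_range
        assert 0.0 <= lo <= hi

    def test_qc_requires_thresholds(self, panel1):
        cfg = ScenarioConfig(standards=panel1, scan_interval=0.5)
        runs, ref = self._batch(panel1, cfg, (1.0,) * 4, 3)
        report = batch_report(runs, ref, panel1)
        with pytest.raises(ValueError):
            qc_evaluate(report, None)

    def test_verdicts_deterministic(self, panel1):
        cfg = ScenarioConfig(standards=panel1, scan_interval=0.5)
        runs, ref = self._batch(panel1, cfg, (1.0,) * 4, 3)
        a = batch_report(runs, ref, panel1).verdicts
        b = batch_report(runs, ref, panel1).verdicts
        assert a == b
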