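"""Batch-level monitoring of postcolumn-infusion metrics across injections.

Each injection is reduced to per-standard summaries (median trace
intensity, median and trough matrix-effect ratio against the batch
reference, fraction of the run inside suppression regions).  Across the
batch the module reports within-group and between-group relative standard
deviations, flags monotone drift, detects transient dip-recovery episodes
(the signature of column buildup of matrix compounds eluting in later
injections), and assigns a pass/warn/fail verdict per injection.

The trough metric used for dip detection is the 5th percentile of the
smoothed matrix-effect ratio: the reported median response is deliberately
robust to localized suppression, so an episode confined to a narrow
retention window moves the trough, not the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .masses import PanelStandard, panel_targets
from .msdata_io import Run
from .profiles import (DEFAULT_HIGH, DEFAULT_LOW, DEFAULT_MERGE_GAP,
                       DEFAULT_MIN_WIDTH, DEFAULT_RATIO_FLOOR,
                       DEFAULT_SMOOTH_WINDOW, MatrixEffectProfile,
                       SuppressionRegion, detect_regions, extract_xic,
                       profile_ratio, _rolling_median)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 x sd(n-1) / mean.

    Scale-invariant: rsd(c*x) == rsd(x) for any c > 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"RSD needs at least two values, got {x.size}")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("RSD is undefined for non-positive means")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass(frozen=True)
class StandardMetrics:
    """Per-standard summary of one injection."""

    median_intensity: float
    median_ratio: float
    trough_ratio: float
    suppressed_fraction: float
    n_regions: int


@dataclass(frozen=True)
class InjectionMetrics:
    """Per-injection PCI summary."""

    sample_id: str
    injection_order: int
    group: str
    standards: dict[str, StandardMetrics]


@dataclass(frozen=True)
class BuildupEvent:
    """A transient dip-recovery episode, as 1-based injection orders."""

    start_injection: int
    end_injection: int
    standard_id: str = ""


@dataclass(frozen=True)
class BuildupResult:
    events: tuple[BuildupEvent, ...]
    drift: bool
    flagged: tuple[int, ...]  # 0-based indices below the rolling baseline


@dataclass(frozen=True)
class QCThresholds:
    """Batch QC rule parameters.

    ``max_suppressed_fraction`` — per-standard ceiling on the share of the
    run inside suppression regions (fail above it).  ``rsd_warn_pct`` —
    intragroup RSD (of median response) above this warns.  ``drop`` and
    ``k`` parameterize buildup detection (relative dip vs rolling baseline,
    minimum consecutive injections).
    """

    max_suppressed_fraction: float = 0.10
    rsd_warn_pct: float = 20.0
    drop: float = 0.25
    k: int = 2


@dataclass
class BatchReport:
    """Everything the batch monitor computed."""

    metrics: list[InjectionMetrics]
    intragroup_rsd: dict[str, dict[str, float]]      # group -> standard -> RSD%
    intergroup_rsd_range: Optional[tuple[float, float]]
    buildup: dict[str, BuildupResult]                # standard -> result
    verdicts: dict[str, str] = field(default_factory=dict)  # sample_id -> verdict
    verdict_reasons: dict[str, list[str]] = field(default_factory=dict)

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for m in self.metrics:
            for name, sm in m.standards.items():
                rows.append({
                    "sample_id": m.sample_id, "injection_order": m.injection_order,
                    "group": m.group, "standard": name,
                    "median_intensity": sm.median_intensity,
                    "median_ratio": sm.median_ratio,
                    "trough_ratio": sm.trough_ratio,
                    "suppressed_fraction": sm.suppressed_fraction,
                    "n_regions": sm.n_regions,
                    "verdict": self.verdicts.get(m.sample_id, ""),
                })
        return pd.DataFrame(rows)


def injection_metrics(run: Run, panel: Sequence[PanelStandard],
                      reference: Run, *,
                      low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH,
                      min_width: float = DEFAULT_MIN_WIDTH,
                      merge_gap: float = DEFAULT_MERGE_GAP,
                      smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                      floor: float = DEFAULT_RATIO_FLOOR,
                      _reference_traces: Optional[dict] = None
                      ) -> InjectionMetrics:
    """Profile one injection against the reference and summarize it.

    ``_reference_traces`` lets batch drivers pass pre-extracted reference
    XICs so the reference run is only scanned once per batch.
    """
    targets = panel_targets(panel)
    out: dict[str, StandardMetrics] = {}
    t0, t1 = run.span()
    span = max(t1 - t0, np.finfo(float).tiny)
    for name, mz in targets.items():
        tr = extract_xic(run, mz, standard_id=name)
        if _reference_traces is not None and name in _reference_traces:
            ref_tr = _reference_traces[name]
        else:
            ref_tr = extract_xic(reference, mz, standard_id=name)
            if _reference_traces is not None:
                _reference_traces[name] = ref_tr
        prof = profile_ratio(tr, ref_tr, floor=floor)
        regions = detect_regions(prof, low=low, high=high, min_width=min_width,
                                 merge_gap=merge_gap, smooth_window=smooth_window)
        sup = [r for r in regions if r.kind == "suppression"]
        sm = _rolling_median(np.where(prof.mask, prof.ratio, np.nan), smooth_window)
        valid = sm[prof.mask & np.isfinite(sm)]
        out[name] = StandardMetrics(
            median_intensity=float(np.median(tr.intensities)),
            median_ratio=float(np.median(valid)) if valid.size else float("nan"),
            trough_ratio=float(np.percentile(valid, 5)) if valid.size else float("nan"),
            suppressed_fraction=float(min(1.0, sum(r.width for r in sup) / span)),
            n_regions=len(regions),
        )
    return InjectionMetrics(sample_id=run.sample_id or f"inj_{run.injection_order}",
                            injection_order=run.injection_order,
                            group=run.group, standards=out)


def detect_buildup(series: Sequence[float], drop: float = 0.25, k: int = 2,
                   baseline_window: int = 5) -> BuildupResult:
    """Detect transient dips against a rolling baseline of normal injections.

    The baseline before injection ``i`` is the median of up to
    ``baseline_window`` preceding non-flagged values (initialized from the
    first injection).  Injection ``i`` is flagged when its value falls below
    ``(1 - drop) x baseline``.  A buildup event is a maximal span of at
    least ``k`` consecutive flagged injections followed by a recovered
    (non-flagged) injection; a flagged span running to the end of the
    series, or an overall monotone decay of at least ``drop``, is reported
    as drift instead.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * k:
        raise ValueError(f"series of length {x.size} is shorter than 2k = {2 * k}")
    if not 0.0 < drop < 1.0:
        raise ValueError("drop must be a fraction in (0, 1)")
    good: list[float] = []
    flagged = np.zeros(x.size, dtype=bool)
    for i, v in enumerate(x):
        baseline = np.median(good[-baseline_window:]) if good else x[0]
        if v < (1.0 - drop) * baseline:
            flagged[i] = True
        else:
            good.append(v)

    events: list[BuildupEvent] = []
    drift = False
    i = 0
    while i < x.size:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j < x.size and flagged[j]:
            j += 1
        if j - i >= k:
            if j < x.size:  # recovery observed
                events.append(BuildupEvent(start_injection=i + 1,
                                           end_injection=j))
            else:
                drift = True
        i = j
    diffs = np.diff(x)
    if np.all(diffs < 0) and x[0] > 0 and (x[0] - x[-1]) / x[0] >= drop:
        drift = True
    return BuildupResult(events=tuple(events), drift=drift,
                         flagged=tuple(int(i) for i in np.flatnonzero(flagged)))


def batch_report(runs: Sequence[Run], reference: Run,
                 panel: Sequence[PanelStandard],
                 thresholds: Optional[QCThresholds] = None,
                 **profile_kwargs) -> BatchReport:
    """Run the full batch monitor: metrics, RSDs, buildup, verdicts.

    ``runs`` are ordered by injection order internally; the reference run is
    profiled against once and shared across injections.
    """
    thresholds = thresholds or QCThresholds()
    ordered = sorted(runs, key=lambda r: r.injection_order)
    ref_traces: dict = {}
    metrics = [injection_metrics(r, panel, reference,
                                 _reference_traces=ref_traces, **profile_kwargs)
               for r in ordered]

    names = list(panel_targets(panel))
    groups = sorted({m.group for m in metrics})
    intragroup: dict[str, dict[str, float]] = {}
    group_means: dict[str, dict[str, float]] = {}
    for g in groups:
        sub = [m for m in metrics if m.group == g]
        intragroup[g] = {}
        group_means[g] = {}
        for name in names:
            vals = [m.standards[name].median_intensity for m in sub]
            group_means[g][name] = float(np.mean(vals))
            if len(vals) >= 2:
                intragroup[g][name] = rsd(vals)
    inter_range = None
    if len(groups) >= 2:
        inter = [rsd([group_means[g][name] for g in groups]) for name in names
                 if all(group_means[g][name] > 0 for g in groups)]
        if inter:
            inter_range = (float(min(inter)), float(max(inter)))

    buildup: dict[str, BuildupResult] = {}
    if len(metrics) >= 2 * thresholds.k:
        for name in names:
            series = [m.standards[name].trough_ratio for m in metrics]
            if np.all(np.isfinite(series)):
                buildup[name] = detect_buildup(series, drop=thresholds.drop,
                                               k=thresholds.k)

    report = BatchReport(metrics=metrics, intragroup_rsd=intragroup,
                         intergroup_rsd_range=inter_range, buildup=buildup)
    qc_evaluate(report, thresholds)
    return report


def qc_evaluate(report: BatchReport,
                thresholds: Optional[QCThresholds] = None) -> dict[str, str]:
    """Assign pass/warn/fail per injection (rules applied fail > warn > pass).

    Fail: any standard's suppressed_fraction exceeds the ceiling, or the
    injection participates in a buildup event.  Warn: the injection's group
    shows intragroup RSD above the threshold for any standard.  Pass
    otherwise.
    """
    if thresholds is None:
        raise ValueError("QC thresholds are required")
    verdicts: dict[str, str] = {}
    reasons: dict[str, list[str]] = {}
    dipped: dict[int, list[str]] = {}
    for name, res in report.buildup.items():
        for ev in res.events:
            for order in range(ev.start_injection, ev.end_injection + 1):
                dipped.setdefault(order, []).append(name)
    for m in report.metrics:
        why: list[str] = []
        for name, sm in m.standards.items():
            if sm.suppressed_fraction > thresholds.max_suppressed_fraction:
                why.append(f"{name}: suppressed_fraction "
                           f"{sm.suppressed_fraction:.2f} > "
                           f"{thresholds.max_suppressed_fraction:.2f}")
        if m.injection_order in dipped:
            why.append("in buildup event for "
                       + ", ".join(dipped[m.injection_order]))
        if why:
            verdicts[m.sample_id] = "fail"
        else:
            high_rsd = [f"{name}: intragroup RSD {v:.1f}% > "
                        f"{thresholds.rsd_warn_pct:.1f}%"
                        for name, v in report.intragroup_rsd.get(m.group, {}).items()
                        if v > thresholds.rsd_warn_pct]
            if high_rsd:
                why.extend(high_rsd)
                verdicts[m.sample_id] = "warn"
            else:
                verdicts[m.sample_id] = "pass"
        reasons[m.sample_id] = why
    report.verdicts = verdicts
    report.verdict_reasons = reasons
    return verdicts
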