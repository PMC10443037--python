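"""Matrix-effect profiles: XIC extraction, ratio curves, region detection.

The postcolumn-infusion readout is an extracted ion chromatogram (XIC) of
each infused standard over the whole run.  Dividing a sample injection's
trace by a reference injection's trace (solvent or extracted blank) gives
the matrix-effect profile: a ratio near 1 means unperturbed ionization,
below 1 ion suppression, above 1 ion enhancement.  Contiguous stretches
where the (median-smoothed) ratio breaches configurable thresholds are
reported as suppression/enhancement regions; the spike-based matrix-effect
percentage ME% = 100 x response_matrix / response_solvent is provided for
comparison with conventional spike-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .masses import ppm_window
from .msdata_io import Channel, ChannelRuleError, Run

#: Default XIC tolerance for infusion standards (ppm).
DEFAULT_XIC_TOL_PPM = 10.0
#: Default ratio floor: points where the reference trace falls below this are
#: masked instead of divided (5x the simulator's default additive baseline).
DEFAULT_RATIO_FLOOR = 5.0
#: Default region-detection thresholds and geometry.
DEFAULT_LOW = 0.7
DEFAULT_HIGH = 1.4
DEFAULT_MIN_WIDTH = 0.05   # minutes
DEFAULT_MERGE_GAP = 0.03   # minutes
DEFAULT_SMOOTH_WINDOW = 5  # scans, applied to the ratio


@dataclass
class Trace:
    """Time-resolved intensity of one target ion.

    ``mask`` flags valid points; resampling outside the source span yields
    masked (never zero-filled) points.
    """

    times: np.ndarray
    intensities: np.ndarray
    target_mz: float = 0.0
    tol: float = DEFAULT_XIC_TOL_PPM
    channel: Channel = Channel.LOW_ENERGY
    standard_id: str = ""
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities differ in length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("trace times must be non-decreasing")
        if self.mask is None:
            self.mask = np.ones(self.times.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.times.shape:
                raise ValueError("mask length mismatch")


@dataclass
class MatrixEffectProfile:
    """Sample-vs-reference ratio curve of one standard on a common grid."""

    sample: Trace
    reference: Trace
    ratio: np.ndarray
    mask: np.ndarray  # True where the ratio is valid
    standard_id: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.reference.times


@dataclass(frozen=True)
class SuppressionRegion:
    """A contiguous interval where the profile breaches a threshold."""

    start: float
    end: float
    kind: str  # "suppression" | "enhancement"
    extreme_ratio: float
    mean_ratio: float
    standard_id: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("region start must precede end")
        if self.kind not in ("suppression", "enhancement"):
            raise ValueError(f"unknown region kind {self.kind!r}")

    @property
    def width(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


def extract_xic(run: Run, mz: float, tol: float = DEFAULT_XIC_TOL_PPM,
                channel: Channel = Channel.LOW_ENERGY, *,
                tol_da: Optional[float] = None,
                standard_id: str = "") -> Trace:
    """Extracted ion chromatogram: per scan, the summed intensity of all
    peaks inside the tolerance window around ``mz``.

    The window is ``+/- tol`` ppm by default, or an absolute ``+/- tol_da``
    daltons when given (used for low-mass fragments where instrument
    rounding exceeds any sensible ppm window).
    """
    spectra = run.spectra_in(channel)
    if not spectra:
        raise ChannelRuleError(f"run has no spectra in channel {channel.value!r}")
    if tol_da is not None:
        lo, hi = max(0.0, mz - tol_da), mz + tol_da
    else:
        lo, hi = ppm_window(mz, tol)
    times = np.empty(len(spectra))
    inten = np.empty(len(spectra))
    for i, sp in enumerate(spectra):
        times[i] = sp.rt
        i0 = np.searchsorted(sp.mz, lo, side="left")
        i1 = np.searchsorted(sp.mz, hi, side="right")
        inten[i] = sp.intensity[i0:i1].sum() if i1 > i0 else 0.0
    return Trace(times=times, intensities=inten, target_mz=mz,
                 tol=(tol if tol_da is None else tol_da),
                 channel=channel, standard_id=standard_id)


def resample(trace: Trace, grid: Sequence[float]) -> Trace:
    """Linear interpolation of a trace onto a new time grid.

    Grid points outside the trace span come back masked.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty resampling grid")
    if trace.times.size == 0:
        raise ValueError("cannot resample an empty trace")
    t0, t1 = trace.times[0], trace.times[-1]
    inside = (grid >= t0) & (grid <= t1)
    vals = np.interp(grid, trace.times, trace.intensities)
    vals[~inside] = 0.0
    return Trace(times=grid, intensities=vals, target_mz=trace.target_mz,
                 tol=trace.tol, channel=trace.channel,
                 standard_id=trace.standard_id, mask=inside)


def smooth(trace: Trace, window: int = DEFAULT_SMOOTH_WINDOW) -> Trace:
    """Centered moving-median smoothing; ends use shrinking windows.

    ``window`` must be odd; ``window=1`` is the identity.  The median
    removes single-scan spikes without biasing the depth of genuine
    plateaus, and preserves monotone segments.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    sm = _rolling_median(trace.intensities, window)
    return replace(trace, intensities=sm,
                   times=trace.times.copy(), mask=trace.mask.copy())


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    if window == 1 or values.size == 0:
        return values.astype(float).copy()
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def profile_ratio(sample: Trace, reference: Trace,
                  floor: float = DEFAULT_RATIO_FLOOR) -> MatrixEffectProfile:
    """Pointwise sample/reference ratio on the reference grid.

    Points where the reference is below ``floor`` (or either trace is
    masked) are masked, never reported as zero or infinity.
    """
    if sample.standard_id and reference.standard_id \
            and sample.standard_id != reference.standard_id:
        raise ValueError(
            f"profile compares different standards: "
            f"{sample.standard_id!r} vs {reference.standard_id!r}"
        )
    if sample.channel != reference.channel:
        raise ValueError("sample and reference traces are from different channels")
    if sample.times[0] > reference.times[-1] or sample.times[-1] < reference.times[0]:
        raise ValueError("sample and reference time spans do not overlap")
    rs = sample if np.array_equal(sample.times, reference.times) \
        else resample(sample, reference.times)
    valid = rs.mask & reference.mask & (reference.intensities >= floor)
    ratio = np.zeros_like(reference.intensities)
    np.divide(rs.intensities, reference.intensities, out=ratio, where=valid)
    return MatrixEffectProfile(sample=rs, reference=reference, ratio=ratio,
                               mask=valid,
                               standard_id=sample.standard_id or reference.standard_id)


def detect_regions(profile: MatrixEffectProfile,
                   low: float = DEFAULT_LOW,
                   high: float = DEFAULT_HIGH,
                   min_width: float = DEFAULT_MIN_WIDTH,
                   merge_gap: float = DEFAULT_MERGE_GAP,
                   smooth_window: int = DEFAULT_SMOOTH_WINDOW
                   ) -> list[SuppressionRegion]:
    """Segment the profile into suppression (< ``low``) and enhancement
    (> ``high``) regions.

    The ratio is median-smoothed before thresholding; masked points break
    intervals; same-kind regions separated by gaps of at most ``merge_gap``
    minutes (with no masked points in between) are merged; regions narrower
    than ``min_width`` minutes are dropped.
    """
    if not 0.0 < low < 1.0 < high:
        raise ValueError(f"thresholds must satisfy 0 < low < 1 < high, "
                         f"got low={low}, high={high}")
    t = profile.times
    # masked points go in as NaN so they never drag the median near gaps
    sm = _rolling_median(np.where(profile.mask, profile.ratio, np.nan),
                         smooth_window)
    regions: list[SuppressionRegion] = []
    for kind, cond in (("suppression", sm < low), ("enhancement", sm > high)):
        flag = cond & profile.mask
        padded = np.concatenate(([False], flag, [False])).astype(int)
        edges = np.flatnonzero(np.diff(padded))
        spans = list(zip(edges[::2], edges[1::2]))  # [i0, i1) index pairs
        # merge across short, fully-valid gaps
        merged: list[list[int]] = []
        for i0, i1 in spans:
            if merged:
                p0, p1 = merged[-1]
                gap_ok = (t[i0] - t[p1 - 1]) <= merge_gap + 1e-9 \
                    and bool(profile.mask[p1:i0].all())
                if gap_ok:
                    merged[-1][1] = i1
                    continue
            merged.append([i0, i1])
        for i0, i1 in merged:
            start, end = float(t[i0]), float(t[i1 - 1])
            if end - start < min_width:
                continue
            seg = sm[i0:i1][profile.mask[i0:i1]]
            extreme = float(seg.min() if kind == "suppression" else seg.max())
            regions.append(SuppressionRegion(
                start=start, end=end, kind=kind, extreme_ratio=extreme,
                mean_ratio=float(seg.mean()), standard_id=profile.standard_id))
    regions.sort(key=lambda r: r.start)
    return regions


def matrix_effect_percent(response_in_matrix: float,
                          response_in_solvent: float) -> float:
    """Spike-based matrix effect: 100 x matrix response / solvent response.

    100% means no matrix effect; below 100% suppression, above enhancement.
    """
    if response_in_solvent <= 0:
        raise ValueError("solvent response must be positive")
    return 100.0 * response_in_matrix / response_in_solvent


def regions_table(regions: Sequence[SuppressionRegion]) -> pd.DataFrame:
    """Flatten regions to the TSV schema used by the CLI."""
    return pd.DataFrame(
        [{"standard": r.standard_id, "kind": r.kind,
          "start_min": r.start, "end_min": r.end,
          "extreme_ratio": r.extreme_ratio, "mean_ratio": r.mean_ratio}
         for r in regions],
        columns=["standard", "kind", "start_min", "end_min",
                 "extreme_ratio", "mean_ratio"],
    )
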