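"""Attribution of suppression regions to their chemical causes.

Two signatures cover the common culprits in reversed-phase bioanalysis:

* **Phospholipids** — glycerophosphocholine lipids surviving protein
  precipitation (or re-eluting from the column in later injections) share
  the phosphocholine head-group fragment near m/z 184.07, visible in the
  high-collision-energy channel.  A region is phospholipid-consistent when
  the fragment trace is strongly enriched inside the region and its signal
  span overlaps the region.
* **PEG polymer** — plastic-ware leachables (e.g. from heparin collection
  tubes) show an arithmetic m/z ladder spaced by the ethylene-oxide repeat
  (~44 Da) in the averaged spectrum of the suppressed interval.

Regions explained by neither can be browsed as a plain candidate-feature
list (most intense co-eluting ions); database annotation is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .msdata_io import Channel, ChannelRuleError, Run, Spectrum
from .profiles import SuppressionRegion, Trace, extract_xic

#: Diagnostic phosphocholine fragment m/z as instrument software rounds it.
#: The formula value (C5H15NO4P+) is 184.0733; the absolute window below is
#: wide enough to cover both conventions.
DEFAULT_FRAGMENT_MZ = 184.075
#: Absolute extraction window for the fragment (Da).
DEFAULT_FRAGMENT_WINDOW = 0.025
#: Verdict thresholds (config defaults; the underlying evidence is returned
#: so callers can apply their own).
DEFAULT_ENRICHMENT_MIN = 3.0
DEFAULT_OVERLAP_MIN = 0.5
#: Polymer-series search defaults: PEG-like repeats.
DEFAULT_REPEAT_RANGE = (40.0, 50.0)
DEFAULT_SERIES_TOL = 0.02
DEFAULT_MIN_MEMBERS = 5
DEFAULT_MIN_REL_INTENSITY = 0.01


@dataclass(frozen=True)
class PhospholipidScreenResult:
    """Evidence that a suppression region coincides with phospholipid elution."""

    region: SuppressionRegion
    fragment_trace: Trace
    overlap_fraction: float
    enrichment: float
    verdict: bool

    @property
    def label(self) -> str:
        return "phospholipid-consistent" if self.verdict else "negative"


@dataclass(frozen=True)
class PolymerSeries:
    """An arithmetic m/z progression found in an averaged spectrum."""

    member_mzs: tuple[float, ...]
    spacing: float
    intercept: float
    residual_rmsd: float
    summed_intensity: float

    def __post_init__(self):
        if len(self.member_mzs) < 2:
            raise ValueError("a polymer series needs at least two members")
        if any(b <= a for a, b in zip(self.member_mzs, self.member_mzs[1:])):
            raise ValueError("series members must be strictly increasing")

    @property
    def n_members(self) -> int:
        return len(self.member_mzs)


def average_spectrum(run: Run, window: tuple[float, float],
                     channel: Channel = Channel.LOW_ENERGY,
                     cluster_tol: float = 0.01) -> Spectrum:
    """Average the scans of a retention-time window into one spectrum.

    Peaks from all scans are merged by centroid clustering (split where
    consecutive sorted m/z gaps exceed ``cluster_tol`` Da); each cluster's
    m/z is the intensity-weighted mean and its intensity the per-scan mean
    (sum over scans / number of scans), so a persistent ion keeps its
    single-scan intensity while a one-scan spike is diluted.
    """
    t0, t1 = window
    scans = [s for s in run.spectra_in(channel) if t0 <= s.rt <= t1]
    if not scans:
        raise ValueError(f"no {channel.value} scans in window {window}")
    mz_all = np.concatenate([s.mz for s in scans])
    it_all = np.concatenate([s.intensity for s in scans])
    if mz_all.size == 0:
        return Spectrum(rt=0.5 * (t0 + t1), channel=channel,
                        mz=np.empty(0), intensity=np.empty(0))
    order = np.argsort(mz_all, kind="stable")
    mz_all, it_all = mz_all[order], it_all[order]
    breaks = np.flatnonzero(np.diff(mz_all) > cluster_tol) + 1
    groups = np.split(np.arange(mz_all.size), breaks)
    out_mz, out_it = [], []
    for g in groups:
        tot = it_all[g].sum()
        if tot > 0:
            out_mz.append(float(np.average(mz_all[g], weights=it_all[g])))
        else:
            out_mz.append(float(mz_all[g].mean()))
        out_it.append(tot / len(scans))
    out_mz_arr = np.asarray(out_mz)
    out_it_arr = np.asarray(out_it)
    # clustering can in principle produce ties; keep strictly increasing m/z
    keep = np.concatenate(([True], np.diff(out_mz_arr) > 0))
    return Spectrum(rt=0.5 * (t0 + t1), channel=channel,
                    mz=out_mz_arr[keep], intensity=out_it_arr[keep])


def phospholipid_screen(run: Run, region: SuppressionRegion,
                        fragment_mz: float = DEFAULT_FRAGMENT_MZ,
                        window: float = DEFAULT_FRAGMENT_WINDOW,
                        enrichment_min: float = DEFAULT_ENRICHMENT_MIN,
                        overlap_min: float = DEFAULT_OVERLAP_MIN,
                        span_rel_threshold: float = 0.1
                        ) -> PhospholipidScreenResult:
    """Screen a suppression region for co-eluting phospholipids.

    The phosphocholine fragment XIC (absolute ``+/- window`` Da) is taken
    from the high-collision-energy channel.  ``enrichment`` compares the
    mean fragment intensity inside vs outside the region (scale-invariant);
    ``overlap_fraction`` is the share of the fragment's above-threshold span
    (>= ``span_rel_threshold`` of its maximum) that falls inside the region.
    The verdict is positive when enrichment >= ``enrichment_min`` and
    overlap >= ``overlap_min``.
    """
    if not run.spectra_in(Channel.HIGH_ENERGY):
        raise ChannelRuleError(
            "phospholipid screen needs the high_energy channel, which is absent"
        )
    frag = extract_xic(run, fragment_mz, channel=Channel.HIGH_ENERGY,
                       tol_da=window, standard_id="phosphocholine-fragment")
    inside = (frag.times >= region.start) & (frag.times <= region.end)
    mean_in = float(frag.intensities[inside].mean()) if inside.any() else 0.0
    mean_out = float(frag.intensities[~inside].mean()) if (~inside).any() else 0.0
    if mean_out > 0:
        enrichment = mean_in / mean_out
    elif mean_in > 0:
        enrichment = math.inf
    else:
        enrichment = 1.0  # no fragment signal anywhere: nothing to attribute
    peak = frag.intensities.max() if frag.intensities.size else 0.0
    if peak > 0:
        above = frag.intensities >= span_rel_threshold * peak
        overlap = float((above & inside).sum() / above.sum())
    else:
        overlap = 0.0
    verdict = enrichment >= enrichment_min and overlap >= overlap_min
    return PhospholipidScreenResult(region=region, fragment_trace=frag,
                                    overlap_fraction=overlap,
                                    enrichment=enrichment, verdict=verdict)


def _extend_chain(mz: np.ndarray, i: int, j: int, tol: float) -> list[int]:
    """Greedy arithmetic-progression extension from anchor pair (i, j)."""
    chain = [i, j]
    d = mz[j] - mz[i]
    expect = mz[j] + d
    while True:
        k0 = np.searchsorted(mz, expect - tol, side="left")
        k1 = np.searchsorted(mz, expect + tol, side="right")
        if k1 <= k0:
            break
        cand = np.arange(k0, k1)
        k = int(cand[np.argmin(np.abs(mz[cand] - expect))])
        chain.append(k)
        expect = mz[k] + d
    return chain


def detect_polymer_series(spectrum: Spectrum,
                          repeat_range: tuple[float, float] = DEFAULT_REPEAT_RANGE,
                          tol: float = DEFAULT_SERIES_TOL,
                          min_members: int = DEFAULT_MIN_MEMBERS,
                          min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY
                          ) -> list[PolymerSeries]:
    """Find arithmetic m/z progressions (polymer ladders) in a spectrum.

    Peaks above ``min_rel_intensity`` of the base peak are chained greedily:
    each (anchor, partner) pair with spacing inside ``repeat_range`` seeds a
    progression extended while a peak exists within ``+/- tol`` Da of the
    next expected position.  Chains with >= ``min_members`` members are
    refit by least squares (member index vs m/z) and reported longest-first
    (ties: higher summed intensity, then lower starting m/z); members of a
    reported series are removed from further anchoring.  Charge states are
    not assigned: the spacing is reported as observed on the m/z axis.
    """
    if spectrum.mz.size == 0:
        return []
    if not spectrum.centroided:
        raise ValueError("polymer-series detection expects a centroided spectrum")
    base = spectrum.intensity.max()
    keep = spectrum.intensity >= min_rel_intensity * base
    mz = spectrum.mz[keep]
    inten = spectrum.intensity[keep]
    n = mz.size
    lo_rep, hi_rep = repeat_range

    candidates: list[tuple[int, float, float, list[int]]] = []
    for i in range(n):
        j0 = np.searchsorted(mz, mz[i] + lo_rep, side="left")
        j1 = np.searchsorted(mz, mz[i] + hi_rep, side="right")
        for j in range(j0, j1):
            chain = _extend_chain(mz, i, j, tol)
            if len(chain) >= min_members:
                candidates.append(
                    (len(chain), float(inten[chain].sum()), float(mz[i]), chain)
                )
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))

    used = np.zeros(n, dtype=bool)
    series: list[PolymerSeries] = []
    for _, total, _, chain in candidates:
        idx = np.asarray(chain)
        if used[idx].any():
            continue
        used[idx] = True
        member_mz = mz[idx]
        k = np.arange(member_mz.size, dtype=float)
        spacing, intercept = np.polyfit(k, member_mz, 1)
        resid = member_mz - (intercept + spacing * k)
        series.append(PolymerSeries(
            member_mzs=tuple(float(x) for x in member_mz),
            spacing=float(spacing), intercept=float(intercept),
            residual_rmsd=float(np.sqrt(np.mean(resid ** 2))),
            summed_intensity=total))
    return series


def list_coeluting_features(run: Run, region: SuppressionRegion,
                            top_n: int = 20,
                            channel: Channel = Channel.LOW_ENERGY,
                            cluster_tol: float = 0.01) -> pd.DataFrame:
    """The most intense merged features co-eluting with a region.

    Returns a DataFrame with columns ``mz``, ``apex_rt``, ``apex_intensity``
    sorted by intensity — a plain candidate list for manual follow-up
    (database annotation is deliberately out of scope).
    """
    cols = ["mz", "apex_rt", "apex_intensity"]
    if top_n <= 0:
        return pd.DataFrame(columns=cols)
    try:
        avg = average_spectrum(run, (region.start, region.end), channel,
                               cluster_tol=cluster_tol)
    except ValueError:
        return pd.DataFrame(columns=cols)
    if avg.mz.size == 0:
        return pd.DataFrame(columns=cols)
    order = np.argsort(avg.intensity)[::-1][:top_n]
    rows = []
    for i in order:
        xic = extract_xic(run, float(avg.mz[i]), channel=channel,
                          tol_da=cluster_tol)
        inside = (xic.times >= region.start) & (xic.times <= region.end)
        if inside.any():
            sub_t = xic.times[inside]
            sub_i = xic.intensities[inside]
            k = int(np.argmax(sub_i))
            apex_rt, apex_int = float(sub_t[k]), float(sub_i[k])
        else:
            apex_rt, apex_int = float("nan"), 0.0
        rows.append({"mz": float(avg.mz[i]), "apex_rt": apex_rt,
                     "apex_intensity": apex_int})
    return pd.DataFrame(rows, columns=cols)
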