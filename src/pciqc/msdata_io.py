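"""mzML I/O for two-channel (MSe-style) runs and lock-mass correction.

A PCI run is acquired as alternating full scans at low collision energy
(intact ions, where the infused standards are monitored) and high collision
energy (nonselective fragments, where the phosphocholine diagnostic lives).
Vendor-neutral mzML has no standard tag for this acquisition mode, so each
scan carries explicit collision-energy user parameters and channel
assignment on read is driven by an auditable rule table
(:class:`ChannelRules`).

Both directions are self-contained: writing emits minimal mzML 1.1.0
(uncompressed base64 float64 arrays) and reading is a streaming
ElementTree parser that understands 32/64-bit float binary arrays with
optional zlib compression, so runs round-trip losslessly and files from
standard converters load without vendor libraries.
"""

from __future__ import annotations

import base64
import enum
import logging
import math
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence
from xml.sax.saxutils import escape, quoteattr

import numpy as np

from .masses import LOCKMASS_MZ, ppm_window

logger = logging.getLogger(__name__)

_MZML_NS = "http://psi.hupo.org/ms/mzml"


class Channel(str, enum.Enum):
    """Acquisition channel of a scan."""

    LOW_ENERGY = "low_energy"
    HIGH_ENERGY = "high_energy"
    LOCKMASS = "lockmass"


class ChannelRuleError(ValueError):
    """Raised when scans cannot be assigned a channel, or a channel is absent."""


@dataclass
class Spectrum:
    """One centroided scan: retention time (minutes), channel, sorted peaks."""

    rt: float
    channel: Channel
    mz: np.ndarray
    intensity: np.ndarray
    centroided: bool = True

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.rt < 0:
            raise ValueError(f"negative retention time {self.rt}")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z values must be strictly increasing")
        if self.intensity.size and (np.any(~np.isfinite(self.intensity))
                                    or np.any(self.intensity < 0)):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class Run:
    """An ordered sequence of spectra plus batch metadata."""

    spectra: list[Spectrum]
    sample_id: str = ""
    group: str = ""
    injection_order: int = 1
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be ordered by non-decreasing retention time")
        if self.injection_order < 1:
            raise ValueError("injection_order must be a positive integer")

    def spectra_in(self, channel: Channel) -> list[Spectrum]:
        return [s for s in self.spectra if s.channel == channel]

    def span(self) -> tuple[float, float]:
        if not self.spectra:
            raise ValueError("empty run")
        return (self.spectra[0].rt, self.spectra[-1].rt)

    def check_scan_interval(self, cv_limit: float = 0.20) -> Optional[float]:
        """Report the CV of low-energy scan intervals; warn if above limit."""
        low = self.spectra_in(Channel.LOW_ENERGY)
        if len(low) < 3:
            return None
        dt = np.diff([s.rt for s in low])
        if dt.mean() <= 0:
            return None
        cv = float(dt.std() / dt.mean())
        if cv > cv_limit:
            warnings.warn(
                f"scan interval irregular: CV {cv:.0%} exceeds {cv_limit:.0%}",
                stacklevel=2,
            )
        return cv


@dataclass(frozen=True)
class ChannelRules:
    """Rules mapping scan metadata to acquisition channels.

    A scan is a lock-mass scan if it carries the ``lock mass scan`` flag;
    otherwise it is high-energy if a collision-energy ramp is recorded (or
    the fixed collision energy exceeds ``low_max_ev``), else low-energy.
    ``filter_patterns`` optionally maps channels to regexes matched against
    the vendor filter string, taking precedence when they match.
    """

    low_max_ev: float = 4.0
    filter_patterns: dict[str, str] = field(default_factory=dict)

    def assign(self, params: dict) -> Optional[Channel]:
        fs = params.get("filter string")
        if fs:
            for chan, pat in self.filter_patterns.items():
                if re.search(pat, str(fs)):
                    return Channel(chan)
        if params.get("lock mass scan"):
            return Channel.LOCKMASS
        if "collision energy ramp start" in params:
            return Channel.HIGH_ENERGY
        ce = params.get("collision energy")
        if ce is not None:
            return (Channel.LOW_ENERGY if float(ce) <= self.low_max_ev
                    else Channel.HIGH_ENERGY)
        return None


# ---------------------------------------------------------------------------
# writing

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


_CHANNEL_PARAMS = {
    Channel.LOW_ENERGY: (
        '<userParam name="collision energy" value="2.0" type="xsd:float"/>'
    ),
    Channel.HIGH_ENERGY: (
        '<userParam name="collision energy ramp start" value="15.0" type="xsd:float"/>'
        '<userParam name="collision energy ramp end" value="40.0" type="xsd:float"/>'
    ),
    Channel.LOCKMASS: (
        '<userParam name="lock mass scan" value="true" type="xsd:boolean"/>'
    ),
}


def write_run(run: Run, path: "str | Path") -> None:
    """Serialize a run to mzML 1.1.0.

    Peaks are stored as uncompressed 64-bit floats (lossless to well beyond
    6 significant digits); batch metadata goes into run-level user
    parameters.  The output is readable by :func:`read_run` and by any
    mzML-aware tool.
    """
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>\n')
    parts.append(f'<mzML xmlns="{_MZML_NS}" version="1.1.0">\n')
    parts.append(
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        '</cvList>\n'
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        '</fileContent></fileDescription>\n'
        '<softwareList count="1"><software id="pciqc" version="0.1.0">'
        '<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="pciqc"/>'
        '</software></softwareList>\n'
        '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">'
        '<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>'
        '</instrumentConfiguration></instrumentConfigurationList>\n'
        '<dataProcessingList count="1"><dataProcessing id="dp1">'
        '<processingMethod order="1" softwareRef="pciqc">'
        '<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>'
        '</processingMethod></dataProcessing></dataProcessingList>\n'
    )
    parts.append('<run id="run1" defaultInstrumentConfigurationRef="IC1">\n')
    meta = {
        "sample_id": run.sample_id,
        "group": run.group,
        "injection_order": str(run.injection_order),
        **run.metadata,
    }
    for key, val in meta.items():
        parts.append(f'<userParam name={quoteattr(str(key))} value={quoteattr(str(val))}/>\n')
    parts.append(f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="dp1">\n')
    for i, sp in enumerate(run.spectra):
        if sp.mz.size and np.any(np.diff(sp.mz) <= 0):
            raise ValueError(f"spectrum {i}: peaks not sorted by m/z")
        mode = ('<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
                if sp.centroided else
                '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>')
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{sp.mz.size}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
            f'{mode}{_CHANNEL_PARAMS[sp.channel]}'
            '<scanList count="1">'
            '<cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>'
            '<scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{sp.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
            '</scan></scanList>'
            '<binaryDataArrayList count="2">'
        )
        mz64, it64 = _b64(sp.mz), _b64(sp.intensity)
        parts.append(
            f'<binaryDataArray encodedLength="{len(mz64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<binary>{mz64}</binary></binaryDataArray>'
            f'<binaryDataArray encodedLength="{len(it64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            f'<binary>{it64}</binary></binaryDataArray>'
            '</binaryDataArrayList></spectrum>\n'
        )
    parts.append('</spectrumList>\n</run>\n</mzML>\n')
    Path(path).write_text("".join(parts))


# ---------------------------------------------------------------------------
# reading

def _read_run_metadata(path: "str | Path") -> dict[str, str]:
    meta: dict[str, str] = {}
    for event, elem in ET.iterparse(str(path), events=("start", "end")):
        tag = elem.tag.rsplit("}", 1)[-1]
        if event == "end" and tag == "userParam":
            meta.setdefault(elem.get("name"), elem.get("value", ""))
        elif event == "start" and tag == "spectrumList":
            break
    return meta


def _centroid_profile(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak picking with 3-point parabolic apex interpolation."""
    if mz.size < 3:
        return mz, inten
    y = inten
    apex = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    out_mz, out_it = [], []
    for i in apex:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        step = 0.5 * (mz[i + 1] - mz[i - 1])
        out_mz.append(mz[i] + delta * step)
        out_it.append(y1 - 0.25 * (y0 - y2) * delta)
    return np.asarray(out_mz), np.asarray(out_it)


def _decode_binary_array(bda: ET.Element) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    dtype = "<f8"
    compressed = False
    for cv in bda.iter():
        if cv.tag.rsplit("}", 1)[-1] != "cvParam":
            continue
        acc = cv.get("accession", "")
        if acc == "MS:1000521":  # 32-bit float
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":  # zlib compression
            compressed = True
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        import zlib

        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum_elem(elem: ET.Element) -> tuple[float, dict, np.ndarray, np.ndarray, bool]:
    """Extract (rt_minutes, params, mz, intensity, centroided) from <spectrum>."""
    params: dict[str, object] = {}
    centroided = False
    rt_min = 0.0
    for node in elem.iter():
        tag = node.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            name = node.get("name", "")
            if name == "centroid spectrum":
                centroided = True
            elif name == "scan start time":
                val = float(node.get("value", "0"))
                unit = node.get("unitName", "minute")
                rt_min = val / 60.0 if unit.startswith("second") else val
            else:
                params[name] = node.get("value", "")
        elif tag == "userParam":
            params[node.get("name", "")] = node.get("value", "")
    arrays: dict[str, np.ndarray] = {}
    for bda in elem.iter(f"{{{_MZML_NS}}}binaryDataArray"):
        names = {cv.get("name") for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")}
        data = _decode_binary_array(bda)
        if "m/z array" in names:
            arrays["mz"] = data
        elif "intensity array" in names:
            arrays["intensity"] = data
    mz = arrays.get("mz", np.empty(0))
    it = arrays.get("intensity", np.empty(0))
    return rt_min, params, mz, it, centroided


def read_run(path: "str | Path",
             channel_rules: Optional[ChannelRules] = None) -> Run:
    """Read an mzML file into a :class:`Run`.

    Every scan is assigned exactly one channel from its collision-energy
    metadata via ``channel_rules``; retention times are converted to minutes
    honoring the mzML unit term; profile scans are centroided on load.
    Raises :class:`ChannelRuleError` if a scan cannot be assigned or no
    low-energy scan exists.
    """
    rules = channel_rules or ChannelRules()
    spectra: list[Spectrum] = []
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, elem in context:
            if elem.tag.rsplit("}", 1)[-1] != "spectrum":
                continue
            rt_min, params, mz, it, centroided = _parse_spectrum_elem(elem)
            chan = rules.assign(params)
            if chan is None:
                raise ChannelRuleError(
                    f"scan {elem.get('id')!r}: no channel rule matches its metadata"
                )
            if not centroided and mz.size:
                mz, it = _centroid_profile(mz, it)
                centroided = True
            spectra.append(Spectrum(rt=rt_min, channel=chan, mz=mz,
                                    intensity=it, centroided=centroided))
            elem.clear()
    except ChannelRuleError:
        raise
    except ET.ParseError as exc:
        raise ValueError(
            f"cannot parse mzML file {path}: {exc} (line/column {exc.position})"
        ) from exc
    except Exception as exc:
        raise ValueError(f"cannot parse mzML file {path}: {exc}") from exc
    if not any(s.channel == Channel.LOW_ENERGY for s in spectra):
        raise ChannelRuleError(f"{path}: no scans matched the low_energy rule")
    meta = _read_run_metadata(path)
    sample_id = meta.pop("sample_id", "")
    group = meta.pop("group", "")
    try:
        injection_order = int(meta.pop("injection_order", "1"))
    except ValueError:
        injection_order = 1
    run = Run(spectra=spectra, sample_id=sample_id, group=group,
              injection_order=injection_order, metadata=meta)
    run.check_scan_interval()
    return run


def load_batch_metadata(path: "str | Path"):
    """Read a batch sidecar TSV (path, sample_id, group, injection_order, role)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"path", "sample_id", "group", "injection_order", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"batch metadata {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# lock-mass correction

def _find_reference(sp: Spectrum, reference_mz: float, search_ppm: float) -> Optional[float]:
    lo, hi = ppm_window(reference_mz, search_ppm)
    i0 = np.searchsorted(sp.mz, lo, side="left")
    i1 = np.searchsorted(sp.mz, hi, side="right")
    if i1 <= i0:
        return None
    j = i0 + int(np.argmax(sp.intensity[i0:i1]))
    return float(sp.mz[j])


def lockmass_correct(run: Run,
                     reference_mz: float = LOCKMASS_MZ,
                     interval: float = 10.0,
                     n_average: int = 3,
                     search_ppm: float = 50.0) -> Run:
    """Single-point lock-mass recalibration of the m/z axis.

    The run is divided into consecutive windows of ``interval`` seconds.  In
    each window the observed m/z of the reference ion (most intense peak
    within ``search_ppm`` of ``reference_mz``) is averaged over up to
    ``n_average`` lock-mass observations, and the resulting multiplicative
    ppm correction is applied to every peak of every scan in that window.
    Windows without an observation inherit the previous window's correction
    (logged); if the reference is never found the run is returned unchanged
    with a warning.

    Lock-mass observations come from dedicated lock-mass scans when present,
    otherwise from the reference ion in the low-energy channel (the lock
    compound is infused continuously, so it is visible there too).
    """
    if not run.spectra:
        return run
    source = run.spectra_in(Channel.LOCKMASS) or run.spectra_in(Channel.LOW_ENERGY)
    obs_t, obs_mz = [], []
    for sp in source:
        m = _find_reference(sp, reference_mz, search_ppm)
        if m is not None:
            obs_t.append(sp.rt)
            obs_mz.append(m)
    if not obs_t:
        warnings.warn(
            f"lock mass {reference_mz} not found within +/-{search_ppm} ppm in any scan; "
            "run left uncorrected"
        )
        return replace(run, spectra=[replace(s) for s in run.spectra])
    obs_t_arr = np.asarray(obs_t)
    obs_mz_arr = np.asarray(obs_mz)

    t0, t1 = run.span()
    step = interval / 60.0  # minutes
    n_iv = max(1, math.ceil((t1 - t0) / step + 1e-12))
    factors = np.empty(n_iv)
    prev = 1.0
    for k in range(n_iv):
        lo_t, hi_t = t0 + k * step, t0 + (k + 1) * step
        inside = np.flatnonzero((obs_t_arr >= lo_t) & (obs_t_arr < hi_t))
        if inside.size == 0:
            logger.info("lock-mass interval %d (%.2f-%.2f min): no observation, "
                        "carrying previous correction", k, lo_t, hi_t)
            factors[k] = prev
            continue
        center = 0.5 * (lo_t + hi_t)
        take = inside[np.argsort(np.abs(obs_t_arr[inside] - center))][:n_average]
        factors[k] = reference_mz / float(obs_mz_arr[take].mean())
        prev = factors[k]

    corrected = []
    for sp in run.spectra:
        k = min(n_iv - 1, int((sp.rt - t0) / step))
        corrected.append(replace(sp, mz=sp.mz * factors[k],
                                 intensity=sp.intensity.copy()))
    return replace(run, spectra=corrected)
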