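"""Shared fixtures: scaled-down scenario configs and random-run builders.

Test scenarios use shorter scans / fewer standards than the full acquisition
defaults so the suite stays fast; the geometry (gradient length, event
windows) matches the defaults so boundary checks stay meaningful.
"""

from dataclasses import replace

import numpy as np
import pytest

from pciqc.masses import default_panel
from pciqc.msdata_io import Channel, Run, Spectrum
from pciqc.simulate import NoiseModel, ScenarioConfig, SuppressionEvent


@pytest.fixture
def panel1():
    """Single-standard panel (atenolol-d7) for fast pipelines."""
    return default_panel()[:1]


@pytest.fixture
def small_config(panel1):
    """1 standard, 0.5 s scans, full 5-min cycle, default 5% noise."""
    return ScenarioConfig(standards=panel1, scan_interval=0.5)


@pytest.fixture
def clean_config(panel1):
    """Noise-free variant: traces are exactly flat in the null scenario."""
    return ScenarioConfig(standards=panel1, scan_interval=0.5,
                          noise=NoiseModel(cv=0.0, additive=0.0))


def make_box_config(panel, depth=0.8, start=2.75, end=3.25, cv=0.05,
                    scan_interval=0.5):
    """Config with one hard-edged suppression event over [start, end]."""
    ev = SuppressionEvent(center=0.5 * (start + end), width=end - start,
                          depth=depth, shape="box")
    return ScenarioConfig(standards=panel, scan_interval=scan_interval,
                          events=(ev,), noise=NoiseModel(cv=cv, additive=1.0))


def random_run(rng, n_spectra=20, channels=(Channel.LOW_ENERGY,
                                            Channel.HIGH_ENERGY)):
    """A random (but valid) two-channel run for oracle/round-trip tests."""
    spectra = []
    rt = 0.0
    for i in range(n_spectra):
        rt += float(rng.uniform(0.001, 0.02))
        n_peaks = int(rng.integers(0, 30))
        mz = np.sort(rng.uniform(50, 850, n_peaks))
        if mz.size:
            mz = mz[np.concatenate(([True], np.diff(mz) > 1e-9))]
        inten = rng.uniform(0, 1e5, mz.size)
        spectra.append(Spectrum(rt=rt, channel=channels[i % len(channels)],
                                mz=mz, intensity=inten))
    return Run(spectra=spectra, sample_id=f"rand{int(rng.integers(1e6))}",
               group="test", injection_order=int(rng.integers(1, 50)),
               metadata={"k": "v"})
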