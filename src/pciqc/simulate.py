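"""Seeded synthetic LC-MS run and batch generator.

The simulator emulates a postcolumn-infusion acquisition: every infusion
standard contributes a constant ion in the low-energy channel whose
intensity is attenuated multiplicatively by ion-suppression events
(ionization competition scales signal, it does not subtract from it), a
phospholipid band adds precursor ions in the low-energy channel and the
phosphocholine fragment in the high-energy channel within its elution
window, and a polymer (PEG) ladder adds an arithmetic m/z progression.
Batches modulate event depths per injection to reproduce the dip-recovery
response pattern caused by column buildup of matrix compounds.

All randomness flows from a single integer seed, so identical
(config, seed) pairs produce bit-identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .masses import LOCKMASS_MZ, default_panel, PanelStandard
from .msdata_io import Channel, Run, Spectrum

#: Physically exact phosphocholine fragment m/z (C5H15NO4P+); the diagnostic
#: screen centers on the instrument-rounded 184.075 with a window wide enough
#: to cover both.
PHOSPHOCHOLINE_FRAGMENT_MZ = 184.0733

#: Monoisotopic ethylene-oxide repeat unit (C2H4O), the PEG ladder spacing.
ETHYLENE_OXIDE_REPEAT = 44.0262


@dataclass(frozen=True)
class GradientProgram:
    """Piecewise-linear mobile-phase program as (time min, %B) breakpoints."""

    breakpoints: Sequence[tuple[float, float]]

    def __post_init__(self):
        bp = [(float(t), float(b)) for t, b in self.breakpoints]
        if not bp or bp[0][0] != 0.0:
            raise ValueError("gradient must start with a breakpoint at t=0")
        times = [t for t, _ in bp]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("gradient breakpoint times must be strictly increasing")
        if any(not 0.0 <= b <= 100.0 for _, b in bp):
            raise ValueError("%B must lie in [0, 100]")
        object.__setattr__(self, "breakpoints", tuple(bp))


def gradient_fraction(program: GradientProgram, t: float) -> float:
    """Organic fraction %B at time ``t`` (minutes), constant after the end."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    times = np.array([p[0] for p in program.breakpoints])
    fracs = np.array([p[1] for p in program.breakpoints])
    return float(np.interp(t, times, fracs))


def default_gradient() -> GradientProgram:
    """5-min reversed-phase cycle: hold 0%B to 0.3 min, ramp to 100%B at
    3.0 min, hold to 3.5 min, return by 3.6 min, re-equilibrate to 5 min."""
    return GradientProgram([(0.0, 0.0), (0.3, 0.0), (3.0, 100.0),
                            (3.5, 100.0), (3.6, 0.0), (5.0, 0.0)])


@dataclass(frozen=True)
class SuppressionEvent:
    """A matrix-effect event multiplying standard intensities by (1 - depth).

    ``width`` is the full width at half depth for the gaussian shape, or the
    full (hard-edged) width for the box shape.  ``weights`` optionally scales
    the depth per standard name (1.0 where omitted).  ``modulated`` events
    respond to per-injection batch modulation.  Negative depth models ion
    enhancement (ratio above 1).
    """

    center: float
    width: float
    depth: float
    shape: str = "gaussian"
    weights: Optional[dict[str, float]] = None
    modulated: bool = False

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("event width must be positive")
        if not -1.0 <= self.depth <= 1.0:
            raise ValueError("event depth must lie in [-1, 1]")
        if self.shape not in ("gaussian", "box"):
            raise ValueError(f"unknown event shape {self.shape!r}")

    def depth_at(self, t: np.ndarray, weight: float = 1.0) -> np.ndarray:
        if self.shape == "box":
            active = np.abs(np.asarray(t) - self.center) <= self.width / 2.0
            return self.depth * weight * active
        sigma = self.width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return self.depth * weight * np.exp(-0.5 * ((np.asarray(t) - self.center) / sigma) ** 2)


@dataclass(frozen=True)
class PhospholipidBand:
    """Late-eluting phospholipid envelope: precursors in the low-energy
    channel, the phosphocholine fragment in the high-energy channel."""

    rt_start: float = 2.75
    rt_end: float = 3.25
    fragment_mz: float = PHOSPHOCHOLINE_FRAGMENT_MZ
    precursor_mzs: Sequence[float] = (496.3398, 524.3711, 758.5694, 786.6007)
    intensity: float = 5e4

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Bell-shaped elution envelope confined to the window."""
        t = np.asarray(t)
        mid = 0.5 * (self.rt_start + self.rt_end)
        sigma = (self.rt_end - self.rt_start) / 4.0
        env = np.exp(-0.5 * ((t - mid) / sigma) ** 2)
        env[(t < self.rt_start) | (t > self.rt_end)] = 0.0
        return env


@dataclass(frozen=True)
class PolymerLadder:
    """PEG-style oligomer series eluting in a window."""

    start_mz: float = 300.10
    repeat: float = ETHYLENE_OXIDE_REPEAT
    n_members: int = 10
    rt_start: float = 1.3
    rt_end: float = 1.7
    intensity: float = 3e4

    def member_mzs(self) -> np.ndarray:
        return self.start_mz + self.repeat * np.arange(self.n_members)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise (per peak), a small additive baseline
    on infused-ion peaks, an optional per-run (injection-to-injection)
    intensity scale CV, and optional m/z jitter in ppm."""

    cv: float = 0.05
    additive: float = 1.0
    run_cv: float = 0.0
    mz_jitter_ppm: float = 0.0

    def __post_init__(self):
        if self.cv < 0 or self.run_cv < 0 or self.additive < 0 or self.mz_jitter_ppm < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one synthetic acquisition."""

    gradient: GradientProgram = field(default_factory=default_gradient)
    standards: Sequence[PanelStandard] = field(default_factory=default_panel)
    events: Sequence[SuppressionEvent] = ()
    band: Optional[PhospholipidBand] = None
    ladder: Optional[PolymerLadder] = None
    noise: NoiseModel = NoiseModel()
    mass_error_ppm: "float | tuple[float, float]" = 0.0
    scan_interval: float = 0.1  # seconds per function; cycle = 2x (two channels)
    run_length: float = 5.0  # minutes
    include_lockmass: bool = True
    lockmass_mz: float = LOCKMASS_MZ
    lockmass_intensity: float = 2e4

    def __post_init__(self):
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be positive")
        if self.run_length <= 0:
            raise ValueError("run_length must be positive")

    def mass_error_at(self, t: np.ndarray) -> np.ndarray:
        """ppm mass error at time t: constant, or linear drift (start, end)."""
        t = np.asarray(t, dtype=float)
        if isinstance(self.mass_error_ppm, (tuple, list)):
            e0, e1 = self.mass_error_ppm
            return e0 + (e1 - e0) * np.clip(t / self.run_length, 0.0, 1.0)
        return np.full_like(t, float(self.mass_error_ppm))


@dataclass(frozen=True)
class BatchModulation:
    """Per-injection multipliers applied to the depth of modulated events."""

    pattern: Sequence[float]
    n_injections: int

    def __post_init__(self):
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        if len(self.pattern) != self.n_injections:
            raise ValueError(
                f"pattern length {len(self.pattern)} != n_injections {self.n_injections}"
            )
        if any(m < 0 for m in self.pattern):
            raise ValueError("modulation multipliers must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def simulate_run(config: ScenarioConfig, seed: int,
                 sample_id: str = "sim", group: str = "sample",
                 injection_order: int = 1) -> Run:
    """Generate one two-channel run from a scenario.

    With ``noise.cv == 0`` and no events every standard's extracted trace is
    exactly flat at its baseline intensity; suppression events attenuate it
    multiplicatively, so a profile ratio against a clean reference recovers
    event depth directly.
    """
    if not config.standards:
        raise ValueError("standards panel is empty")
    rng = np.random.default_rng(seed)
    run_scale = float(_lognormal_factors(rng, config.noise.run_cv, ()))

    cycle = 2.0 * config.scan_interval / 60.0  # minutes between low-energy scans
    n_cycles = int(config.run_length / cycle)
    t_low = np.arange(n_cycles) * cycle
    t_high = t_low + config.scan_interval / 60.0

    names = [s.name for s in config.standards]
    std_mz = np.array([s.target_mz() for s in config.standards])
    std_base = np.array([s.baseline_intensity for s in config.standards])

    # multiplicative suppression factor per (scan, standard)
    factor = np.ones((n_cycles, len(names)))
    for ev in config.events:
        for j, nm in enumerate(names):
            w = 1.0 if ev.weights is None else float(ev.weights.get(nm, 1.0))
            factor[:, j] *= 1.0 - np.clip(ev.depth_at(t_low, w), -1.0, 1.0)
    std_int = (std_base[None, :] * factor
               * _lognormal_factors(rng, config.noise.cv, (n_cycles, len(names)))
               * run_scale)
    if config.noise.additive > 0:
        std_int = std_int + rng.uniform(0, 2 * config.noise.additive,
                                        size=std_int.shape)

    cols = [(m, "std", j) for j, m in enumerate(std_mz)]
    if config.include_lockmass:
        lock_int = (config.lockmass_intensity
                    * _lognormal_factors(rng, config.noise.cv, (n_cycles,)))
        cols.append((config.lockmass_mz, "lock", 0))
    band_int = ladder_int = None
    if config.band is not None:
        env = config.band.envelope(t_low)
        rel = np.linspace(1.0, 0.5, len(config.band.precursor_mzs))
        band_int = (config.band.intensity * env[:, None] * rel[None, :]
                    * _lognormal_factors(rng, config.noise.cv,
                                         (n_cycles, len(config.band.precursor_mzs))))
        for j, m in enumerate(config.band.precursor_mzs):
            cols.append((m, "band", j))
    if config.ladder is not None:
        lad_mz = config.ladder.member_mzs()
        in_win = ((t_low >= config.ladder.rt_start)
                  & (t_low <= config.ladder.rt_end)).astype(float)
        ladder_int = (config.ladder.intensity * in_win[:, None]
                      * _lognormal_factors(rng, config.noise.cv,
                                           (n_cycles, len(lad_mz))))
        for j, m in enumerate(lad_mz):
            cols.append((m, "ladder", j))

    cols.sort(key=lambda c: c[0])
    low_mz = np.array([c[0] for c in cols])
    if np.any(np.diff(low_mz) <= 0):
        raise ValueError("m/z collision between simulated species; adjust the scenario")
    low_int = np.empty((n_cycles, len(cols)))
    for k, (_, kind, j) in enumerate(cols):
        if kind == "std":
            low_int[:, k] = std_int[:, j]
        elif kind == "lock":
            low_int[:, k] = lock_int
        elif kind == "band":
            low_int[:, k] = band_int[:, j]
        else:
            low_int[:, k] = ladder_int[:, j]

    err_low = config.mass_error_at(t_low) * 1e-6
    err_high = config.mass_error_at(t_high) * 1e-6
    jitter = config.noise.mz_jitter_ppm * 1e-6

    frag_env = None
    if config.band is not None:
        frag_env = (config.band.intensity * config.band.envelope(t_high)
                    * _lognormal_factors(rng, config.noise.cv, (n_cycles,)))

    spectra: list[Spectrum] = []
    for i in range(n_cycles):
        mz_i = low_mz * (1.0 + err_low[i])
        if jitter > 0:
            mz_i = np.sort(mz_i * (1.0 + rng.normal(0.0, jitter, size=mz_i.size)))
        keep = low_int[i] > 0
        spectra.append(Spectrum(rt=float(t_low[i]), channel=Channel.LOW_ENERGY,
                                mz=mz_i[keep], intensity=low_int[i][keep]))
        if frag_env is not None and frag_env[i] > 0:
            fmz = config.band.fragment_mz * (1.0 + err_high[i])
            if jitter > 0:
                fmz *= 1.0 + rng.normal(0.0, jitter)
            hmz = np.array([fmz])
            hint = np.array([frag_env[i]])
        else:
            hmz = np.empty(0)
            hint = np.empty(0)
        spectra.append(Spectrum(rt=float(t_high[i]), channel=Channel.HIGH_ENERGY,
                                mz=hmz, intensity=hint))
    return Run(spectra=spectra, sample_id=sample_id, group=group,
               injection_order=injection_order,
               metadata={"scenario_seed": str(seed)})


def simulate_batch(config: ScenarioConfig, modulation: BatchModulation,
                   seed: int, group: str = "sample",
                   sample_prefix: str = "inj") -> list[Run]:
    """Simulate a batch of injections with per-injection event modulation.

    Injection ``i`` (1-based ``injection_order``) multiplies the depth of
    every ``modulated`` event by ``modulation.pattern[i-1]`` (clipped to
    [-1, 1]).  Per-run seeds derive deterministically from the master seed,
    so different master seeds change noise realizations but never the event
    structure.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=modulation.n_injections)
    runs = []
    for i, mult in enumerate(modulation.pattern):
        events = tuple(
            replace(ev, depth=float(np.clip(ev.depth * mult, -1.0, 1.0)))
            if ev.modulated else ev
            for ev in config.events
        )
        cfg_i = replace(config, events=events)
        runs.append(simulate_run(cfg_i, int(child_seeds[i]),
                                 sample_id=f"{sample_prefix}_{i + 1:02d}",
                                 group=group, injection_order=i + 1))
    return runs


def scenario_library() -> dict[str, ScenarioConfig]:
    """Named presets covering the study situations.

    - ``solvent``: clean reference injection — no events, band or ladder.
    - ``ppt_plasma``: protein-precipitated plasma — strong late suppression
      (2.75-3.25 min) with a co-eluting phospholipid band.
    - ``ostro_plasma``: the same sample after phospholipid-removal cleanup —
      residual shallow suppression, band attenuated 20-fold.
    - ``citrate`` / ``heparin``: plasma stored in citrate vs heparin tubes;
      heparin adds a PEG ladder and suppression near 1.5 min.
    - ``buildup_urine``: urine batch scenario with a modulated late event
      (and a phospholipid band) for injection-order dip-recovery studies.
    """
    band = PhospholipidBand()
    return {
        "solvent": ScenarioConfig(),
        "ppt_plasma": ScenarioConfig(
            events=(SuppressionEvent(center=3.0, width=0.5, depth=0.8, shape="box"),),
            band=band,
        ),
        "ostro_plasma": ScenarioConfig(
            events=(SuppressionEvent(center=3.0, width=0.5, depth=0.15, shape="box"),),
            band=replace(band, intensity=band.intensity / 20.0),
        ),
        "citrate": ScenarioConfig(),
        "heparin": ScenarioConfig(
            events=(SuppressionEvent(center=1.5, width=0.4, depth=0.7, shape="box"),),
            ladder=PolymerLadder(),
        ),
        "buildup_urine": ScenarioConfig(
            events=(SuppressionEvent(center=3.2, width=0.4, depth=0.2,
                                     shape="gaussian", modulated=True),),
            band=PhospholipidBand(rt_start=3.0, rt_end=3.4, intensity=2e4),
        ),
    }


def get_scenario(name: str) -> ScenarioConfig:
    lib = scenario_library()
    try:
        return lib[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(lib)}"
        ) from None


#: Default dip-recovery modulation for batch studies: normal response for two
#: injections, a three-injection buildup episode, then recovery.
DEFAULT_DIP_PATTERN = (1.0, 1.0, 3.0, 3.0, 3.0, 1.0, 1.0, 1.0)
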