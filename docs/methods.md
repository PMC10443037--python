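# Methods

## The postcolumn-infusion model

A PCI standard is infused at constant concentration downstream of the
column, so in the absence of matrix effect its monitored ion produces a
flat trace over the run. Ion suppression acts by ionization competition,
which scales the available signal rather than subtracting from it; the
simulator and the analysis therefore treat matrix effect as multiplicative.
For standard *s* with baseline response `B_s`, the simulated low-energy
trace is

```
I_s(t) = B_s · Π_e (1 − d_e(t) · w_{e,s}) · ε(t) · c + a(t)
```

where `d_e(t)` is the depth profile of event *e* (gaussian with
full-width-at-half-depth `width`, or a hard-edged box), `w_{e,s}` an
optional per-standard weight, `ε(t)` unit-mean log-normal noise with
coefficient of variation `cv`, `c` a per-injection log-normal scale factor
with CV `run_cv`, and `a(t)` a small uniform additive baseline. Under this
model the profile ratio `R(t) = I_sample(t)/I_reference(t)` of a noise-free
run recovers `Π(1 − d)` exactly, which is what makes simulated events a
usable ground truth for region-detection tests.

## Acquisition model

The two MSe-style functions (low collision energy for intact ions, a
collision-energy ramp for nonselective fragments) are encoded as MS1 scans
distinguished by collision-energy user parameters in mzML; channel
assignment on read is an explicit rule table (`collision energy ≤ 4 eV →
low_energy`, ramp present → `high_energy`, lock-mass flag → `lockmass`),
with optional vendor filter-string regexes taking precedence. Retention
time is minutes everywhere internally; the mzML unit term is honored on
read. Profile-mode input is centroided on load by local maxima with
3-point parabolic apex interpolation.

Defaults mirror the acquisition the toolkit models: 0.1 s scan time per
function (alternating, so the per-channel sampling interval is 0.2 s), a
5-min gradient cycle (aqueous hold to 0.3 min, linear ramp to 100 %B at
3.0 min, hold to 3.5 min, return and re-equilibrate to 5 min), lock-mass
correction every 10 s averaged over 3 observations against leucine
enkephalin.

### Lock mass conventions

The stored reference 556.2771 equals the monoisotopic mass of C28H37N5O7
plus a hydrogen *atom* — the vendor convention that ignores the electron
removed with the charge. The electron-corrected ion value is 556.2766
(lighter by m_e = 0.00055 Da, ~1 ppm at this mass). User panels default to
`electron_correction=True` (physically exact), but the lock-mass constant
is kept verbatim in the instrument convention to avoid introducing a
systematic 1 ppm offset against instrument-reported axes. Neither
convention is asserted as "correct"; both are exposed on `AdductSpec`.

Correction is applied per 10-s interval as a single multiplicative ppm
factor (mean of up to `n_average` observations nearest the interval
center); intervals without an observation inherit the previous factor.
Residual error is bounded by the drift accumulated within one interval,
and the operation is idempotent once the axis is corrected.

## Pipeline numerical choices

- **XIC**: per-scan sum of peak intensities within ±10 ppm of the target
  (absolute ±0.025 Da for the m/z 184.075 phosphocholine fragment, because
  the commonly quoted value differs from the formula value 184.0733 by
  ~9 mDa — more than any sensible ppm window at that mass).
- **Ratio floor**: reference points below 5 counts (5× the simulator's
  default additive baseline) are masked, never divided; masked points are
  flagged and break regions, they are never reported as 0 or ∞.
- **Smoothing**: centered moving median, window 5 scans, applied to the
  ratio (not the raw traces) so single-scan spikes vanish without biasing
  plateau depth; window ends shrink symmetrically; masked points enter as
  NaN so they never drag the median near gaps.
- **Region detection**: thresholds `low = 0.7`, `high = 1.4`; regions
  shorter than 0.05 min dropped; same-kind regions separated by ≤ 0.03 min
  of fully valid points merged (merge before the width filter, so split
  halves of one event survive). The thresholds are deliberately tunable
  config: "significant" suppression is a lab policy, not a universal
  constant.
- **Polymer series**: peaks ≥ 1 % of the base peak are chained greedily
  from every (anchor, partner) pair with spacing in [40, 50] Da, extending
  while a peak lies within ±0.02 Da of the next expected position (the
  expectation re-anchors on each found member so centroid error does not
  accumulate). Chains with ≥ 5 members are refit by least squares — exact
  on noise-free ladders — and accepted longest-first with ties broken by
  summed intensity then starting m/z; members of accepted series cannot
  anchor further series. Charge state is not assigned; spacing is reported
  as observed on the m/z axis.
- **Phospholipid screen**: verdict positive when fragment enrichment
  (mean intensity inside region / outside) ≥ 3 and ≥ 50 % of the fragment's
  above-threshold span (≥ 10 % of its maximum) lies inside the region.
  Enrichment is scale-invariant by construction; when there is no fragment
  signal anywhere it is defined as 1 (nothing to attribute), and as ∞ when
  signal exists only inside the region.

## Batch monitoring

Per injection and standard the toolkit records the median trace intensity
(the reported "response"), the median and 5th-percentile ("trough") of the
smoothed ratio profile, and the suppressed time fraction. The median
response is deliberately robust to localized suppression, which also makes
it blind to narrow transient events — so dip-recovery (buildup) detection
runs on the **trough ratio** series instead: a localized episode moves the
5th percentile from ≈ 0.9 (noise floor of a clean profile) to the event
depth, independent of where in the gradient it elutes.

`detect_buildup` flags injection *i* when its metric falls below
`(1 − drop)` × a rolling baseline (median of up to 5 preceding non-flagged
injections, initialized from the first injection — buildup episodes return
"to the initial values", so the baseline must exclude flagged points). A
maximal span of ≥ k consecutive flagged injections followed by a recovered
one is a buildup event; a flagged span running to the end of the series, or
an overall monotone decay ≥ `drop`, is drift. Defaults `drop = 0.25`,
`k = 2`.

Intragroup RSD (100·sd/mean, n−1 denominator) is computed per group and
standard on median responses; the intergroup figure is the min–max range
across standards of the RSD of group means. QC verdicts apply rules in
fail → warn → pass order: fail on suppressed fraction above 0.10 for any
standard or membership in a buildup event; warn on intragroup RSD above
20 %; pass otherwise.

## What the simulator does and does not emulate

It emulates: flat infusion baselines, multiplicative suppression/
enhancement events with per-standard weights, a phospholipid band whose
precursors appear in the low-energy channel and whose phosphocholine
fragment appears in the high-energy channel with the same elution envelope,
a PEG ladder confined to an elution window, constant or linearly drifting
ppm mass error, per-peak and per-injection intensity noise, and
injection-order modulation of event depths.

It does **not** emulate chromatographic peak shapes of analytes (PCI
monitors infused standards, not eluting analytes), carryover, detector
saturation, electrospray physics, isotope fine structure, or realistic
full-scan chemical noise. Passing tests therefore demonstrate that the
algorithms recover their own model's ground truth under realistic noise
levels — not that the default thresholds are optimal for any particular
instrument, which is why all of them are exposed as configuration.

Scenario presets pin the study situations: `ppt_plasma` (box suppression
across 2.75–3.25 min with a phospholipid band; `ostro_plasma` attenuates
the band 20-fold and the event below the detection threshold),
`heparin` (suppression near 1.5 min plus a 10-member PEG ladder,
repeat 44.0262 Da — the nominal "44 Da" is the rounded ethylene-oxide
monoisotopic repeat) versus `citrate` (clean), and `buildup_urine`
(modulated late-eluting event for injection-order studies). Event depths
are chosen values — deep enough to be unambiguous (0.7–0.8 for single-run
scenarios, 0.2 base for the modulated buildup event) — since the underlying
studies report window positions, not depths. Default noise CV is 5 %,
typical of TOF trace variability.

## Problem sizes used in tests

The test suite and acceptance checks run scaled-down configurations chosen
as the smallest sizes at which the checks remain meaningful: usually one
standard, 0.5 s scan time (1 s per-channel sampling, 300 points per
5-min trace), 8-injection batches, and 20-seed repetitions for the
statistical claims (region-boundary recovery within 2 scan intervals,
buildup sensitivity ≥ 18/20 with ≤ 2/20 false events). The full default
configuration (8 standards, 0.2 s per-channel sampling, 3000 points per
trace) is exercised end-to-end in the CLI tests.

## Known limitations

- No retention-time alignment between sample and reference: grids are
  resampled linearly, not warped. Large RT shifts will smear region bounds.
- The per-injection "response" proxies instrument performance through the
  PCI standard's trace, not through any analyte's peak response; the two
  agree only insofar as the analyte ionizes like the standard at its
  retention time.
- Polymer-series detection is greedy; two interleaved ladders sharing
  members resolve in favor of the longer/more intense one.
- A global sensitivity drop in a sample injection is indistinguishable from
  whole-run suppression in the ratio; such injections fail on suppressed
  fraction rather than being separated into a sensitivity metric.
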