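"""Monoisotopic mass arithmetic for the infusion-standards panel.

Postcolumn-infusion (PCI) quality control monitors a small panel of
isotopically labelled standards whose ions must be located on the m/z axis
to better than a few ppm.  This module provides exact monoisotopic masses
from an embedded atomic-mass table, adduct m/z derivation ([M+H]+, [M+Na]+,
[M+K]+ ...), ppm tolerance windows, and the default standards panel.

Isotope labels are first-class element symbols: deuterium is ``D`` (or
``[2H]``) and carbon-13 is ``[13C]``, each with its own entry in the mass
table, because PCI panels are typically built entirely from isotopologues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

#: Version tag of the embedded monoisotopic mass table (values in Da, >= 6 dp,
#: from the IUPAC/CIAAW atomic mass evaluation).  Fixed at package build time
#: for reproducibility; never fetched at runtime.
ATOMIC_MASS_TABLE_VERSION = "CIAAW-2021/AME2020"

#: Monoisotopic atomic masses in Da.  Isotope labels (D, 13C, 15N, 18O) are
#: distinct symbols so labelled formulas stay ordinary element-count maps.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.007825032,
    "D": 2.014101778,
    "2H": 2.014101778,
    "C": 12.000000000,
    "13C": 13.003354835,
    "N": 14.003074004,
    "15N": 15.000108899,
    "O": 15.994914620,
    "18O": 17.999159613,
    "P": 30.973761998,
    "S": 31.972071174,
    "Na": 22.989769282,
    "K": 38.963706487,
    "Cl": 34.968852682,
    "F": 18.998403163,
    "Br": 78.918337601,
    "I": 126.904471853,
    "Si": 27.976926535,
}

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: The lock-mass reference m/z for leucine enkephalin, stored verbatim in the
#: H-atom convention (neutral monoisotopic mass + 1.007825, no electron
#: correction) as printed by the instrument software.  Recomputing it with
#: electron correction would introduce a ~1 ppm systematic offset.
LOCKMASS_MZ = 556.2771

#: Elemental formula of leucine enkephalin (the lock-mass compound).
LEUCINE_ENKEPHALIN_FORMULA = "C28H37N5O7"


class UnknownElementError(ValueError):
    """Raised when a formula contains a symbol absent from the mass table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"unknown element symbol {symbol!r}: not in the embedded "
            f"monoisotopic mass table ({ATOMIC_MASS_TABLE_VERSION})"
        )


class FormulaParseError(ValueError):
    """Raised when a formula string cannot be tokenized."""


_TOKEN = re.compile(r"(?:\[(?P<iso>\d+[A-Z][a-z]?)\]|(?P<el>[A-Z][a-z]?))(?P<count>\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition as a symbol -> count mapping.

    Counts are strictly positive; an empty mapping is the identity formula
    (mass zero), used e.g. for pass-through adducts.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        counts = dict(self.element_counts)
        for sym, n in counts.items():
            if sym not in MONOISOTOPIC_MASSES:
                raise UnknownElementError(sym)
            if not isinstance(n, int) or n < 1:
                raise ValueError(f"count for {sym!r} must be a positive integer, got {n!r}")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse e.g. ``C14H15D7N2O3`` or ``C8[13C]6H11Cl2NO2``.

        Isotopes are written either as the symbols ``D``/``T`` style entries
        present in the mass table or bracketed mass-number notation
        ``[13C]``; a bare leading mass number (``13C6``) is rejected because
        it is ambiguous with preceding counts.
        """
        counts: dict[str, int] = {}
        pos = 0
        text = text.strip()
        if not text:
            return cls({})
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m or m.start() != pos or not (m.group("iso") or m.group("el")):
                raise FormulaParseError(
                    f"cannot parse formula {text!r} at position {pos} "
                    f"(write isotopes as [13C], [2H] or D)"
                )
            sym = m.group("iso") or m.group("el")
            if sym not in MONOISOTOPIC_MASSES:
                raise UnknownElementError(sym)
            n = int(m.group("count") or 1)
            if n < 1:
                raise FormulaParseError(f"zero count for {sym!r} in {text!r}")
            counts[sym] = counts.get(sym, 0) + n
            pos = m.end()
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts)


def _as_formula(formula: "ElementalFormula | str") -> ElementalFormula:
    if isinstance(formula, str):
        return ElementalFormula.parse(formula)
    return formula


def monoisotopic_mass(formula: "ElementalFormula | str") -> float:
    """Exact monoisotopic mass in Da: sum of count x atomic mass."""
    f = _as_formula(formula)
    return sum(n * MONOISOTOPIC_MASSES[sym] for sym, n in f.element_counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """How a neutral molecule appears as an ion.

    m/z = (M + mass(added_formula) - electron_correction * charge * m_e) / charge.

    ``electron_correction=True`` is the physically exact positive-ion
    convention (electrons are removed with the charges); ``False`` is the
    H-atom convention many instrument vendors print, which is heavier by one
    electron mass per charge.
    """

    name: str
    added_formula: ElementalFormula
    charge: int = 1
    electron_correction: bool = True

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """m/z of the adduct ion of a neutral molecule of ``neutral_mass`` Da."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if adduct.charge < 1:
        raise ValueError("charge must be >= 1")
    m = neutral_mass + monoisotopic_mass(adduct.added_formula)
    if adduct.electron_correction:
        m -= adduct.charge * ELECTRON_MASS
    return m / adduct.charge


def ppm_window(mz: float, tol: float) -> tuple[float, float]:
    """Symmetric relative tolerance window ``mz * (1 +/- tol*1e-6)``.

    The lower bound is clamped at 0 for degenerate (huge) tolerances.
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if tol < 0:
        raise ValueError(f"ppm tolerance must be >= 0, got {tol}")
    low = mz * (1.0 - tol * 1e-6)
    high = mz * (1.0 + tol * 1e-6)
    return (max(0.0, low), high)


#: Common positive-mode adducts.  electron_correction=True by default for user
#: panels (see LOCKMASS_MZ for the one stored vendor-convention constant).
DEFAULT_ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", ElementalFormula({"H": 1})),
    "[M+Na]+": AdductSpec("[M+Na]+", ElementalFormula({"Na": 1})),
    "[M+K]+": AdductSpec("[M+K]+", ElementalFormula({"K": 1})),
}


@dataclass(frozen=True)
class PanelStandard:
    """One postcolumn-infusion standard.

    Either ``formula`` (preferred) or an explicit ``mz`` must be given.  The
    first adduct in ``adducts`` is the primary monitored ion.
    ``baseline_intensity`` is the nominal detector response used by the run
    simulator (arbitrary counts).
    """

    name: str
    formula: Optional[str] = None
    mz: Optional[float] = None
    adducts: Sequence[str] = ("[M+H]+",)
    infusion_conc_mg_per_L: float = 0.1
    baseline_intensity: float = 5e4

    def __post_init__(self):
        if self.formula is None and self.mz is None:
            raise ValueError(f"standard {self.name!r}: need a formula or an explicit m/z")

    def target_mz(self, adduct: Optional[str] = None) -> float:
        """m/z of the monitored ion (primary adduct unless named)."""
        if self.formula is None:
            return float(self.mz)  # explicit m/z entries pass through
        name = adduct or self.adducts[0]
        try:
            spec = DEFAULT_ADDUCTS[name]
        except KeyError:
            raise KeyError(f"unknown adduct {name!r} for standard {self.name!r}") from None
        return adduct_mz(monoisotopic_mass(self.formula), spec)


def default_panel() -> list[PanelStandard]:
    """The eight-standard isotopologue panel with its infusion concentrations.

    Standards span a broad polarity range (metformin to simvastatin) so that
    the matrix-effect readout covers the whole reversed-phase gradient; the
    nonpolar end (simvastatin, lacidipine) preferentially forms Na+ adducts.
    """
    return [
        PanelStandard("atenolol-d7", "C14H15D7N2O3", adducts=("[M+H]+",),
                      infusion_conc_mg_per_L=0.025, baseline_intensity=6e4),
        PanelStandard("caffeine-d3", "C8H7D3N4O2", adducts=("[M+H]+",),
                      infusion_conc_mg_per_L=0.125, baseline_intensity=8e4),
        PanelStandard("diclofenac-13C6", "C8[13C]6H11Cl2NO2", adducts=("[M+H]+",),
                      infusion_conc_mg_per_L=0.25, baseline_intensity=4e4),
        PanelStandard("lacidipine-13C8", "C18[13C]8H33NO6", adducts=("[M+Na]+", "[M+H]+"),
                      infusion_conc_mg_per_L=0.030, baseline_intensity=2e4),
        PanelStandard("metformin-d6", "C4H5D6N5", adducts=("[M+H]+",),
                      infusion_conc_mg_per_L=0.030, baseline_intensity=7e4),
        PanelStandard("nifedipine-d6", "C17H12D6N2O6", adducts=("[M+H]+",),
                      infusion_conc_mg_per_L=0.125, baseline_intensity=3e4),
        PanelStandard("simvastatin-d6", "C25H32D6O5", adducts=("[M+Na]+", "[M+H]+"),
                      infusion_conc_mg_per_L=0.125, baseline_intensity=2.5e4),
        PanelStandard("acetaminophen-d4", "C8H5D4NO2", adducts=("[M+H]+",),
                      infusion_conc_mg_per_L=0.25, baseline_intensity=9e4),
    ]


def load_panel(path: "str | Path") -> list[PanelStandard]:
    """Load a standards panel from YAML.

    Expected layout::

        standards:
          - name: atenolol-d7
            formula: C14H15D7N2O3          # or:  mz: 274.227
            adducts: ["[M+H]+"]
            infusion_conc_mg_per_L: 0.025
            baseline_intensity: 60000
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["standards"] if isinstance(doc, dict) else doc
    panel = []
    for e in entries:
        panel.append(PanelStandard(
            name=e["name"],
            formula=e.get("formula"),
            mz=e.get("mz"),
            adducts=tuple(e.get("adducts", ("[M+H]+",))),
            infusion_conc_mg_per_L=float(e.get("infusion_conc_mg_per_L", 0.1)),
            baseline_intensity=float(e.get("baseline_intensity", 5e4)),
        ))
    if not panel:
        raise ValueError(f"panel file {path} contains no standards")
    # unique adduct-qualified names
    names = [s.name for s in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate standard names in panel")
    return panel


def panel_targets(panel: Iterable[PanelStandard]) -> dict[str, float]:
    """Map standard name -> primary monitored m/z."""
    return {s.name: s.target_mz() for s in panel}
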