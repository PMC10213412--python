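"""Soil microbial physiology from 18O-water incubations and alkali titrations.

The 18O-water method measures microbial growth as incorporation of 18O
from labelled soil water into newly synthesized DNA over a short
incubation, alongside headspace CO2 accumulation for respiration:

    DNA_produced = O_total * (at%_excess/100) * (100/at%_label) * (100/31.21)
    Growth       = fDNA * DNA_produced * 1000 / (DW * t)
    Respiration  = dCO2/(22.4 * DW * t) * M * V * 1000,  M = 12.01 g/mol C
    qCO2         = Respiration / MBC
    CUE          = Growth / (Growth + Respiration)

with fDNA = MBC/DNA the biomass-to-DNA conversion factor of the
precultured soil, 31.21 the oxygen mass percentage of DNA and 22.4 the
molar gas volume (L/mol, STP; no temperature correction is applied).
Growth and respiration are in ng C per g dry soil per hour.

Carbon mineralization over a closed-jar incubation is recovered by back
titration of the NaOH trap with HCl:

    CM = c_HCl * (V0 - V1) * 22 / m_kg       [mg CO2 per kg soil]

where 22 g/mol is the equivalent mass of CO2 (two HCl per carbonate) and
m_kg the incubated soil mass in kg (0.1 for the standard 100 g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: Oxygen mass percentage of DNA.
DNA_OXYGEN_PERCENT = 31.21
#: Molar volume of an ideal gas at STP, L/mol.
MOLAR_VOLUME_STP = 22.4
#: Molar mass of carbon, g/mol.
CARBON_MOLAR_MASS = 12.01
#: Equivalent mass of CO2 in the back-titration (44.01/2, rounded as used).
CO2_EQUIVALENT_MASS = 22.0


@dataclass
class IncubationRecord:
    """Raw inputs of one 18O-CUE assay.

    Attributes
    ----------
    O_total: ug oxygen in the dried sample DNA.
    at_label: 18O atom% of the labelled soil solution.
    at_excess: atom% difference labelled minus unlabelled sample.
    DW: g soil dry weight.
    t: h incubation time.
    dCO2: ppm headspace CO2 increase.
    V: L total headspace gas volume.
    MBC: ug microbial biomass C per g soil.
    DNA_preculture: ug DNA per g of the precultured sample.
    blank_dCO2: ppm CO2 increase of the soil-free blank vial, optional.
    """

    O_total: float
    at_label: float
    at_excess: float
    DW: float
    t: float
    dCO2: float
    V: float
    MBC: float
    DNA_preculture: float
    blank_dCO2: Optional[float] = None

    def __post_init__(self):
        for name in ("O_total", "at_label", "DW", "t", "V"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.at_excess <= self.at_label:
            raise ValueError("at_excess must lie in [0, at_label]")
        if self.corrected_dCO2 < 0:
            raise ValueError("dCO2 negative after blank correction")

    @property
    def corrected_dCO2(self) -> float:
        """Blank-corrected headspace CO2 increase (ppm), floored at 0."""
        if self.blank_dCO2 is None:
            return self.dCO2
        return max(0.0, self.dCO2 - self.blank_dCO2)


@dataclass
class TitrationRecord:
    """One back-titration of the NaOH trap of a mineralization jar."""

    c_HCl: float  # mol/L
    V0: float  # mL, blank titration volume
    V1: float  # mL, sample titration volume
    soil_mass: float = 100.0  # g fresh soil incubated

    def __post_init__(self):
        if self.c_HCl <= 0:
            raise ValueError("c_HCl must be positive")
        if self.V1 < 0:
            raise ValueError("titration volumes must be non-negative")
        if self.V1 > self.V0:
            raise ValueError(
                "sample titration volume exceeds blank (over-titration)"
            )
        if self.soil_mass <= 0:
            raise ValueError("soil_mass must be positive")


def dna_produced(record: IncubationRecord) -> float:
    """Newly produced DNA (ug) over the incubation."""
    return (
        record.O_total
        * (record.at_excess / 100.0)
        * (100.0 / record.at_label)
        * (100.0 / DNA_OXYGEN_PERCENT)
    )


def growth_rate(record: IncubationRecord, dna: float) -> float:
    """Microbial growth rate (ng C/g/h) from newly produced DNA (ug).

    Uses fDNA = MBC/DNA_preculture to convert DNA to biomass C.
    """
    if record.DNA_preculture <= 0:
        raise ValueError("DNA_preculture must be positive")
    fdna = record.MBC / record.DNA_preculture
    return fdna * dna * 1000.0 / (record.DW * record.t)


def respiration_rate(record: IncubationRecord) -> float:
    """Microbial respiration rate (ng C/g/h) from headspace CO2."""
    dco2 = record.corrected_dCO2
    return (
        dco2
        / (MOLAR_VOLUME_STP * record.DW * record.t)
        * CARBON_MOLAR_MASS
        * record.V
        * 1000.0
    )


def cue_and_qco2(
    growth: float, respiration: float, mbc: float
) -> tuple[float, float]:
    """Carbon use efficiency and metabolic quotient.

    CUE = growth/(growth+respiration); NaN when both rates are zero.
    qCO2 = respiration/MBC (ng C per ug MBC per h).
    """
    if growth < 0 or respiration < 0:
        raise ValueError("rates must be non-negative")
    if mbc <= 0:
        raise ValueError("MBC must be positive")
    total = growth + respiration
    cue = growth / total if total > 0 else float("nan")
    return cue, respiration / mbc


def carbon_mineralization(
    record: TitrationRecord, *, as_carbon: bool = False
) -> float:
    """Carbon mineralization (mg CO2 per kg soil per incubation).

    ``as_carbon=True`` converts to CO2-C (x 12.01/44.01).
    """
    cm = (
        record.c_HCl
        * (record.V0 - record.V1)
        * CO2_EQUIVALENT_MASS
        / (record.soil_mass / 1000.0)
    )
    if as_carbon:
        cm *= CARBON_MOLAR_MASS / 44.01
    return cm


def process_incubation(record: IncubationRecord) -> dict:
    """Full physiology result for one incubation record."""
    dna = dna_produced(record)
    growth = growth_rate(record, dna)
    resp = respiration_rate(record)
    cue, qco2 = cue_and_qco2(growth, resp, record.MBC)
    return {
        "DNA_produced": dna,
        "fDNA": record.MBC / record.DNA_preculture,
        "growth": growth,
        "respiration": resp,
        "qCO2": qco2,
        "CUE": cue,
    }


_INCUBATION_COLS = [
    "O_total", "at_label", "at_excess", "DW", "t", "dCO2", "V",
    "MBC", "DNA_preculture",
]


def physiology_table(
    incubation: pd.DataFrame,
    titration: Optional[pd.DataFrame] = None,
    *,
    cm_as_carbon: bool = False,
) -> pd.DataFrame:
    """Per-sample physiology from tables of raw records.

    ``incubation`` needs the :class:`IncubationRecord` fields as columns
    (``blank_dCO2`` optional); ``titration``, if given, needs the
    :class:`TitrationRecord` fields and must be row-aligned by index.
    """
    missing = [c for c in _INCUBATION_COLS if c not in incubation.columns]
    if missing:
        raise ValueError(f"incubation table missing columns: {missing}")
    rows = {}
    for idx, row in incubation.iterrows():
        rec = IncubationRecord(
            **{c: float(row[c]) for c in _INCUBATION_COLS},
            blank_dCO2=(
                float(row["blank_dCO2"])
                if "blank_dCO2" in incubation.columns
                and np.isfinite(row.get("blank_dCO2", np.nan))
                else None
            ),
        )
        rows[idx] = process_incubation(rec)
    out = pd.DataFrame.from_dict(rows, orient="index")
    if titration is not None:
        cm = {}
        for idx, row in titration.iterrows():
            rec = TitrationRecord(
                c_HCl=float(row["c_HCl"]),
                V0=float(row["V0"]),
                V1=float(row["V1"]),
                soil_mass=float(row.get("soil_mass", 100.0)),
            )
            cm[idx] = carbon_mineralization(rec, as_carbon=cm_as_carbon)
        out["CM"] = pd.Series(cm)
    return out
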