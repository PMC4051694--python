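"""Spectrophotometric pigment quantitation for cyanobacterial extracts.

Phycocyanin is quantified from phosphate-buffer extracts by the
Bennett–Bogorad two-wavelength formula

    PC (mg/mL) = (A615 − 0.474 · A652) / 5.34

per cm of optical path (the A652 term corrects for allophycocyanin
absorbance at 615 nm). Chlorophyll a in 100% methanol extracts follows
Beer–Lambert with extinction coefficient 74.5 mL mg⁻¹ cm⁻¹ at 665 nm.
Both are linear in absorbance. Negative computed concentrations (possible
when A652 dominates) are reported with a warning flag, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "AbsorbanceReading",
    "PigmentResult",
    "phycocyanin_conc",
    "chlorophyll_conc",
    "process_readings",
    "PC_A652_COEFF",
    "PC_DENOM",
    "CHL_EXTINCTION",
]

PC_A652_COEFF = 0.474       # allophycocyanin correction factor
PC_DENOM = 5.34             # phycocyanin divisor, mL/mg per cm
CHL_EXTINCTION = 74.5       # chlorophyll a in methanol, mL mg^-1 cm^-1


@dataclass(frozen=True)
class AbsorbanceReading:
    od615: float = 0.0
    od652: float = 0.0
    od665: float = 0.0
    path_cm: float = 1.0
    sample: str = ""
    phase: str = ""           # light / dark
    timepoint: str = ""

    def __post_init__(self):
        if min(self.od615, self.od652, self.od665) < 0:
            raise ValueError("absorbances must be >= 0")
        if self.path_cm <= 0:
            raise ValueError("path length must be > 0")


@dataclass(frozen=True)
class PigmentResult:
    phycocyanin: Optional[float]      # mg/mL
    chlorophyll: Optional[float]      # mg/mL
    negative_flag: bool = False
    sample: str = ""
    phase: str = ""
    timepoint: str = ""


def phycocyanin_conc(reading: AbsorbanceReading,
                     a652_coeff: float = PC_A652_COEFF,
                     denom: float = PC_DENOM) -> PigmentResult:
    """Phycocyanin concentration (mg/mL) from A615/A652."""
    pc = (reading.od615 - a652_coeff * reading.od652) / (denom * reading.path_cm)
    return PigmentResult(
        phycocyanin=pc, chlorophyll=None, negative_flag=pc < 0,
        sample=reading.sample, phase=reading.phase, timepoint=reading.timepoint)


def chlorophyll_conc(reading: AbsorbanceReading,
                     extinction: float = CHL_EXTINCTION) -> PigmentResult:
    """Chlorophyll a concentration (mg/mL) from A665 in methanol."""
    chl = reading.od665 / (extinction * reading.path_cm)
    return PigmentResult(
        phycocyanin=None, chlorophyll=chl, negative_flag=chl < 0,
        sample=reading.sample, phase=reading.phase, timepoint=reading.timepoint)


def process_readings(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized pigment table: expects OD615/OD652/OD665 (+ optional path_cm)."""
    path = table["path_cm"] if "path_cm" in table else 1.0
    out = table.copy()
    out["phycocyanin_mg_ml"] = (
        (table["OD615"] - PC_A652_COEFF * table["OD652"]) / (PC_DENOM * path))
    out["chlorophyll_mg_ml"] = table["OD665"] / (CHL_EXTINCTION * path)
    out["negative_flag"] = (out["phycocyanin_mg_ml"] < 0) | (
        out["chlorophyll_mg_ml"] < 0)
    return out
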