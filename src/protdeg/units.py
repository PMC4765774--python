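"""Unit conversions between measurement signal, molecule counts, molarity
and residue flux.

The measurement proxy for per-cell abundance is fluorescence (or enzyme
activity) normalized by OD600. A calibration against purified protein puts
this on an absolute scale: roughly 10 proteins per cell per RFU·OD600⁻¹.
The calibration is coarse — converted values should be read as
order-of-magnitude estimates, which callers are reminded of via the
``coarse_calibration`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "CalibrationConstants",
    "ConfigurationError",
    "signal_to_proteins",
    "proteins_to_molar",
    "protein_rate_to_residue_rate",
    "residue_count_from_fasta",
]


class ConfigurationError(ValueError):
    """A required calibration constant is missing or invalid."""


@dataclass(frozen=True)
class CalibrationConstants:
    """Calibration constants for converting measurement units.

    Parameters
    ----------
    rfu_per_od_to_proteins : float
        Proteins·cell⁻¹ per unit of RFU·OD600⁻¹ (default 10, from a
        purified-protein fluorescence calibration).
    cell_volume : float
        Cytoplasmic volume in litres (default 1e-15 L = 1 fL, a standard
        E. coli value).
    residue_count : int, optional
        Amino-acid residues per target-protein molecule; construct-specific
        and required only for residue-flux conversion.
    coarse_calibration : bool
        Marks the signal→proteins slope as a rough correlation; propagated
        into reports so converted values are not over-read.
    """

    rfu_per_od_to_proteins: float = 10.0
    cell_volume: float = 1e-15
    residue_count: Optional[int] = None
    coarse_calibration: bool = True

    def __post_init__(self) -> None:
        if self.rfu_per_od_to_proteins <= 0:
            raise ValueError("rfu_per_od_to_proteins must be positive")
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be positive")
        if self.residue_count is not None and self.residue_count <= 0:
            raise ValueError("residue_count must be positive when set")


def _check_nonnegative(x, what: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{what} must be nonnegative")
    return arr


def signal_to_proteins(x, cal: CalibrationConstants = CalibrationConstants()):
    """RFU·OD⁻¹ (or any rate thereof) → proteins·cell⁻¹ (or rate).

    The conversion is linear, so it applies to rates unchanged.
    """
    arr = _check_nonnegative(x, "signal")
    out = arr * cal.rfu_per_od_to_proteins
    return out if out.ndim else float(out)


def proteins_to_molar(n, cal: CalibrationConstants = CalibrationConstants()):
    """Proteins·cell⁻¹ → molar concentration (mol/L) in one cell volume."""
    arr = _check_nonnegative(n, "protein count")
    out = arr / (Avogadro * cal.cell_volume)
    return out if out.ndim else float(out)


def protein_rate_to_residue_rate(r, cal: CalibrationConstants):
    """Proteins·cell⁻¹·h⁻¹ → residues·cell⁻¹·h⁻¹ (amino-acid flux).

    Useful for comparing degradation burden across proteins of different
    size (a protease processes residues, not molecules).
    """
    if cal.residue_count is None:
        raise ConfigurationError(
            "residue_count is not set; provide the construct's residue count "
            "(e.g. via residue_count_from_fasta)"
        )
    arr = _check_nonnegative(r, "rate")
    out = arr * cal.residue_count
    return out if out.ndim else float(out)


def residue_count_from_fasta(path) -> int:
    """Residue count of a construct from its amino-acid FASTA (first record).

    Stop symbols (``*``) are excluded from the count.
    """
    from Bio import SeqIO

    path = Path(path)
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"no FASTA record found in {path}")
    return len(str(record.seq).replace("*", ""))
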