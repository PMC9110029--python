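"""Sliding-window residue property profiles.

Profiles are unweighted means of per-residue scale values over an odd window
(default 9 residues), the convention of the ExPASy ProtScale service.  Three
published scales ship with the package: Kyte-Doolittle hydrophobicity,
Deleage-Roux alpha-helical propensity and Zimmerman bulkiness.  Positions
closer than half a window to either end are undefined (NaN); unknown
residues (X) are excluded from the window mean, and a window with more than
20% unknowns is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "PropertyScale",
    "CorrelationResult",
    "HYDROPHOBICITY",
    "HELICAL_PROPENSITY",
    "BULKINESS",
    "SCALES",
    "window_profile",
    "region_mean",
    "pearson_correlation",
]

# Kyte J., Doolittle R.F. (1982) hydropathy scale.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Deleage G., Roux B. (1987) alpha-helix conformational parameter.
_DELEAGE_ROUX_ALPHA = {
    "A": 1.489, "R": 1.224, "N": 0.772, "D": 0.924, "C": 0.966,
    "Q": 1.164, "E": 1.504, "G": 0.510, "H": 1.003, "I": 1.003,
    "L": 1.236, "K": 1.172, "M": 1.363, "F": 1.195, "P": 0.492,
    "S": 0.739, "T": 0.785, "W": 1.090, "Y": 0.787, "V": 0.990,
}

# Zimmerman J.M., Eliezer N., Simha R. (1968) bulkiness.
_ZIMMERMAN_BULKINESS = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}

_MAX_UNKNOWN_FRACTION = 0.2


@dataclass(frozen=True)
class PropertyScale:
    """A per-residue numeric scale with its window configuration."""

    name: str
    residue_values: Mapping[str, float]
    window: int = 9

    def __post_init__(self):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residue_values)
        if missing:
            raise DataError(f"scale {self.name!r} missing residues {sorted(missing)}")
        if self.window < 1 or self.window % 2 == 0:
            raise DataError("window must be an odd integer >= 1")
        object.__setattr__(self, "residue_values", dict(self.residue_values))


HYDROPHOBICITY = PropertyScale("hydrophobicity", _KYTE_DOOLITTLE)
HELICAL_PROPENSITY = PropertyScale("helical_propensity", _DELEAGE_ROUX_ALPHA)
BULKINESS = PropertyScale("bulkiness", _ZIMMERMAN_BULKINESS)

SCALES = {s.name: s for s in (HYDROPHOBICITY, HELICAL_PROPENSITY, BULKINESS)}


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    pvalue: float


def _residue_values(seq: str, scale: PropertyScale) -> np.ndarray:
    """Per-residue values with NaN for X; any other unknown letter is an error."""
    vals = np.empty(len(seq))
    for i, aa in enumerate(seq):
        if aa == "X":
            vals[i] = np.nan
        else:
            try:
                vals[i] = scale.residue_values[aa]
            except KeyError:
                raise DataError(f"unknown residue letter {aa!r} at position {i + 1}") from None
    return vals


def window_profile(seq: str, scale: PropertyScale, window: int | None = None) -> np.ndarray:
    """Positionwise windowed property means (NaN where undefined).

    The value at position i (0-based) is the unweighted mean of the scale
    values over the window centred at i.  Edge positions within half a
    window of either end are NaN, as are windows with more than 20% unknown
    residues.
    """
    w = scale.window if window is None else int(window)
    if w < 1 or w % 2 == 0:
        raise DataError("window must be an odd integer >= 1")
    if len(seq) < w:
        raise DataError(f"sequence shorter ({len(seq)}) than window ({w})")
    vals = _residue_values(seq, scale)
    half = (w - 1) // 2
    out = np.full(len(seq), np.nan)
    for i in range(half, len(seq) - half):
        win = vals[i - half : i + half + 1]
        n_unknown = int(np.isnan(win).sum())
        if n_unknown / w > _MAX_UNKNOWN_FRACTION:
            continue
        out[i] = np.nanmean(win)
    return out


def region_mean(seq: str, scale: PropertyScale) -> float:
    """Unweighted mean of raw per-residue scale values over a whole region."""
    if not seq:
        raise DataError("empty sequence")
    vals = _residue_values(seq, scale)
    if np.isnan(vals).all():
        raise DataError("no known residues in region")
    return float(np.nanmean(vals))


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation r plus the least-squares line y = a + b x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DataError("need equal-length samples with at least 3 points")
    lr = stats.linregress(x, y)
    return CorrelationResult(r=float(lr.rvalue), slope=float(lr.slope),
                             intercept=float(lr.intercept), pvalue=float(lr.pvalue))
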