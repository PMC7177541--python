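"""Circular-dichroism unit conversion and mean residue weight.

Spectropolarimeters report ellipticity in machine units (theta, mdeg).
For comparison across constructs and with deconvolution software the
signal is converted to the per-residue molar CD absorption coefficient

    delta_epsilon = theta * 0.1 * MRW / (l * C * 3298)

where MRW is the mean residue weight in Da (molecular weight divided by
the number of residues), l the cuvette path length in cm, C the protein
concentration in mg/mL, and 3298 the Delta-epsilon / mean-residue-
ellipticity conversion constant.  The conversion is applied pointwise
over a wavelength series; no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .datasets import residue_masses
from .records import CANONICAL, ProteinRecord, SequenceError

__all__ = ["WATER_MASS_DA", "CDMeasurement", "mean_residue_weight",
           "molecular_weight", "theta_to_delta_epsilon",
           "delta_epsilon_to_theta"]

WATER_MASS_DA = 18.0153


def molecular_weight(record: ProteinRecord) -> float:
    """Average molecular weight of the chain in Da (one water per chain)."""
    masses = residue_masses()
    non_canonical = [c for c in record.sequence if c not in CANONICAL]
    if non_canonical:
        raise SequenceError(
            f"cannot compute mass with ambiguous residues {set(non_canonical)}")
    return sum(masses[c] for c in record.sequence) + WATER_MASS_DA


def mean_residue_weight(record: ProteinRecord) -> float:
    """Mean residue weight: molecular weight / residue count (Da)."""
    return molecular_weight(record) / len(record)


def theta_to_delta_epsilon(theta, mrw: float, path_length_cm: float,
                           concentration_mg_per_ml: float):
    """Convert machine-unit ellipticity to delta-epsilon (pointwise).

    ``theta`` may be a scalar or an array (e.g. a 190-260 nm series); the
    result has the same shape.  Positive path length, concentration and MRW
    are required.
    """
    for name, v in [("mrw", mrw), ("path_length_cm", path_length_cm),
                    ("concentration_mg_per_ml", concentration_mg_per_ml)]:
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    theta = np.asarray(theta, dtype=float)
    out = theta * 0.1 * mrw / (path_length_cm * concentration_mg_per_ml * 3298.0)
    return float(out) if out.ndim == 0 else out


def delta_epsilon_to_theta(delta_epsilon, mrw: float, path_length_cm: float,
                           concentration_mg_per_ml: float):
    """Inverse of :func:`theta_to_delta_epsilon`."""
    for name, v in [("mrw", mrw), ("path_length_cm", path_length_cm),
                    ("concentration_mg_per_ml", concentration_mg_per_ml)]:
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    de = np.asarray(delta_epsilon, dtype=float)
    out = de * (path_length_cm * concentration_mg_per_ml * 3298.0) / (0.1 * mrw)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CDMeasurement:
    """One CD reading (or series) with the quantities needed to convert it."""

    theta: float | np.ndarray
    path_length_cm: float
    concentration_mg_per_ml: float
    mrw: float

    def __post_init__(self) -> None:
        for name in ("path_length_cm", "concentration_mg_per_ml", "mrw"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def delta_epsilon(self):
        return theta_to_delta_epsilon(self.theta, self.mrw,
                                      self.path_length_cm,
                                      self.concentration_mg_per_ml)
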