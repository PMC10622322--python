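"""Pluggable fragment-intensity and retention-time prediction.

Production pipelines predict fragment intensities and retention times
with learned models; this package only requires the interface below,
plus a deterministic toy predictor used by the simulator and tests. The
toy predictor computes exact singly charged b/y fragment ion m/z values
(monoisotopic, via pyteomics) and assigns each ion a reproducible
pseudo-random intensity derived from a hash of the peptide and ion
label, with a configurable fraction of ions lacking an intensity
prediction (NaN), mimicking real predictors that only cover part of the
ion series. Retention times follow a simple additive
hydrophobicity-coefficient model.
"""

from __future__ import annotations

import zlib
from typing import Protocol, runtime_checkable

import numpy as np
from pyteomics import mass

from .psm_qc import Spectrum


@runtime_checkable
class FragmentRtPredictor(Protocol):
    """Interface a fragment/RT predictor must satisfy (deterministic)."""

    def predict_fragments(self, peptide: str) -> Spectrum: ...

    def predict_rt(self, peptide: str) -> float: ...


def _unit_hash(text: str) -> float:
    """Deterministic value in [0, 1) from a string."""
    return (zlib.crc32(text.encode()) & 0xFFFFFFFF) / 2**32


# additive retention coefficients (arbitrary hydrophobicity-like scale)
_RT_COEFF = {
    "A": 0.5, "C": 0.1, "D": -0.5, "E": -0.3, "F": 2.5, "G": 0.0,
    "H": -1.0, "I": 2.0, "K": -1.5, "L": 2.2, "M": 1.3, "N": -0.6,
    "P": 0.3, "Q": -0.4, "R": -1.2, "S": -0.2, "T": 0.2, "V": 1.5,
    "W": 2.8, "Y": 1.6,
}


class ToyPredictor:
    """Deterministic b/y-ion predictor for simulation and testing.

    Not a learned model: intensities are hash-derived, so identical
    peptides always yield identical predictions, which is all the
    downstream QC machinery requires.
    """

    def __init__(self, missing_rate: float = 0.05, charge: int = 1):
        if not (0.0 <= missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        self.missing_rate = missing_rate
        self.charge = charge

    def _ions(self, peptide: str) -> list[tuple[str, float]]:
        ions = []
        for i in range(1, len(peptide)):
            ions.append(
                (f"b{i}", mass.fast_mass(peptide[:i], ion_type="b", charge=self.charge))
            )
            ions.append(
                (f"y{i}", mass.fast_mass(peptide[-i:], ion_type="y", charge=self.charge))
            )
        return ions

    def predict_fragments(self, peptide: str) -> Spectrum:
        peaks: dict[float, tuple[str, float]] = {}
        for label, mz in self._ions(peptide):
            u = _unit_hash(f"{peptide}/{label}/intensity")
            if _unit_hash(f"{peptide}/{label}/missing") < self.missing_rate:
                inten = float("nan")
            else:
                inten = 0.05 + 0.95 * u
            # rare exact m/z collisions (e.g. symmetric sequences): keep first
            if mz not in peaks:
                peaks[mz] = (label, inten)
        order = sorted(peaks)
        labels, intensities = zip(*(peaks[mz] for mz in order))
        return Spectrum(
            mz=np.array(order),
            intensity=np.array(intensities),
            retention_time=self.predict_rt(peptide),
            identifier=f"predicted:{peptide}",
            labels=labels,
        )

    def predict_rt(self, peptide: str) -> float:
        """Predicted retention time in seconds.

        Coefficients are weighted by residue position (N-terminal
        residues count less), so retention is sensitive to sequence
        order, not composition alone — permuted peptides elute at
        different times.
        """
        n = len(peptide)
        total = sum(
            _RT_COEFF.get(res, 0.0) * (0.5 + i / max(n - 1, 1))
            for i, res in enumerate(peptide)
        )
        return 600.0 + 60.0 * total


def precursor_mz(peptide: str, charge: int = 2) -> float:
    """Monoisotopic precursor m/z of the unmodified peptide."""
    return mass.fast_mass(peptide, charge=charge)
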