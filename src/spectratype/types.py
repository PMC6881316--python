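"""Core domain containers shared by every pipeline stage.

All masses are in daltons (Da) throughout; intensities are in arbitrary
units (a.u.) unless a stage has normalized them (total ion current = 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RawSpectrum",
    "PeakList",
    "MSP",
    "SpecimenRecord",
    "Hit",
    "IdentificationResult",
]


@dataclass
class RawSpectrum:
    """A continuous profile spectrum on an ascending m/z grid.

    Parameters
    ----------
    mz : array of float
        Strictly ascending masses in Da.
    intensity : array of float
        Non-negative intensities, same length as ``mz``.
    meta : dict
        Provenance: ``specimen_id``, ``replicate_id``, acquisition range, ...
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"length mismatch: {self.mz.size} mz vs {self.intensity.size} intensities"
            )
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size

    def replace(self, *, mz=None, intensity=None, meta=None) -> "RawSpectrum":
        return RawSpectrum(
            self.mz if mz is None else mz,
            self.intensity if intensity is None else intensity,
            dict(self.meta) if meta is None else meta,
        )


@dataclass
class PeakList:
    """Sparse fingerprint of one spectrum: (m/z, intensity, S/N) triples."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.mz.shape == self.intensity.shape == self.snr.shape):
            raise ValueError("mz, intensity and snr must have equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("peak mz must be strictly ascending")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class MSP:
    """Main-spectra-projection consensus: one reference fingerprint.

    Each peak carries the consensus mass, the mean normalized intensity over
    the replicate peak lists that contributed to it, and the fraction of
    source lists in which it was observed.
    """

    label: str
    mz: np.ndarray
    mean_intensity: np.ndarray
    frequency: np.ndarray
    n_sources: int

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if not (self.mz.shape == self.mean_intensity.shape == self.frequency.shape):
            raise ValueError("MSP columns must have equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("MSP mz must be strictly ascending")
        if np.any((self.frequency <= 0) | (self.frequency > 1)):
            raise ValueError("frequencies must lie in (0, 1]")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")

    def __len__(self) -> int:
        return self.mz.size

    def as_peaklist(self) -> PeakList:
        """View the consensus as a query-able peak list (S/N column unused)."""
        return PeakList(
            self.mz.copy(),
            self.mean_intensity.copy(),
            np.full(self.mz.size, np.inf),
            source_id=self.label,
        )


@dataclass(frozen=True)
class SpecimenRecord:
    """One commercial specimen: how it was sold vs. what it turned out to be."""

    specimen_id: str
    marketed_species: str
    origin: str
    season: str
    assigned_species: str

    FIELDS = ("specimen_id", "marketed_species", "origin", "season", "assigned_species")


@dataclass(frozen=True)
class Hit:
    label: str
    score: float
    category: str  # "species" | "low_confidence" | "unreliable"


@dataclass
class IdentificationResult:
    """Ranked library matches for one query, scores descending in [0, 3]."""

    query_id: str
    hits: Sequence[Hit]

    def __post_init__(self) -> None:
        scores = [h.score for h in self.hits]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("hits must be sorted by descending score")

    @property
    def top(self) -> Hit:
        if not self.hits:
            raise ValueError("empty identification result")
        return self.hits[0]
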