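"""Synthetic linear-mode protein mass spectra with the statistical structure
of a replicate biotyping study.

The generator emulates a market survey of commercial truffles: a panel of
species-specific protein peaks per species (sister species in a complex share
a configurable fraction of peaks), specimens per species, and 2 biological x
3 technical replicate spectra per specimen. Each spectrum is a sum of
Gaussian peaks (FWHM = m/z / resolution, typical linear-mode physics) on an
exponentially decaying chemical baseline, with additive Gaussian noise,
per-spectrum ppm calibration jitter, per-specimen and per-replicate
log-normal intensity variability, and per-peak dropout.

Mislabeling is injected through the design table (marketed name may differ
from the true species), never randomly, so ground truth is always known.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import RawSpectrum, SpecimenRecord

__all__ = [
    "ParameterError",
    "SpeciesPanel",
    "SimulationConfig",
    "DesignRow",
    "StudySet",
    "generate_panels",
    "simulate_spectrum",
    "simulate_study",
]

#: ppm window used when deciding whether two panel peaks are "the same" mass.
SHARED_PEAK_PPM = 200.0


class ParameterError(ValueError):
    """A simulation parameter combination is infeasible or invalid."""


@dataclass
class SpeciesPanel:
    """The idealized fingerprint of one species.

    ``peak_mzs`` are strictly ascending masses in Da within the acquisition
    window; ``peak_rel_intensities`` are unitless relative abundances
    (log-normal, unit median). Panels sharing a ``complex_id`` share a
    fraction of their peak masses, emulating sister species that are hard to
    delimit.
    """

    species_name: str
    peak_mzs: np.ndarray
    peak_rel_intensities: np.ndarray
    complex_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.peak_mzs = np.asarray(self.peak_mzs, dtype=float)
        self.peak_rel_intensities = np.asarray(self.peak_rel_intensities, dtype=float)
        if self.peak_mzs.shape != self.peak_rel_intensities.shape:
            raise ParameterError("peak mz and intensity arrays differ in length")
        if self.peak_mzs.size >= 2 and not np.all(np.diff(self.peak_mzs) > 0):
            raise ParameterError("panel peak mzs must be strictly ascending")
        if np.any(self.peak_rel_intensities <= 0):
            raise ParameterError("relative intensities must be positive")

    @property
    def n_peaks(self) -> int:
        return self.peak_mzs.size


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    The replicate design defaults (2 biological x 3 technical = 6 spectra per
    specimen) mirror the protein-extraction protocol the study-scale fixture
    emulates; the remaining defaults are chosen to resemble linear-mode
    protein profiles: resolution m/dm ~ 600, ~40 informative peaks per
    species, 25% intensity CV between replicates, 300 ppm calibration
    scatter, and sparse (5%) peak dropout.
    """

    n_species: int = 7
    specimens_per_species: Sequence[int] = ()
    n_biological: int = 2
    n_technical: int = 3
    peaks_per_species: int = 40
    complex_overlap: float = 0.5
    intensity_cv: float = 0.25
    dropout_prob: float = 0.05
    ppm_jitter_sd: float = 300.0
    baseline_b0: float = 50.0
    baseline_tau: float = 3000.0
    noise_sd: float = 1.0
    resolution: float = 600.0
    grid_step: float = 1.0
    seed: int = 0
    mass_range: tuple = (2000.0, 20000.0)
    min_peak_spacing: float = 25.0
    peak_amplitude: float = 100.0
    rel_intensity_sigma: float = 0.6
    #: groups of species indices whose panels share ``complex_overlap`` of
    #: their peaks (e.g. a species complex of sister taxa).
    complex_groups: Sequence[Sequence[int]] = ()

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ParameterError("n_species must be positive")
        if not self.specimens_per_species:
            self.specimens_per_species = tuple([1] * self.n_species)
        self.specimens_per_species = tuple(int(c) for c in self.specimens_per_species)
        if len(self.specimens_per_species) != self.n_species:
            raise ParameterError("specimens_per_species must have n_species entries")
        if any(c < 1 for c in self.specimens_per_species):
            raise ParameterError("specimen counts must be positive")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ParameterError("replicate counts must be positive")
        for name in ("complex_overlap", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.intensity_cv < 0:
            raise ParameterError("intensity_cv must be non-negative")
        if self.grid_step <= 0 or self.resolution <= 0:
            raise ParameterError("grid_step and resolution must be positive")
        lo, hi = self.mass_range
        if not lo < hi:
            raise ParameterError("mass_range must be (lo, hi) with lo < hi")
        for group in self.complex_groups:
            if any(not 0 <= i < self.n_species for i in group):
                raise ParameterError("complex_groups indices out of range")

    @property
    def replicates_per_specimen(self) -> int:
        return self.n_biological * self.n_technical

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class DesignRow:
    """One specimen of a study design; marketed name may differ from truth."""

    specimen_id: str
    marketed_species: str
    true_species: str
    origin: str = ""
    season: str = ""


@dataclass
class StudySet:
    """The complete simulated study: spectra, metadata and ground truth."""

    spectra: Mapping  # (specimen_id, replicate_id) -> RawSpectrum
    records: Sequence[SpecimenRecord]
    truth: Mapping  # specimen_id -> true species
    panels: Sequence[SpeciesPanel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {r.specimen_id for r in self.records}
        if set(self.truth) != ids:
            raise ParameterError("truth must cover exactly the specimen ids")

    def replicates(self, specimen_id: str):
        """Replicate spectra of one specimen, in replicate-id order."""
        keys = sorted(k for k in self.spectra if k[0] == specimen_id)
        return [self.spectra[k] for k in keys]


def _spaced_positions(n: int, lo: float, hi: float, spacing: float,
                      rng: np.random.Generator) -> np.ndarray:
    """n sorted positions in [lo, hi] with pairwise gaps >= spacing (exact
    construction: uniform draws in the shrunken interval plus a linear
    spacing ramp)."""
    span = hi - lo - (n - 1) * spacing
    if span <= 0:
        raise ParameterError(
            f"cannot place {n} peaks with spacing {spacing} Da in [{lo}, {hi}] Da"
        )
    base = np.sort(rng.uniform(lo, lo + span, size=n))
    return base + np.arange(n) * spacing


def _lognormal_unit_median(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.normal(0.0, sigma, size=n))


def _cv_multipliers(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal multipliers with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    s2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-0.5 * s2, math.sqrt(s2), size=n))


def generate_panels(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    species_names: Optional[Sequence[str]] = None,
) -> list[SpeciesPanel]:
    """Draw one peak panel per species.

    Species grouped in ``config.complex_groups`` share ``complex_overlap`` of
    their peaks: a master position set with global minimum spacing is drawn
    for the whole group, a shared subset is fixed, and the remainder is
    partitioned into private peaks, so the shared fraction is exact to within
    one peak and no two group peaks collide.
    """
    rng = config.rng() if rng is None else rng
    if species_names is None:
        species_names = [f"Species_{i + 1:02d}" for i in range(config.n_species)]
    if len(species_names) != config.n_species:
        raise ParameterError("species_names must have n_species entries")

    lo, hi = config.mass_range
    k = config.peaks_per_species
    group_of = {}
    for gi, group in enumerate(config.complex_groups):
        for idx in group:
            if idx in group_of:
                raise ParameterError("a species cannot belong to two complexes")
            group_of[idx] = gi

    positions: dict[int, np.ndarray] = {}
    complex_ids: dict[int, Optional[str]] = {i: None for i in range(config.n_species)}

    for gi, group in enumerate(config.complex_groups):
        members = list(group)
        n_shared = int(round(config.complex_overlap * k))
        n_private = k - n_shared
        total = n_shared + n_private * len(members)
        master = _spaced_positions(total, lo, hi, config.min_peak_spacing, rng)
        perm = rng.permutation(total)
        shared = master[np.sort(perm[:n_shared])]
        rest = perm[n_shared:]
        for j, idx in enumerate(members):
            private = master[np.sort(rest[j * n_private:(j + 1) * n_private])]
            positions[idx] = np.sort(np.concatenate([shared, private]))
            complex_ids[idx] = f"complex_{gi}"

    for i in range(config.n_species):
        if i not in positions:
            positions[i] = _spaced_positions(k, lo, hi, config.min_peak_spacing, rng)

    panels = []
    for i in range(config.n_species):
        rel = _lognormal_unit_median(k, config.rel_intensity_sigma, rng)
        panels.append(
            SpeciesPanel(
                species_name=species_names[i],
                peak_mzs=positions[i],
                peak_rel_intensities=rel,
                complex_id=complex_ids[i],
            )
        )
    return panels


_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def simulate_spectrum(
    panel: SpeciesPanel,
    specimen_effect: Optional[np.ndarray],
    replicate_effect: Optional[np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> RawSpectrum:
    """Render one replicate spectrum of one specimen.

    intensity(m) = sum_k A_k G(m; mu_k (1 + d_ppm), FWHM = mu_k / resolution)
                   + b0 exp(-(m - lo) / tau) + N(0, noise_sd), clipped at 0,

    where A_k combines the panel's relative abundance with the specimen- and
    replicate-level multipliers and is zeroed with probability dropout_prob.
    d_ppm is a single per-spectrum calibration offset.
    """
    lo, hi = config.mass_range
    n_grid = int(round((hi - lo) / config.grid_step)) + 1
    grid = lo + config.grid_step * np.arange(n_grid)

    n = panel.n_peaks
    specimen_effect = np.ones(n) if specimen_effect is None else np.asarray(specimen_effect)
    replicate_effect = np.ones(n) if replicate_effect is None else np.asarray(replicate_effect)

    d_ppm = rng.normal(0.0, config.ppm_jitter_sd) * 1e-6 if config.ppm_jitter_sd > 0 else 0.0
    keep = rng.random(n) >= config.dropout_prob if config.dropout_prob > 0 else np.ones(n, bool)

    amps = (
        config.peak_amplitude
        * panel.peak_rel_intensities
        * specimen_effect
        * replicate_effect
        * keep
    )

    signal = np.zeros(n_grid)
    for mu0, amp in zip(panel.peak_mzs, amps):
        if amp == 0.0:
            continue
        mu = mu0 * (1.0 + d_ppm)
        sigma = (mu / config.resolution) / _FWHM_TO_SIGMA
        a = np.searchsorted(grid, mu - 6.0 * sigma)
        b = np.searchsorted(grid, mu + 6.0 * sigma)
        if a >= b:
            continue
        window = grid[a:b]
        signal[a:b] += amp * np.exp(-0.5 * ((window - mu) / sigma) ** 2)

    if config.baseline_b0 > 0:
        signal += config.baseline_b0 * np.exp(-(grid - lo) / config.baseline_tau)
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n_grid)

    return RawSpectrum(grid, np.clip(signal, 0.0, None),
                       meta={"species": panel.species_name,
                             "mass_range": (lo, hi)})


def simulate_study(
    config: SimulationConfig,
    design: Sequence[DesignRow],
    rng: Optional[np.random.Generator] = None,
    panels: Optional[Sequence[SpeciesPanel]] = None,
) -> StudySet:
    """Simulate a full replicate study from a design table.

    One panel per distinct true species is drawn (alphabetical order, unless
    ``panels`` is supplied); each design row then yields n_biological x
    n_technical spectra sharing a per-specimen intensity profile, with an
    extra multiplier layer per biological replicate.
    """
    if not design:
        raise ParameterError("design must be non-empty")
    rng = config.rng() if rng is None else rng

    species = sorted({row.true_species for row in design})
    if panels is None:
        if len(species) != config.n_species:
            raise ParameterError(
                f"design names {len(species)} species but config.n_species={config.n_species}"
            )
        panels = generate_panels(config, rng, species_names=species)
    panel_by_species = {p.species_name: p for p in panels}
    missing = [s for s in species if s not in panel_by_species]
    if missing:
        raise ParameterError(f"species in design without a panel: {missing}")

    spectra: dict[tuple, RawSpectrum] = {}
    records: list[SpecimenRecord] = []
    truth: dict[str, str] = {}
    seen: set[str] = set()
    for row in design:
        if row.specimen_id in seen:
            raise ParameterError(f"duplicate specimen_id {row.specimen_id!r}")
        seen.add(row.specimen_id)
        panel = panel_by_species[row.true_species]
        spec_mult = _cv_multipliers(panel.n_peaks, config.intensity_cv, rng)
        for b in range(1, config.n_biological + 1):
            bio_mult = _cv_multipliers(panel.n_peaks, config.intensity_cv, rng)
            for t in range(1, config.n_technical + 1):
                tech_mult = _cv_multipliers(panel.n_peaks, config.intensity_cv, rng)
                spectrum = simulate_spectrum(
                    panel, spec_mult, bio_mult * tech_mult, config, rng
                )
                rep_id = f"b{b}t{t}"
                spectrum.meta.update(specimen_id=row.specimen_id, replicate_id=rep_id)
                spectra[(row.specimen_id, rep_id)] = spectrum
        records.append(
            SpecimenRecord(
                specimen_id=row.specimen_id,
                marketed_species=row.marketed_species,
                origin=row.origin,
                season=row.season,
                assigned_species=row.true_species,
            )
        )
        truth[row.specimen_id] = row.true_species

    return StudySet(spectra=spectra, records=records, truth=truth, panels=list(panels))
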