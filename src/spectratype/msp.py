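"""Consensus reference spectra (main spectra projections).

The six replicate peak lists of a specimen (or all replicate lists of a
species) are fused into one reference fingerprint: peaks are pooled,
binned by single-linkage within a ppm tolerance, and each bin is summarized
by its consensus mass, mean normalized intensity and replicate frequency.
Bins seen in fewer than ``min_freq`` of the source lists are dropped, the
``max_peaks`` most frequent/intense survive, and only the 3-15 kDa window
is considered.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import MSP, PeakList

__all__ = ["MspParams", "PeakBin", "bin_peaklists", "build_msp"]


@dataclass
class MspParams:
    """Consensus parameters: 3-15 kDa window, 2000 ppm cross-replicate
    binning tolerance, 200 ppm consensus-mass precision, 25% minimum
    replicate frequency, at most 70 peaks."""

    mass_range: tuple = (3000.0, 15000.0)
    spectrum_tol_ppm: float = 2000.0
    msp_tol_ppm: float = 200.0
    min_freq: float = 0.25
    max_peaks: int = 70

    def __post_init__(self) -> None:
        if self.spectrum_tol_ppm <= 0 or self.msp_tol_ppm <= 0:
            raise ValueError("ppm tolerances must be positive")
        if not 0 < self.min_freq <= 1:
            raise ValueError("min_freq must lie in (0, 1]")
        if self.max_peaks < 1:
            raise ValueError("max_peaks must be positive")


@dataclass
class PeakBin:
    """One mass bin: at most one member peak per source list."""

    centroid: float
    #: (source index, mz, intensity) triples
    members: list = field(default_factory=list)

    @property
    def sources(self) -> set:
        return {m[0] for m in self.members}


def _weighted_centroid(members) -> float:
    mz = np.array([m[1] for m in members])
    w = np.array([m[2] for m in members])
    total = w.sum()
    if total <= 0:
        return float(mz.mean())
    return float(np.dot(mz, w) / total)


def bin_peaklists(peaklists: Sequence[PeakList], tol_ppm: float) -> list[PeakBin]:
    """Single-linkage ppm binning of pooled peaks.

    Pooled peaks are walked in ascending mass order; a peak joins the open
    bin while its gap to the bin's intensity-weighted centroid is within
    ``tol_ppm`` of the centroid, otherwise it opens a new bin. Within a bin
    at most one peak per source list survives (the one closest to the
    centroid), after which the centroid is recomputed.
    """
    if not peaklists:
        raise ValueError("need at least one peak list")
    pooled = sorted(
        (float(mz), float(inten), src)
        for src, pl in enumerate(peaklists)
        for mz, inten in zip(pl.mz, pl.intensity)
    )
    bins: list[PeakBin] = []
    for mz, inten, src in pooled:
        if bins:
            b = bins[-1]
            if mz - b.centroid <= tol_ppm * b.centroid / 1e6:
                b.members.append((src, mz, inten))
                b.centroid = _weighted_centroid(b.members)
                continue
        bins.append(PeakBin(centroid=mz, members=[(src, mz, inten)]))

    # dedupe: keep, per source, the member closest to the centroid
    # (ties: lower mz, then higher intensity — independent of source order)
    for b in bins:
        best: dict[int, tuple] = {}
        for src, mz, inten in b.members:
            key = (abs(mz - b.centroid), mz, -inten)
            if src not in best or key < best[src][0]:
                best[src] = (key, (src, mz, inten))
        b.members = sorted((v[1] for v in best.values()),
                           key=lambda m: (m[1], -m[2], m[0]))
        b.centroid = _weighted_centroid(b.members)
    bins.sort(key=lambda b: b.centroid)
    return bins


def _round_to_ppm(mz: float, ppm: float) -> float:
    step = mz * ppm / 1e6
    if step <= 0:
        return mz
    return round(mz / step) * step


def build_msp(
    peaklists: Sequence[PeakList],
    params: MspParams = None,
    label: str = "",
) -> MSP:
    """Fuse replicate peak lists into one consensus reference spectrum.

    Each list is first restricted to the consensus mass window and its
    retained intensities renormalized to unit sum so replicates contribute
    comparably; lists are then pooled and binned at ``spectrum_tol_ppm``.
    A bin's frequency is the fraction of source lists contributing to it
    (denominator = number of input lists, including any with no peaks in
    the window). Bins below ``min_freq`` are dropped; if more than
    ``max_peaks`` survive, ties are broken by frequency, then mean
    intensity, then mass.
    """
    params = params or MspParams()
    if not peaklists:
        raise ValueError("need at least one peak list")
    n_sources = len(peaklists)
    lo, hi = params.mass_range

    trimmed: list[PeakList] = []
    for pl in peaklists:
        mask = (pl.mz >= lo) & (pl.mz < hi)
        inten = pl.intensity[mask]
        total = inten.sum()
        if total > 0:
            inten = inten / total
        trimmed.append(PeakList(pl.mz[mask], inten, pl.snr[mask], pl.source_id))

    bins = bin_peaklists(trimmed, params.spectrum_tol_ppm)
    rows = []  # (mz, mean_intensity, frequency)
    for b in bins:
        freq = len(b.sources) / n_sources
        if freq < params.min_freq:
            continue
        # sum in sorted order so the mean is independent of source numbering
        mean_int = float(np.mean(np.sort([m[2] for m in b.members])))
        rows.append((_round_to_ppm(b.centroid, params.msp_tol_ppm), mean_int, freq))

    # merge rows whose rounded consensus masses collided (rare)
    merged: dict[float, tuple] = {}
    for mz, mi, fr in rows:
        if mz in merged:
            omz, omi, ofr = merged[mz]
            merged[mz] = (mz, (omi + mi) / 2, max(ofr, fr))
        else:
            merged[mz] = (mz, mi, fr)
    rows = sorted(merged.values())

    if not rows:
        raise ValueError(
            f"no consensus peaks survive for {label!r}: {n_sources} lists, "
            f"window [{lo}, {hi}) Da, min_freq {params.min_freq} — "
            "check the mass window and tolerances"
        )
    if len(rows) > params.max_peaks:
        rows = sorted(rows, key=lambda r: (-r[2], -r[1], r[0]))[: params.max_peaks]
        rows.sort()

    mz, mi, fr = (np.array(col) for col in zip(*rows))
    return MSP(label=label, mz=mz, mean_intensity=mi, frequency=fr, n_sources=n_sources)
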