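"""Spectral preprocessing: trim, smooth, baseline-subtract, normalize and
pick peaks.

The chain mirrors standard linear-mode biotyping practice: two passes of
Savitzky-Golay smoothing with a 5 Da window, morphological top-hat baseline
subtraction, total-ion-current normalization, a robust (MAD-based) local
noise estimate, and S/N >= 3 peak picking capped at 150 peaks with a 5 m/z
minimum apex separation. Everything here is deterministic; there is no
randomness in preprocessing.

Window widths are given in Da and converted to odd point counts via the
median local grid spacing, so non-uniform m/z grids are supported.
"""
from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

from .types import PeakList, RawSpectrum

__all__ = [
    "PreprocessParams",
    "trim_range",
    "smooth_sg",
    "baseline_tophat",
    "estimate_noise",
    "normalize_tic",
    "pick_peaks",
    "preprocess_pipeline",
]


@dataclass
class PreprocessParams:
    """Defaults follow the acquisition software's standard processing:
    5 Da SG window applied twice, S/N floor 3, at most 150 peaks, 5 m/z
    minimum apex separation, acquisition window 2-20 kDa."""

    mass_range: tuple = (2000.0, 20000.0)
    sg_window_da: float = 5.0
    sg_passes: int = 2
    sg_polyorder: int = 3
    tophat_width_da: float = 500.0
    snr_min: float = 3.0
    max_peaks: int = 150
    peak_width: float = 5.0  # minimum apex separation, m/z
    normalize: bool = True
    noise_windows: int = 10

    def __post_init__(self) -> None:
        if self.sg_window_da <= 0 or self.tophat_width_da <= 0:
            raise ValueError("window widths must be positive")
        if self.snr_min <= 0 or self.peak_width <= 0 or self.max_peaks < 1:
            raise ValueError("snr_min, peak_width and max_peaks must be positive")
        if self.sg_passes < 1 or self.sg_polyorder < 1:
            raise ValueError("sg_passes and sg_polyorder must be positive")


def _window_points(mz: np.ndarray, width_da: float) -> int:
    """Convert a width in Da to an odd number of grid points."""
    spacing = float(np.median(np.diff(mz)))
    n = max(int(round(width_da / spacing)), 1)
    return n if n % 2 == 1 else n + 1


def trim_range(spectrum: RawSpectrum, lo: float, hi: float) -> RawSpectrum:
    """Keep points with lo <= mz < hi (half-open)."""
    if not lo < hi:
        raise ValueError(f"invalid range [{lo}, {hi})")
    mask = (spectrum.mz >= lo) & (spectrum.mz < hi)
    if not mask.any():
        raise ValueError(
            f"no points in [{lo}, {hi}) Da — check units (masses must be in Da)"
        )
    return spectrum.replace(mz=spectrum.mz[mask], intensity=spectrum.intensity[mask])


def smooth_sg(
    spectrum: RawSpectrum,
    window_da: float = 5.0,
    passes: int = 2,
    polyorder: int = 3,
) -> RawSpectrum:
    """Savitzky-Golay smoothing, applied ``passes`` times.

    Edges are handled by evaluating the terminal-window polynomial fit, so
    output length equals input length. The filter preserves polynomials up
    to ``polyorder`` exactly.
    """
    npts = _window_points(spectrum.mz, window_da)
    if npts == 1:
        # window narrower than the grid spacing: nothing to smooth
        return spectrum.replace(intensity=spectrum.intensity.copy())
    if len(spectrum) < npts:
        raise ValueError(f"spectrum has {len(spectrum)} points < window of {npts}")
    if polyorder >= npts:
        raise ValueError(f"polyorder {polyorder} >= window of {npts} points")
    y = spectrum.intensity
    for _ in range(passes):
        y = savgol_filter(y, npts, polyorder, mode="interp")
    # SG can undershoot slightly at sharp features; intensities stay >= 0
    return spectrum.replace(intensity=np.clip(y, 0.0, None))


def baseline_tophat(spectrum: RawSpectrum, width_da: float = 500.0):
    """Morphological top-hat baseline subtraction.

    The baseline is the morphological opening (erosion then dilation with a
    flat structuring element of ``width_da``); the corrected signal is the
    non-negative residual, and corrected + baseline reconstructs the input
    to machine precision.

    Before filtering, the signal is padded by half a structuring width on
    each side with a linear extrapolation of the terminal trend; without it
    the opening cannot follow a monotone baseline at the spectrum edges and
    leaves a spurious edge hump.

    Returns ``(corrected, baseline)``.
    """
    npts = _window_points(spectrum.mz, width_da)
    if npts < 3:
        raise ValueError(f"top-hat width of {npts} point(s) is too narrow (need >= 3)")
    x = spectrum.intensity
    half = npts // 2
    if len(x) > half:
        lslope = (x[half] - x[0]) / half
        rslope = (x[-1] - x[-1 - half]) / half
    else:
        lslope = rslope = 0.0
    lpad = x[0] - lslope * np.arange(half, 0, -1)
    rpad = x[-1] + rslope * np.arange(1, half + 1)
    padded = np.concatenate([lpad, x, rpad])
    opened = maximum_filter1d(minimum_filter1d(padded, npts), npts)[half:len(x) + half]
    # opening never exceeds its input, and inside the original domain the
    # padded signal equals the input, so this is a pointwise exact baseline
    baseline = np.minimum(opened, x)
    corrected = x - baseline
    return (
        spectrum.replace(intensity=corrected),
        spectrum.replace(intensity=baseline),
    )


def estimate_noise(spectrum: RawSpectrum, n_windows: int = 10) -> np.ndarray:
    """Robust local noise level, one value per grid point.

    The first difference of the signal removes slow structure; within each
    of ``n_windows`` equal slices the noise is 1.4826 x MAD of the
    differences divided by sqrt(2) (differencing doubles the variance), and
    the per-window levels are linearly interpolated to every m/z.
    """
    if len(spectrum) < 20:
        raise ValueError(f"need >= 20 points to estimate noise, got {len(spectrum)}")
    d = np.diff(spectrum.intensity)
    edges = np.linspace(0, d.size, n_windows + 1).astype(int)
    centers, levels = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        w = d[a:b]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        levels.append(1.4826 * mad / math.sqrt(2.0))
        centers.append(0.5 * (spectrum.mz[a] + spectrum.mz[min(b, d.size - 1) ]))
    return np.interp(spectrum.mz, centers, levels)


def normalize_tic(spectrum: RawSpectrum) -> RawSpectrum:
    """Scale intensities to unit total ion current (sum = 1)."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spectrum.replace(intensity=spectrum.intensity / total)


def _snr(intensity: np.ndarray, noise: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = intensity / noise
    snr[noise == 0] = np.where(intensity[noise == 0] > 0, np.inf, 0.0)
    return snr


def pick_peaks(
    spectrum: RawSpectrum,
    noise: np.ndarray,
    params: PreprocessParams = None,
) -> PeakList:
    """S/N-thresholded local-maximum peak picking.

    Candidates are strict local maxima with S/N >= ``snr_min``; apexes
    closer than ``peak_width`` m/z are resolved by keeping the more intense
    (ties: lower m/z); if more than ``max_peaks`` survive, the most intense
    are kept. Output is sorted by m/z.
    """
    params = params or PreprocessParams()
    x = spectrum.intensity
    noise = np.asarray(noise, dtype=float)
    if noise.shape != x.shape:
        raise ValueError("noise must be aligned with the spectrum grid")
    if len(x) < 3:
        return PeakList(np.array([]), np.array([]), np.array([]),
                        source_id=str(spectrum.meta.get("specimen_id", "")))

    interior = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
    snr = _snr(x, noise)
    cand = interior[snr[interior] >= params.snr_min]

    # greedy minimum-separation: higher intensity wins, ties -> lower m/z;
    # an accepted apex suppresses later (weaker) apexes within peak_width,
    # so only the nearest accepted neighbours need checking
    order = cand[np.lexsort((spectrum.mz[cand], -x[cand]))]
    kept: list[int] = []
    kept_mz: list[float] = []
    for idx in order:
        m = spectrum.mz[idx]
        pos = bisect.bisect_left(kept_mz, m)
        if pos > 0 and m - kept_mz[pos - 1] < params.peak_width:
            continue
        if pos < len(kept_mz) and kept_mz[pos] - m < params.peak_width:
            continue
        kept_mz.insert(pos, m)
        kept.append(idx)
    kept = np.asarray(kept, dtype=int)
    if kept.size > params.max_peaks:
        sel = np.lexsort((spectrum.mz[kept], -x[kept]))[: params.max_peaks]
        kept = kept[sel]
    kept = np.sort(kept)
    return PeakList(
        spectrum.mz[kept], x[kept], snr[kept],
        source_id=str(spectrum.meta.get("specimen_id", "")),
    )


def preprocess_pipeline(raw: RawSpectrum, params: PreprocessParams = None) -> PeakList:
    """Full chain: trim -> smooth (x passes) -> top-hat -> normalize ->
    noise estimate -> peak picking. Deterministic for fixed input."""
    params = params or PreprocessParams()
    s = trim_range(raw, *params.mass_range)
    s = smooth_sg(s, params.sg_window_da, params.sg_passes, params.sg_polyorder)
    s, _ = baseline_tophat(s, params.tophat_width_da)
    if params.normalize:
        s = normalize_tic(s)
    noise = estimate_noise(s, params.noise_windows)
    peaks = pick_peaks(s, noise, params)
    if raw.meta.get("specimen_id") and not peaks.source_id:
        peaks.source_id = raw.meta["specimen_id"]
    return peaks
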