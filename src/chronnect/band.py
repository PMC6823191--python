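"""Wavelet reconstruction of a frequency band from parcel time series.

BOLD connectivity analyses conventionally restrict to a low-frequency
band (here 0.03-0.07 Hz) before estimating correlations.  The band is
isolated with a shift-invariant (maximal-overlap / stationary) discrete
wavelet transform: the multiresolution detail component at level j has
theoretical passband [f_nyq / 2^j, f_nyq / 2^(j-1)], and the output is
the sum of the detail components whose passband falls mostly inside the
requested band.

A level is selected when the intersection of its passband with the
requested band covers at least half of the narrower of the two
intervals.  At a 2 s sampling interval (Nyquist 0.25 Hz) and the
default 0.03-0.07 Hz band this selects exactly level 3
(0.03125-0.0625 Hz); dyadic passbands cannot match an arbitrary band
exactly, and levels that merely graze the band edge are excluded.

The default filter is the least-asymmetric 16-tap wavelet (``sym8``).
Boundaries are handled by reflection padding before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .synthetic import ParcelTimeSeriesSet

__all__ = ["BandLimitedSeries", "modwt_band_reconstruct", "band_levels",
           "mra_components"]

DEFAULT_WAVELET = "sym8"
_OVERLAP_FRACTION = 0.5


@dataclass
class BandLimitedSeries:
    """Band-limited parcel series, same trial-structured indexing as input."""

    values: np.ndarray
    sampling_interval_s: float
    labels: list[str]
    conditions: list[str]
    band_hz: tuple[float, float]
    wavelet_name: str
    levels_used: list[int]

    def concatenated(self, subject: int, condition: int) -> np.ndarray:
        v = self.values[subject, condition]
        return np.concatenate(list(v), axis=1)


def band_levels(f_lo: float, f_hi: float, sampling_interval_s: float,
                max_level: int = 10) -> list[int]:
    """Decomposition levels whose passband mostly overlaps [f_lo, f_hi]."""
    f_nyq = 0.5 / sampling_interval_s
    if f_lo >= f_hi:
        raise ValueError("band must satisfy f_lo < f_hi")
    if f_lo >= f_nyq:
        raise ValueError(
            f"requested band ({f_lo}-{f_hi} Hz) lies entirely above the "
            f"Nyquist frequency {f_nyq} Hz"
        )
    if f_hi > f_nyq:
        raise ValueError(f"f_hi={f_hi} Hz exceeds the Nyquist frequency {f_nyq} Hz")
    levels = []
    for j in range(1, max_level + 1):
        lo, hi = f_nyq / 2**j, f_nyq / 2 ** (j - 1)
        overlap = min(hi, f_hi) - max(lo, f_lo)
        if overlap >= _OVERLAP_FRACTION * min(hi - lo, f_hi - f_lo):
            levels.append(j)
    if not levels:
        raise ValueError(
            f"no dyadic passband overlaps {f_lo}-{f_hi} Hz sufficiently at "
            f"sampling interval {sampling_interval_s} s"
        )
    return levels


def mra_components(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    """Additive multiresolution components [A_level, D_level, ..., D_1].

    The stationary transform requires a length divisible by 2**level,
    so the series is reflection-padded and the components cropped back;
    the components still sum to the input exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    block = 2**level
    pad = pywt.Wavelet(wavelet).dec_len * block
    if n < block:
        raise ValueError(
            f"series of length {n} is too short for a level-{level} "
            f"decomposition; at least {block} samples are required"
        )
    total = n + 2 * pad
    total = ((total + block - 1) // block) * block
    right = pad + (total - (n + 2 * pad))
    xp = np.pad(x, (pad, right), mode="reflect")
    comps = pywt.mra(xp, wavelet, level=level, transform="swt")
    return [c[pad:pad + n] for c in comps]


def _band_filter_1d(x: np.ndarray, levels: list[int], wavelet: str) -> np.ndarray:
    if np.ptp(x) == 0:
        return np.zeros_like(x)  # constant series carries no oscillatory energy
    comps = mra_components(x, wavelet, max(levels))
    # comps[0] is the smooth; detail for level j sits at index (max_level - j + 1)
    out = np.zeros_like(x)
    for j in levels:
        out += comps[max(levels) - j + 1]
    return out


def modwt_band_reconstruct(
    series: ParcelTimeSeriesSet,
    f_lo: float = 0.03,
    f_hi: float = 0.07,
    wavelet: str = DEFAULT_WAVELET,
) -> BandLimitedSeries:
    """Reconstruct the [f_lo, f_hi] wavelet component of every parcel series.

    Filtering operates on the trial-concatenated run of each
    subject/condition (single trials are far too short to support the
    required decomposition depth); the output is epoched back to the
    input's trial structure, so shapes match exactly.
    """
    levels = band_levels(f_lo, f_hi, series.sampling_interval_s)
    n_subj, n_cond, n_trials, p, spt = series.values.shape
    out = np.empty_like(series.values)
    for s in range(n_subj):
        for c in range(n_cond):
            run = series.concatenated(s, c)  # (p, n_trials * spt)
            filt = np.empty_like(run)
            for i in range(p):
                filt[i] = _band_filter_1d(run[i], levels, wavelet)
            out[s, c] = filt.reshape(p, n_trials, spt).transpose(1, 0, 2)
    return BandLimitedSeries(
        values=out,
        sampling_interval_s=series.sampling_interval_s,
        labels=list(series.labels),
        conditions=list(series.conditions),
        band_hz=(f_lo, f_hi),
        wavelet_name=wavelet,
        levels_used=levels,
    )
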