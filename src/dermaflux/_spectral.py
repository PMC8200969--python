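"""Shared Fourier-domain band-pass machinery.

A radial ideal annulus ``[low, high)`` in cycles/px selects the analysis
band. Input maps are mean-subtracted and Hann-tapered before the FFT so
that border discontinuities do not leak energy into the band; the RMS is
read back with the window's energy compensated.
"""

from __future__ import annotations

import numpy as np

__all__ = ["validate_band", "annulus_mask", "bandpass", "bandpass_rms", "band_limited_field"]


def validate_band(band: tuple[float, float]) -> tuple[float, float]:
    low, high = float(band[0]), float(band[1])
    if not (0.0 < low < high <= 0.5):
        raise ValueError(f"band must satisfy 0 < low < high <= 0.5 cycles/px, got {band}")
    return low, high


def annulus_mask(shape: tuple[int, int], band: tuple[float, float]) -> np.ndarray:
    """Boolean mask over the 2-D FFT grid for radial frequency in [low, high)."""
    low, high = validate_band(band)
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fr, fc)
    return (r >= low) & (r < high)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wr = np.hanning(shape[0])
    wc = np.hanning(shape[1])
    return wr[:, None] * wc[None, :]


def bandpass(arr: np.ndarray, band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Windowed ideal-annulus band-pass.

    Returns ``(filtered, window)`` where ``filtered`` is the filtered,
    windowed map. The DC term is removed exactly (mean subtraction before
    windowing), so a constant offset never reaches the band.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D raster, got shape {arr.shape}")
    w = _hann2d(arr.shape)
    spec = np.fft.fft2((arr - arr.mean()) * w)
    spec[~annulus_mask(arr.shape, band)] = 0.0
    return np.fft.ifft2(spec).real, w


def bandpass_rms(arr: np.ndarray, band: tuple[float, float]) -> float:
    """RMS of the in-band component, compensated for the Hann taper."""
    filtered, w = bandpass(arr, band)
    wsq = float(np.sum(w * w))
    if wsq == 0.0:
        return 0.0
    return float(np.sqrt(np.sum(filtered * filtered) / wsq))


def band_limited_field(
    shape: tuple[int, int],
    band: tuple[float, float],
    rms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian random field with support exactly inside the annulus.

    The returned field is normalized to the requested RMS exactly (zero
    field when ``rms`` is 0).
    """
    validate_band(band)
    if rms < 0:
        raise ValueError("rms must be >= 0")
    noise = rng.standard_normal(shape)
    spec = np.fft.fft2(noise)
    spec[~annulus_mask(shape, band)] = 0.0
    field = np.fft.ifft2(spec).real
    cur = float(np.sqrt(np.mean(field * field)))
    if cur == 0.0 or rms == 0.0:
        return np.zeros(shape)
    return field * (rms / cur)
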