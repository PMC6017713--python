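"""Lock-in demodulation of thermal frame stacks and image quality metrics.

A modulated buried heat source produces a surface temperature of the form
``offset + |T| cos(omega t + arg T)`` per pixel once transients have decayed.
Demodulation extracts the complex amplitude ``T`` with a single temporal DFT
bin over an integer number of modulation cycles (rectangular window — the
acquisition protocol starts after transients vanish, so leakage is controlled
by integer-cycle truncation, not tapering).

Metrics follow the conventions of modulated-thermography work: per-pixel SNR
from the signal bin against the mean non-harmonic bin power, hotspot FWHM by
linear interpolation of half-maximum crossings, transverse thermal
resolution as mean hotspot FWHM minus the physical source width, and
visibility as (max - min)/mean across a line through neighbouring sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from .model import ComplexSurfaceImage

__all__ = [
    "ThermalFrameStack",
    "MetricsRecord",
    "DemodulationError",
    "demodulate",
    "snr_map",
    "profile_fwhm",
    "fwhm",
    "find_hotspots",
    "transverse_resolution",
    "visibility",
]


class DemodulationError(ValueError):
    """The frame stack cannot be demodulated at the requested frequency."""


@dataclass(frozen=True)
class ThermalFrameStack:
    """Time-ordered surface-temperature images.

    ``frames`` has shape (nt, ny, nx) in kelvin, sampled uniformly at
    ``frame_rate`` [Hz] with square pixels of pitch ``pixel_pitch`` [m].
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (nt >= 2, ny, nx)")
        if self.frame_rate <= 0 or self.pixel_pitch <= 0:
            raise ValueError("frame_rate and pixel_pitch must be positive")
        if self.timestamps is not None:
            dt = np.diff(self.timestamps)
            if np.any(np.abs(dt - dt[0]) > 1e-6 * abs(dt[0])):
                raise ValueError("timestamps must be uniform to 1e-6 relative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class MetricsRecord:
    """Summary metrics of one demodulated scene."""

    mean_snr_db: float
    fwhm_mm: tuple[float, ...]
    transverse_resolution_mm: float
    visibility: float | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_mm):
            raise ValueError("fwhm must be > 0")
        if self.visibility is not None and self.visibility < 0:
            raise ValueError("visibility must be >= 0")


def _integer_cycle_window(stack: ThermalFrameStack, f_demod: float) -> int:
    """Largest integer-cycle window length in frames, validated."""
    fs = stack.frame_rate
    nt = stack.n_frames
    n_cycles = int(np.floor(nt * f_demod / fs + 1e-9))
    if n_cycles < 1:
        raise DemodulationError(
            f"recording ({nt / fs:.3g} s) shorter than one cycle of {f_demod} Hz")
    n_frames_f = n_cycles * fs / f_demod
    window = int(round(n_frames_f))
    if abs(window - n_frames_f) > 1e-6 * window:
        raise DemodulationError(
            f"frame rate {fs} Hz not commensurate with {f_demod} Hz: "
            f"{n_cycles} cycles span {n_frames_f} frames")
    if window < stack.n_frames:
        warnings.warn(
            f"truncating {nt} frames to {window} ({n_cycles} whole cycles)",
            stacklevel=3)
    return window


def demodulate(stack: ThermalFrameStack, f_demod: float) -> ComplexSurfaceImage:
    """Complex amplitude per pixel at ``f_demod``.

    For a pixel trace ``offset + a cos(2 pi f t + phi)`` the result is
    ``a exp(+j phi)``, i.e. the cosine-referenced complex amplitude (the same
    quantity the spectral model predicts for the surface field).  ``f_demod=0``
    returns the temporal mean.  The stack is truncated to the largest whole
    number of demodulation cycles; per-pixel means are removed first.
    """
    if f_demod < 0:
        raise DemodulationError("f_demod must be >= 0")
    if f_demod == 0.0:
        return ComplexSurfaceImage(stack.frames.mean(axis=0).astype(complex),
                                   stack.pixel_pitch, stack.pixel_pitch, 0.0)
    if f_demod >= stack.frame_rate / 2:
        raise DemodulationError(
            f"f_demod={f_demod} Hz at or above Nyquist ({stack.frame_rate / 2} Hz)")
    window = _integer_cycle_window(stack, f_demod)
    t = np.arange(window) / stack.frame_rate
    phasor = np.exp(-2j * np.pi * f_demod * t)
    data = stack.frames[:window] - stack.frames[:window].mean(axis=0)
    amp = (2.0 / window) * np.tensordot(phasor, data, axes=(0, 0))
    return ComplexSurfaceImage(amp, stack.pixel_pitch, stack.pixel_pitch, f_demod)


def snr_map(stack: ThermalFrameStack, f_demod: float,
            roi: tuple[slice, slice] | None = None,
            harmonic_guard: int = 1):
    """Per-pixel SNR [dB] at ``f_demod`` and its mean over a region of interest.

    SNR = 10 log10(power in the signal bin / mean power per non-signal bin),
    where the DC bin and ``harmonic_guard`` bins around every integer harmonic
    of the demodulation frequency are excluded from the noise estimate (a
    squared-voltage drive puts real signal in the harmonics).  Pixels with
    exactly zero noise power are reported as +inf and excluded from the mean
    with a warning.  Default ROI is the full image.
    """
    if f_demod <= 0:
        raise DemodulationError("snr_map needs f_demod > 0")
    if f_demod >= stack.frame_rate / 2:
        raise DemodulationError("f_demod at or above Nyquist")
    window = _integer_cycle_window(stack, f_demod)
    n_cycles = int(round(window * f_demod / stack.frame_rate))
    data = stack.frames[:window] - stack.frames[:window].mean(axis=0)
    spec = np.fft.rfft(data, axis=0)
    power = np.abs(spec) ** 2
    n_bins = power.shape[0]

    keep = np.ones(n_bins, dtype=bool)
    keep[0] = False
    for h in range(n_cycles, n_bins, n_cycles):
        lo = max(h - harmonic_guard, 0)
        hi = min(h + harmonic_guard + 1, n_bins)
        keep[lo:hi] = False
    if not np.any(keep):
        raise DemodulationError("no noise bins left after harmonic exclusion")

    signal = power[n_cycles]
    noise = power[keep].mean(axis=0)
    # noise at the roundoff floor of the signal bin counts as zero noise
    zero_noise = noise <= signal * 1e-24
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_db = 10.0 * np.log10(signal / noise)
    snr_db = np.where(zero_noise, np.inf, snr_db)

    region = snr_db if roi is None else snr_db[roi]
    finite = region[np.isfinite(region)]
    if finite.size < region.size:
        warnings.warn("zero-noise pixels reported as +inf and excluded from mean",
                      stacklevel=2)
    mean_db = float(finite.mean()) if finite.size else float("inf")
    return snr_db, mean_db


def profile_fwhm(profile: np.ndarray, spacing: float,
                 peak_index: int | None = None) -> float:
    """FWHM of a single-peaked 1-D profile via linear interpolation [same units
    as ``spacing``].

    Raises ``ValueError`` when a half-maximum crossing is missing on either
    side (the peak is unbounded within the profile).
    """
    prof = np.asarray(profile, dtype=float)
    if prof.ndim != 1 or prof.size < 3:
        raise ValueError("profile must be 1-D with >= 3 samples")
    i_pk = int(np.argmax(prof)) if peak_index is None else int(peak_index)
    half = prof[i_pk] / 2.0

    def cross(direction: int) -> float:
        i = i_pk
        while 0 <= i + direction < prof.size:
            j = i + direction
            if prof[j] < half:
                # linear interpolation between i and j
                frac = (prof[i] - half) / (prof[i] - prof[j])
                return i + direction * frac
            i = j
        raise ValueError("no half-maximum crossing inside the profile")

    return (cross(+1) - cross(-1)) * spacing


def fwhm(image, axis: str = "x", peak: tuple[int, int] | None = None,
         pixel_pitch: float | None = None) -> float:
    """Hotspot FWHM [mm] along an axis-aligned line through a peak.

    ``image`` is a :class:`ComplexSurfaceImage` or a 2-D magnitude array (then
    ``pixel_pitch`` [m] is required).  ``peak`` defaults to the global
    magnitude maximum.
    """
    if isinstance(image, ComplexSurfaceImage):
        mag = image.magnitude
        pitch = image.dx if axis == "x" else image.dy
    else:
        mag = np.abs(np.asarray(image))
        if pixel_pitch is None:
            raise ValueError("pixel_pitch required for bare arrays")
        pitch = pixel_pitch
    if peak is None:
        peak = np.unravel_index(int(np.argmax(mag)), mag.shape)
    iy, ix = peak
    if axis == "x":
        prof, idx = mag[iy, :], ix
    elif axis == "y":
        prof, idx = mag[:, ix], iy
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return profile_fwhm(prof, pitch, peak_index=idx) * 1e3


def find_hotspots(image, min_distance: int = 3,
                  noise_floor: float | None = None,
                  threshold_db: float = 6.0) -> list[tuple[int, int]]:
    """Local maxima above (noise floor + ``threshold_db``), ``min_distance``
    pixels apart, brightest first.

    The noise floor defaults to the median magnitude of the image.
    """
    mag = image.magnitude if isinstance(image, ComplexSurfaceImage) \
        else np.abs(np.asarray(image))
    floor = float(np.median(mag)) if noise_floor is None else noise_floor
    thresh = floor * 10.0 ** (threshold_db / 20.0)
    coords = peak_local_max(mag, min_distance=min_distance,
                            threshold_abs=thresh, exclude_border=False)
    order = np.argsort([-mag[tuple(c)] for c in coords])
    return [tuple(coords[i]) for i in order]


def transverse_resolution(image, source_width_mm: float,
                          hotspots: list[tuple[int, int]] | None = None,
                          axis: str = "x",
                          pixel_pitch: float | None = None) -> float:
    """Mean hotspot FWHM minus the physical source width [mm].

    Negative results (over-resolved relative to the physical width) are
    clipped to zero with a warning.
    """
    if hotspots is None:
        hotspots = find_hotspots(image)
    if len(hotspots) < 1:
        raise ValueError("no hotspots found")
    widths = [fwhm(image, axis=axis, peak=h, pixel_pitch=pixel_pitch)
              for h in hotspots]
    res = float(np.mean(widths)) - source_width_mm
    if res < 0:
        warnings.warn("resolution below source width; clipping to 0", stacklevel=2)
        return 0.0
    return res


def visibility(profile: np.ndarray) -> float:
    """(max - min) / mean of a magnitude profile across neighbouring sources."""
    prof = np.asarray(profile, dtype=float)
    if prof.size < 3:
        raise ValueError("visibility needs >= 3 samples")
    mean = prof.mean()
    if mean <= 0:
        raise ValueError("undefined visibility: non-positive mean")
    return float((prof.max() - prof.min()) / mean)
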