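"""Power spectra, individual alpha peak frequency, and alpha-band PSD.

The spectrum is a Welch estimate (Hann-tapered 4-s segments, 50% overlap,
0.25 Hz resolution) averaged over the selected epochs, scaled so the
one-sided PSD integrates to signal variance.  The individual alpha peak
frequency (IAF) is the largest local maximum of the PSD within 8-13 Hz, with
an explicit edge fallback flagged as ``boundary_peak``.  The alpha-band PSD
is the mean PSD over the closed window IAF ± 1 Hz — the window follows the
IAF and is deliberately NOT clipped to 8-13 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import signal

from .errors import ParameterError
from .preprocess import EpochSet

__all__ = ["Spectrum", "AlphaMetrics", "compute_psd", "detect_iaf",
           "alpha_band_psd", "subject_alpha_metrics",
           "DISTINCT_PEAK", "BOUNDARY_PEAK", "FLAT"]

DISTINCT_PEAK = "distinct_peak"
BOUNDARY_PEAK = "boundary_peak"
FLAT = "flat"

_TOL = 1e-9  # frequency-grid comparison tolerance, Hz


@dataclass
class Spectrum:
    """Per-channel one-sided power spectral density (µV²/Hz)."""

    channels: tuple[str, ...]
    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs
    fs: float
    n_epochs_averaged: int = 1

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def channel_index(self, name: str) -> int:
        up = [c.upper() for c in self.channels]
        if name.upper() not in up:
            raise ParameterError(f"channel {name!r} not in spectrum")
        return up.index(name.upper())

    def channel_psd(self, name: str) -> np.ndarray:
        return self.psd[self.channel_index(name)]


@dataclass
class AlphaMetrics:
    """Per-channel IAF and IAF-anchored alpha-band PSD for one subject."""

    subject_id: str
    channels: tuple[str, ...]
    iaf: Mapping[str, float]
    alpha_psd: Mapping[str, float]
    peak_quality: Mapping[str, str]
    mode: str = "per_electrode"


def compute_psd(epochset: EpochSet, segment_len: float = 4.0,
                overlap: float = 0.5) -> Spectrum:
    """Welch PSD averaged across epochs (Hann window, density scaling)."""
    fs = epochset.fs
    nperseg = int(round(segment_len * fs))
    if epochset.n_epochs < 1:
        raise ParameterError("need at least one epoch")
    if epochset.epochs.shape[-1] < nperseg:
        raise ParameterError(
            f"epoch of {epochset.epochs.shape[-1]} samples shorter than one "
            f"{nperseg}-sample segment")
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(epochset.epochs, fs=fs, window="hann",
                              nperseg=nperseg, noverlap=noverlap,
                              detrend="constant", scaling="density", axis=-1)
    psd = psd.mean(axis=0)  # average over epochs
    return Spectrum(channels=epochset.channels, freqs=freqs, psd=psd, fs=fs,
                    n_epochs_averaged=epochset.n_epochs)


def detect_iaf(spectrum: Spectrum, channel: str,
               band: tuple[float, float] = (8.0, 13.0)
               ) -> tuple[float, str]:
    """Locate the individual alpha peak frequency in the closed band.

    Returns ``(iaf, quality)`` where quality is ``distinct_peak`` when the
    band maximum is a strict local maximum, ``boundary_peak`` when the band
    maximum sits on a band edge with no interior local maximum, and ``flat``
    for a constant in-band spectrum (then iaf = lower band edge).
    """
    lo, hi = band
    if lo >= hi:
        raise ParameterError("band must satisfy lo < hi")
    f = spectrum.freqs
    if lo < f[0] - _TOL or hi > f[-1] + _TOL:
        raise ParameterError(f"band {band} outside frequency grid "
                             f"[{f[0]}, {f[-1]}]")
    p = spectrum.channel_psd(channel)
    in_band = np.flatnonzero((f >= lo - _TOL) & (f <= hi + _TOL))
    pb = p[in_band]

    if np.allclose(pb, pb[0], rtol=0.0, atol=0.0):
        return float(f[in_band[0]]), FLAT

    # candidate local maxima: strictly greater than both full-grid neighbours
    candidates = []
    for j in in_band:
        left = p[j - 1] if j - 1 >= 0 else -np.inf
        right = p[j + 1] if j + 1 < len(p) else -np.inf
        if p[j] > left and p[j] > right:
            candidates.append(j)
    if candidates:
        vals = p[candidates]
        best = max(vals)
        # tie toward the lower frequency: first index attaining the max
        j = candidates[int(np.flatnonzero(vals == best)[0])]
        return float(f[j]), DISTINCT_PEAK

    # no local maximum in band: the maximum must sit on a band edge
    j = in_band[int(np.argmax(pb))]
    return float(f[j]), BOUNDARY_PEAK


def alpha_band_psd(spectrum: Spectrum, channel: str, iaf: float) -> float:
    """Mean PSD over the closed window [iaf - 1, iaf + 1] Hz."""
    f = spectrum.freqs
    lo, hi = iaf - 1.0, iaf + 1.0
    if lo < f[0] - _TOL or hi > f[-1] + _TOL:
        raise ParameterError(
            f"window [{lo}, {hi}] Hz outside frequency grid")
    sel = (f >= lo - _TOL) & (f <= hi + _TOL)
    return float(spectrum.channel_psd(channel)[sel].mean())


def subject_alpha_metrics(epochset: EpochSet, mode: str = "per_electrode",
                          band: tuple[float, float] = (8.0, 13.0),
                          spectrum: Optional[Spectrum] = None) -> AlphaMetrics:
    """IAF and alpha-band PSD for every channel of one subject.

    ``per_electrode``: each channel is evaluated at its own IAF.
    ``occipital_mean``: a single IAF (mean of the O1 and O2 IAFs) is applied
    to every channel.
    """
    if mode not in ("per_electrode", "occipital_mean"):
        raise ParameterError(f"unknown mode {mode!r}")
    spec = spectrum if spectrum is not None else compute_psd(epochset)

    iafs: dict[str, float] = {}
    quality: dict[str, str] = {}
    for ch in spec.channels:
        iafs[ch], quality[ch] = detect_iaf(spec, ch, band)

    if mode == "occipital_mean":
        try:
            common = 0.5 * (iafs["O1"] + iafs["O2"])
        except KeyError:
            raise ParameterError(
                "occipital_mean mode requires O1 and O2") from None
        eval_iaf = {ch: common for ch in spec.channels}
    else:
        eval_iaf = iafs

    apsd = {ch: alpha_band_psd(spec, ch, eval_iaf[ch]) for ch in spec.channels}
    return AlphaMetrics(subject_id=epochset.subject_id, channels=spec.channels,
                        iaf=eval_iaf, alpha_psd=apsd, peak_quality=quality,
                        mode=mode)
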