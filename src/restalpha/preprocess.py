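"""Filtering, re-referencing and artifact-screened epoch selection.

The band-pass is a cascade of zero-phase Butterworth high-pass and low-pass
stages (sosfiltfilt).  A gentle high-pass (order 2) keeps the DC-step
transient short while the steeper low-pass (order 6) still attenuates mains
frequencies by >26 dB after the forward-backward pass.

Epoch screening is a deterministic surrogate for visual artifact rejection:
the recording is tiled into non-overlapping candidate epochs, each scored by
the maximum peak-to-peak amplitude across channels, candidates above a hard
threshold are excluded, and the ``n_select`` lowest-scoring epochs win (ties
broken by earlier onset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .edfio import Recording
from .errors import MontageError, ParameterError, QualityError

__all__ = ["EpochSet", "bandpass_filter", "rereference", "screen_epochs",
           "remove_artifact_components"]


@dataclass
class EpochSet:
    """Selected artifact-screened epochs of one subject."""

    subject_id: str
    channels: tuple[str, ...]
    fs: float
    epochs: np.ndarray            # n_epochs x channels x samples, µV
    epoch_onsets: np.ndarray      # seconds into the source recording
    screening_scores: np.ndarray  # per *candidate* epoch, µV peak-to-peak
    epoch_len: float = 20.0
    ica_removed: Optional[int] = None
    ica_failed: bool = False

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def channel_index(self, name: str) -> int:
        up = [c.upper() for c in self.channels]
        if name.upper() not in up:
            raise ParameterError(f"channel {name!r} not in epoch set")
        return up.index(name.upper())


def bandpass_filter(recording: Recording, low: float = 1.0, high: float = 45.0,
                    hp_order: int = 2, lp_order: int = 6) -> Recording:
    """Zero-phase band-pass: Butterworth high-pass + low-pass, filtfilt."""
    fs = recording.fs
    if not (0.0 < low < high < fs / 2.0):
        raise ParameterError(
            f"cutoffs must satisfy 0 < {low} < {high} < fs/2 = {fs / 2}")
    sos_hp = signal.butter(hp_order, low, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(lp_order, high, btype="lowpass", fs=fs, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    out = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return recording.copy_with(data=out)


def rereference(recording: Recording, scheme: str = "T9T10") -> Recording:
    """Subtract the mean of the two retroauricular channels from every channel."""
    if scheme != "T9T10":
        raise ParameterError(f"unknown reference scheme {scheme!r}")
    try:
        t9 = recording.get("T9")
        t10 = recording.get("T10")
    except ParameterError:
        raise MontageError("reference channels T9/T10 missing") from None
    ref = 0.5 * (t9 + t10)
    return recording.copy_with(data=recording.data - ref[None, :],
                               reference="T9T10")


def screen_epochs(recording: Recording, epoch_len: float = 20.0,
                  n_select: int = 8, hard_threshold: float = 400.0) -> EpochSet:
    """Select the ``n_select`` cleanest non-overlapping epochs.

    Candidates are tiled from t = 0.  Score = max over channels of
    peak-to-peak amplitude; scores above ``hard_threshold`` µV disqualify a
    candidate outright.
    """
    fs = recording.fs
    samples = int(round(epoch_len * fs))
    if samples <= 0:
        raise ParameterError("epoch length must be positive")
    n_cand = recording.n_samples // samples
    if n_cand < n_select:
        raise ParameterError(
            f"recording admits only {n_cand} candidate epochs; "
            f"{n_select} requested")

    cands = recording.data[:, :n_cand * samples].reshape(
        recording.data.shape[0], n_cand, samples)
    scores = (cands.max(axis=2) - cands.min(axis=2)).max(axis=0)

    eligible = np.flatnonzero(scores <= hard_threshold)
    if len(eligible) < n_select:
        raise QualityError(
            f"only {len(eligible)} candidate epochs below the "
            f"{hard_threshold} µV threshold (need {n_select}); "
            f"scores: {np.round(scores, 1).tolist()}")

    # stable sort on score -> ties broken by earlier onset
    order = eligible[np.argsort(scores[eligible], kind="stable")]
    chosen = np.sort(order[:n_select])

    epochs = cands[:, chosen, :].transpose(1, 0, 2).copy()
    onsets = chosen * samples / fs
    return EpochSet(subject_id=recording.subject_id,
                    channels=recording.channels, fs=fs, epochs=epochs,
                    epoch_onsets=onsets.astype(float),
                    screening_scores=scores, epoch_len=epoch_len)


def remove_artifact_components(epochset: EpochSet,
                               template_channels: Sequence[str] = ("Fp1", "Fp2"),
                               corr_threshold: float = 0.8,
                               max_iter: int = 500,
                               random_state: int = 0) -> EpochSet:
    """Optional ICA-based blink removal (off by default in the pipeline).

    Components whose absolute correlation with the mean of the frontal
    template channels exceeds ``corr_threshold`` are zeroed before
    reconstruction.  On decomposition failure the input is returned
    unchanged with ``ica_failed`` set.
    """
    if len(epochset.channels) < 2:
        raise ParameterError("ICA requires at least 2 channels")
    n_ep, n_ch, n_s = epochset.epochs.shape
    X = epochset.epochs.transpose(1, 0, 2).reshape(n_ch, n_ep * n_s)
    try:
        idx = [epochset.channel_index(c) for c in template_channels]
    except ParameterError:
        raise MontageError(
            f"template channels {template_channels} missing") from None
    template = X[idx].mean(axis=0)

    try:
        from sklearn.decomposition import FastICA
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(n_components=n_ch, max_iter=max_iter,
                          random_state=random_state, whiten="unit-variance")
            sources = ica.fit_transform(X.T)  # (t, k)
        mixing = ica.mixing_                  # (n_ch, k)
        mean = ica.mean_
    except Exception:
        out = EpochSet(**{**epochset.__dict__})
        out.epochs = epochset.epochs.copy()
        out.ica_failed = True
        out.ica_removed = None
        return out

    t_sd = template.std()
    removed = 0
    keep = sources.copy()
    for k in range(sources.shape[1]):
        s_sd = sources[:, k].std()
        if t_sd == 0 or s_sd == 0:
            continue
        corr = float(np.corrcoef(sources[:, k], template)[0, 1])
        if abs(corr) > corr_threshold:
            keep[:, k] = 0.0
            removed += 1

    X_clean = (keep @ mixing.T + mean).T
    epochs = X_clean.reshape(n_ch, n_ep, n_s).transpose(1, 0, 2).copy()
    out = EpochSet(**{**epochset.__dict__})
    out.epochs = epochs
    out.ica_removed = removed
    out.ica_failed = False
    return out
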