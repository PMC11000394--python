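"""Seeded synthetic resting-EEG cohort generator.

Each channel is the sum of three independent Gaussian processes plus
transient blink artifacts:

* an aperiodic 1/f^beta background, synthesized directly in the frequency
  domain from its target power spectral density;
* a narrowband alpha component with a Gaussian spectral bump (1 Hz FWHM)
  centred on the subject's true alpha peak frequency, rescaled to an exact
  per-channel RMS amplitude;
* white sensor noise;
* Poisson-placed biphasic blink transients (~0.5 s, 150 µV peak) weighted
  onto the frontal channels.

Cohorts are matched case/control pairs: each pair shares age and sex, a
fixed fraction of pairs carries the migraine flag in both members, and the
case member's alpha amplitude at the effect channels is multiplied by
``delta``.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .edfio import Recording, write_edf
from .errors import ParameterError
from .montage import Montage, standard_montage

__all__ = [
    "SubjectSpec", "CohortSpec", "simulate_subject", "simulate_cohort",
    "draw_cohort_manifest", "save_cohort", "default_alpha_topography",
    "ALPHA_FWHM_HZ",
]

#: Full width at half maximum of the alpha spectral bump (Hz).
ALPHA_FWHM_HZ = 1.0
_ALPHA_SIGMA = ALPHA_FWHM_HZ / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Region -> relative alpha RMS weight (posterior-dominant topography).
DEFAULT_REGION_WEIGHTS: Mapping[str, float] = {
    "occipital": 1.0,
    "parietal": 0.7,
    "temporal": 0.35,
    "central": 0.3,
    "frontal": 0.1,
    "inferior": 0.3,
}
# The inferior chain is heterogeneous: P9/P10 sit close to the occipito-
# temporal sources, T9/T10 and F9/F10 do not.
_INFERIOR_OVERRIDES = {"P9": 0.5, "P10": 0.5, "T9": 0.15, "T10": 0.15,
                       "F9": 0.1, "F10": 0.1}

_BLINK_WEIGHTS = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.5, "F8": 0.5}


def default_alpha_topography(montage: Montage, base_amp: float = 0.7
                             ) -> dict[str, float]:
    """Per-channel alpha RMS amplitudes (µV) for a posterior-dominant rhythm."""
    out = {}
    for e in montage:
        w = _INFERIOR_OVERRIDES.get(e.name, DEFAULT_REGION_WEIGHTS[e.region])
        out[e.name] = base_amp * w
    return out


@dataclass
class SubjectSpec:
    """Generative parameters for one synthetic subject."""

    subject_id: str
    group: str  # "case" or "control"
    iaf_true: float
    alpha_amp: Mapping[str, float]  # per-channel RMS, µV
    aperiodic_exponent: float = 1.5
    aperiodic_scale: float = 1.0  # µV²/Hz at 1 Hz
    noise_sd: float = 2.0  # µV
    artifact_rate: float = 2.0  # blink events / min
    age: float = 33.0
    sex: str = "m"
    migraine: bool = False

    def __post_init__(self):
        if not (8.5 <= self.iaf_true <= 12.5):
            raise ParameterError(
                f"iaf_true {self.iaf_true} outside [8.5, 12.5] Hz")
        if any(a < 0 for a in self.alpha_amp.values()):
            raise ParameterError("alpha_amp must be non-negative")
        if self.aperiodic_exponent < 0:
            raise ParameterError("aperiodic_exponent must be >= 0")


@dataclass
class CohortSpec:
    """Parameters of a matched two-group synthetic cohort."""

    n_per_group: int = 21
    effect_channels: tuple[str, ...] = ("P3", "P4", "Pz", "P10", "T3", "T4")
    delta: float = 1.0  # case alpha-amplitude factor at effect channels
    # mean true IAF per (group, migraine) cell, Hz
    iaf_means: Mapping[tuple[str, bool], float] = field(default_factory=lambda: {
        ("control", False): 10.1,
        ("case", False): 10.6,
        ("control", True): 10.3,
        ("case", True): 10.3,
    })
    iaf_sd: float = 0.4  # doubled in migraine strata
    duration: float = 200.0  # s
    fs: float = 250.0
    seed: int = 0
    base_alpha_amp: float = 0.7  # µV RMS at O1/O2
    aperiodic_exponent: float = 1.5
    aperiodic_scale: float = 1.0
    noise_sd: float = 2.0
    artifact_rate: float = 2.0
    migraine_fraction: float = 14.0 / 21.0
    male_fraction: float = 13.0 / 21.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ParameterError("delta must be positive")
        if self.n_per_group < 2:
            raise ParameterError("need at least 2 subjects per group")
        if self.duration < 8 * 20.0:
            raise ParameterError(
                "duration must admit at least eight disjoint 20-s epochs")


def _freq_domain_noise(rng: np.random.Generator, n: int, fs: float,
                       one_sided_psd: np.ndarray,
                       n_series: int = 1) -> np.ndarray:
    """Stationary Gaussian series with the given one-sided target PSD.

    Returns an (n_series, n) array; rows are independent realizations.
    """
    n_freq = len(one_sided_psd)
    amp = np.sqrt(one_sided_psd * fs * n / 2.0)
    z = (rng.standard_normal((n_series, n_freq))
         + 1j * rng.standard_normal((n_series, n_freq))) / np.sqrt(2.0)
    spec = amp[None, :] * z
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _blink_waveform(fs: float) -> np.ndarray:
    """Biphasic ~0.5 s transient with unit peak amplitude."""
    t = np.arange(int(round(0.5 * fs))) / fs
    w = np.sin(2.0 * np.pi * 2.0 * t) * np.hanning(len(t))
    return w / np.abs(w).max()


def simulate_subject(spec: SubjectSpec, montage: Optional[Montage] = None,
                     duration: float = 600.0, fs: float = 250.0,
                     seed: int = 0) -> Recording:
    """Generate one subject's multichannel recording (µV), deterministically."""
    montage = montage if montage is not None else standard_montage()
    if duration < 180.0:
        raise ParameterError("duration must be at least 180 s")
    if fs < 100.0:
        raise ParameterError("sampling rate must be at least 100 Hz")
    lo, hi = spec.iaf_true - 1.0, spec.iaf_true + 1.0
    if not (0.0 < lo and hi < fs / 2.0):
        raise ParameterError(
            f"alpha band [{lo}, {hi}] Hz outside (0, {fs / 2}) Hz")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    n_ch = len(montage)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    with np.errstate(divide="ignore"):
        aper_psd = spec.aperiodic_scale * np.where(
            freqs > 0, freqs, np.inf) ** (-spec.aperiodic_exponent)
    aper_psd[0] = 0.0

    alpha_psd = np.exp(-0.5 * ((freqs - spec.iaf_true) / _ALPHA_SIGMA) ** 2)

    names = montage.names
    data = _freq_domain_noise(rng, n, fs, aper_psd, n_series=n_ch)
    alpha = _freq_domain_noise(rng, n, fs, alpha_psd, n_series=n_ch)
    amps = np.array([float(spec.alpha_amp.get(name, 0.0)) for name in names])
    rms = np.sqrt(np.mean(alpha ** 2, axis=-1))
    scale = np.where(rms > 0, amps / np.where(rms > 0, rms, 1.0), 0.0)
    data += alpha * scale[:, None]
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal((n_ch, n))

    # blink transients, frontally weighted
    n_blinks = rng.poisson(spec.artifact_rate * duration / 60.0)
    wave = _blink_waveform(fs)
    for _ in range(n_blinks):
        onset = int(rng.integers(0, max(1, n - len(wave))))
        polarity = 150.0
        for name, w in _BLINK_WEIGHTS.items():
            if name in montage:
                i = names.index(montage.canonical(name))
                data[i, onset:onset + len(wave)] += polarity * w * wave

    return Recording(subject_id=spec.subject_id, channels=names, fs=fs,
                     data=data, reference="Cz")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def draw_cohort_manifest(spec: CohortSpec, montage: Optional[Montage] = None
                         ) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw all subject-level generative parameters (no signals).

    Returns the per-subject specs (cases then controls within each matched
    pair) and the manifest table recording every true parameter.
    """
    montage = montage if montage is not None else standard_montage()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0F0]))
    n = spec.n_per_group
    n_migraine = int(round(spec.migraine_fraction * n))
    n_male = int(round(spec.male_fraction * n))
    base_amp = default_alpha_topography(montage, spec.base_alpha_amp)

    subjects: list[SubjectSpec] = []
    rows = []
    for pair in range(n):
        age = float(np.clip(rng.normal(33.0, 10.0), 18.0, 65.0))
        sex = "m" if pair < n_male else "f"
        migraine = pair < n_migraine
        for group in ("case", "control"):
            sd = spec.iaf_sd * (2.0 if migraine else 1.0)
            mean = spec.iaf_means[(group, migraine)]
            iaf = _truncated_normal(rng, mean, sd, 8.5, 12.5)
            amp = dict(base_amp)
            if group == "case" and spec.delta != 1.0:
                for ch in spec.effect_channels:
                    canon = montage.canonical(ch)
                    amp[canon] = amp[canon] * spec.delta
            sid = f"{'V' if group == 'case' else 'C'}{pair + 1:02d}"
            subj = SubjectSpec(
                subject_id=sid, group=group, iaf_true=iaf, alpha_amp=amp,
                aperiodic_exponent=spec.aperiodic_exponent,
                aperiodic_scale=spec.aperiodic_scale,
                noise_sd=spec.noise_sd, artifact_rate=spec.artifact_rate,
                age=age, sex=sex, migraine=migraine)
            subjects.append(subj)
            row = {"subject_id": sid, "group": group, "age": age, "sex": sex,
                   "migraine": migraine, "iaf_true": iaf}
            for ch, a in amp.items():
                row[f"alpha_amp_{ch}"] = a
            rows.append(row)
    manifest = pd.DataFrame(rows)
    return subjects, manifest


def simulate_cohort(spec: CohortSpec, montage: Optional[Montage] = None
                    ) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a full matched cohort; deterministic given ``spec.seed``."""
    montage = montage if montage is not None else standard_montage()
    subjects, manifest = draw_cohort_manifest(spec, montage)
    # one child seed per subject, derived from the cohort seed
    seeds = np.random.SeedSequence([spec.seed, 0x51D5]).generate_state(len(subjects))
    recordings = [
        simulate_subject(subj, montage, duration=spec.duration, fs=spec.fs,
                         seed=int(s))
        for subj, s in zip(subjects, seeds)
    ]
    return recordings, manifest


def save_cohort(recordings: Sequence[Recording], manifest: pd.DataFrame,
                out_dir) -> list[Path]:
    """Write one EDF per subject plus a tab-separated manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        p = out_dir / f"{rec.subject_id}.edf"
        write_edf(rec, p)
        paths.append(p)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return paths
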