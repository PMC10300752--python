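"""Synthetic NIRS-like breathing signals for the three study conditions.

The generator emulates the qualitative structure of chest-wall NIRS
hemodynamics during controlled breathing tasks: a quasi-periodic
respiratory oscillation riding on slow drift plus sensor noise. The three
conditions differ the way the real tasks do — loaded breathing (breathing
against resistance) has the largest oscillation amplitude, rapid/shallow
breathing is paced at 25 breaths/min and has the shortest period and the
smallest amplitude, and relaxed baseline breathing sits between them.

Model per recording: breath i has a rate r_i ~ N(rate_mean, rate_jitter)
and amplitude a_i ~ N(amplitude_mean, amplitude_jitter); phase advances
2*pi per breath. The waveform is sin(phase) + 0.2 sin(2*phase) — the fixed
second harmonic keeps the classes from being trivially linearly separable —
scaled by the breath's amplitude, plus a slow sinusoidal drift and white
Gaussian noise. HHb is generated anti-phase at 0.4x the O2Hb amplitude
with independent noise of the same standard deviation (so its
signal-to-noise ratio is lower, as observed for real HHb); THb is their
sum. All numeric defaults other than the 25 breaths/min pacing and the
amplitude/period ordering are generator choices, collected in
:data:`DEFAULT_PARAMS` and editable per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import periodogram

from .nirs_io import Condition, NirsRecording, Window, crop_windows

__all__ = [
    "ConditionParams",
    "DEFAULT_PARAMS",
    "SECOND_HARMONIC",
    "HHB_RATIO",
    "simulate_recording",
    "make_synthetic_dataset",
    "dominant_frequency",
    "PeriodogramOracle",
]

#: Fixed second-harmonic fraction of the breath waveform.
SECOND_HARMONIC = 0.2
#: HHb oscillation amplitude relative to O2Hb (anti-phase).
HHB_RATIO = 0.4


@dataclass(frozen=True)
class ConditionParams:
    """Generator parameters for one breathing condition.

    rate_mean/rate_jitter are in breaths per minute (mean and per-breath
    standard deviation); amplitudes and noise are in the same arbitrary
    concentration units as the output signal; drift_period is in seconds.
    """

    rate_mean: float
    rate_jitter: float
    amplitude_mean: float
    amplitude_jitter: float
    drift_amplitude: float
    drift_period: float
    noise_sd: float

    def __post_init__(self):
        if self.rate_mean <= 0:
            raise ValueError("rate_mean must be positive")
        for name in ("rate_jitter", "amplitude_jitter", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")


#: Default condition parameters. The rapid/shallow rate of 25 breaths/min is
#: the paced rate of the task it emulates; the rest encode the qualitative
#: ordering (loaded largest amplitude, rapid shortest period and smallest
#: amplitude) with magnitudes chosen once for this generator.
DEFAULT_PARAMS: dict[Condition, ConditionParams] = {
    Condition.BASELINE: ConditionParams(
        rate_mean=14.0, rate_jitter=1.0, amplitude_mean=1.0,
        amplitude_jitter=0.15, drift_amplitude=0.5, drift_period=60.0,
        noise_sd=0.1),
    Condition.LOADED: ConditionParams(
        rate_mean=12.0, rate_jitter=1.0, amplitude_mean=2.5,
        amplitude_jitter=0.375, drift_amplitude=0.5, drift_period=60.0,
        noise_sd=0.1),
    Condition.RAPID_SHALLOW: ConditionParams(
        rate_mean=25.0, rate_jitter=2.0, amplitude_mean=0.5,
        amplitude_jitter=0.075, drift_amplitude=0.5, drift_period=60.0,
        noise_sd=0.1),
}


def _breath_track(duration: float, p: ConditionParams,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-breath start times, durations and amplitudes covering duration."""
    starts, durs, amps = [], [], []
    t = 0.0
    while t < duration:
        rate = max(rng.normal(p.rate_mean, p.rate_jitter), 0.2 * p.rate_mean)
        amp = max(rng.normal(p.amplitude_mean, p.amplitude_jitter), 0.0)
        starts.append(t)
        durs.append(60.0 / rate)
        amps.append(amp)
        t += durs[-1]
    return np.array(starts), np.array(durs), np.array(amps)


def simulate_recording(
    condition: Condition | str,
    duration: float,
    sampling_rate: float = 10.0,
    params: ConditionParams | None = None,
    seed: int = 0,
    subject_id: str = "sim",
    include_thb: bool = True,
) -> NirsRecording:
    """Generate one synthetic recording for a breathing condition.

    Identical arguments (including ``seed``) give bit-identical output.
    """
    condition = Condition(condition)
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = params if params is not None else DEFAULT_PARAMS[condition]
    rng = np.random.default_rng(seed)

    starts, durs, amps = _breath_track(duration, p, rng)
    drift_phase = rng.uniform(0.0, 2.0 * math.pi)

    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    phase = 2.0 * math.pi * (idx + (t - starts[idx]) / durs[idx])
    wave = np.sin(phase) + SECOND_HARMONIC * np.sin(2.0 * phase)
    osc = amps[idx] * wave
    drift = p.drift_amplitude * np.sin(2.0 * math.pi * t / p.drift_period + drift_phase)

    o2hb = osc + drift + rng.normal(0.0, p.noise_sd, size=n)
    hhb = -HHB_RATIO * osc + rng.normal(0.0, p.noise_sd, size=n)
    channels = {"O2Hb": o2hb, "HHb": hhb}
    if include_thb:
        channels["THb"] = o2hb + hhb
    return NirsRecording(subject_id=subject_id, condition=condition,
                         channels=channels, sampling_rate=sampling_rate)


def _subject_params(base: ConditionParams,
                    rng: np.random.Generator) -> ConditionParams:
    """Mild between-subject variability: +-~4% rate, ~10% amplitude."""
    return replace(
        base,
        rate_mean=max(base.rate_mean + rng.normal(0.0, 0.5), 1.0),
        amplitude_mean=max(base.amplitude_mean * rng.normal(1.0, 0.1),
                           0.1 * base.amplitude_mean),
    )


def make_synthetic_dataset(
    n_per_class: int,
    window_len: int = 64,
    seed: int = 0,
    sampling_rate: float = 10.0,
    windows_per_subject: int = 10,
    params: dict[Condition, ConditionParams] | None = None,
) -> list[Window]:
    """Generate a balanced labeled window set from per-subject recordings.

    Each synthetic subject contributes one recording per condition (as in
    the study design), sized to yield ``windows_per_subject`` windows, so
    subject-level splitting is exercisable. Exactly ``n_per_class`` windows
    per condition are returned.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if windows_per_subject < 1:
        raise ValueError("windows_per_subject must be >= 1")
    params = params if params is not None else DEFAULT_PARAMS
    n_subjects = math.ceil(n_per_class / windows_per_subject)
    duration = windows_per_subject * window_len / sampling_rate
    ss = np.random.SeedSequence(seed)
    windows: list[Window] = []
    for s, subj_ss in enumerate(ss.spawn(n_subjects)):
        subject_id = f"S{s:03d}"
        subj_rng = np.random.default_rng(subj_ss)
        for condition in Condition:
            cond_params = _subject_params(params[condition], subj_rng)
            rec_seed = int(subj_rng.integers(2**31))
            rec = simulate_recording(
                condition, duration, sampling_rate, cond_params,
                seed=rec_seed, subject_id=subject_id)
            windows.extend(crop_windows(rec, window_len, window_len))
    by_class: dict[Condition, list[Window]] = {c: [] for c in Condition}
    for w in windows:
        if len(by_class[w.label]) < n_per_class:
            by_class[w.label].append(w)
    out: list[Window] = []
    for c in Condition:
        assert len(by_class[c]) == n_per_class
        out.extend(by_class[c])
    return out


# ---------------------------------------------------------------------------
# Periodogram oracle — an independent, training-free reference classifier
# ---------------------------------------------------------------------------

def dominant_frequency(values: np.ndarray, sampling_rate: float = 10.0,
                       nfft: int = 512) -> float:
    """Frequency (Hz) of the largest non-DC periodogram peak of a 1D signal."""
    x = np.asarray(values, dtype=np.float64).ravel()
    freqs, power = periodogram(x - x.mean(), fs=sampling_rate, nfft=nfft)
    return float(freqs[1:][np.argmax(power[1:])])


@dataclass
class PeriodogramOracle:
    """Two-threshold rule classifier on spectral peak and amplitude.

    Rapid/shallow breathing is identified by its dominant frequency above
    ``freq_threshold``; the remaining windows are called loaded when the
    O2Hb peak-to-peak amplitude exceeds ``amplitude_threshold``, else
    baseline. Used as a floor any trained model must beat, and to verify
    the generator's class signatures independently of the network.
    """

    freq_threshold: float = 0.33  # Hz, between ~14 and 25 breaths/min
    amplitude_threshold: float = 3.5  # between baseline/loaded peak-to-peak
    sampling_rate: float = 10.0

    @classmethod
    def fit(cls, windows, sampling_rate: float = 10.0) -> "PeriodogramOracle":
        """Set both thresholds at midpoints of per-class medians."""
        feats = {c: [] for c in Condition}
        for w in windows:
            o2hb = w.values[w.channel_names.index("O2Hb")]
            feats[w.label].append((dominant_frequency(o2hb, sampling_rate),
                                   float(np.ptp(o2hb))))
        med = {c: np.median(np.array(v), axis=0) for c, v in feats.items()}
        slow = max(med[Condition.BASELINE][0], med[Condition.LOADED][0])
        f_thr = 0.5 * (slow + med[Condition.RAPID_SHALLOW][0])
        a_thr = 0.5 * (med[Condition.BASELINE][1] + med[Condition.LOADED][1])
        return cls(freq_threshold=f_thr, amplitude_threshold=a_thr,
                   sampling_rate=sampling_rate)

    def classify(self, window: Window) -> Condition:
        o2hb = window.values[window.channel_names.index("O2Hb")]
        if dominant_frequency(o2hb, self.sampling_rate) > self.freq_threshold:
            return Condition.RAPID_SHALLOW
        if float(np.ptp(o2hb)) > self.amplitude_threshold:
            return Condition.LOADED
        return Condition.BASELINE

    def accuracy(self, windows) -> float:
        """Fraction of windows classified correctly (0-1 scale)."""
        hits = sum(self.classify(w) == w.label for w in windows)
        return hits / len(windows)
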