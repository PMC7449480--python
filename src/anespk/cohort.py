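"""Synthetic EEG/AEP cohort generation.

Emulates an anesthesia transition protocol: each patient contributes a
sequence of loss/return-of-consciousness events (LOC1, ROC1, LOC2, ROC2),
and every event yields one "conscious" and one "unconscious" data point —
a 10 s EEG epoch plus a train of auditory-evoked-potential (AEP) sweeps.

The EEG generative model is a convex mixture of two fixed spectral shapes:
a delta/theta-dominant "unconscious" shape and a broadband "conscious"
shape with alpha, beta and gamma content.  The mixing weight shifts with
the state of consciousness by ``eeg_effect`` and with the patient by a
Gaussian offset of SD ``between_patient_sd``, so spectral and
entropy-based features respond to state in the clinically documented
direction (spectral slowing and increased regularity under anesthesia).

The AEP model is a mid-latency template of two Gabor-like deflections
(positive near 30 ms, negative near 45 ms — Pa/Nb analogues) buried in
EEG-like background noise; unconsciousness attenuates the deflections by
``aep_amplitude_effect`` and delays them by ``aep_latency_effect`` ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CohortConfig",
    "EpochedSignal",
    "AEPSweepSet",
    "generate_cohort",
    "inject_artifacts",
    "event_sequence",
]

STATES = ("conscious", "unconscious")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_patients : int
        Number of patients in the cohort.
    sampling_rate : float
        EEG/AEP sampling rate in Hz.
    epoch_duration : float
        Duration of one EEG epoch in seconds.
    events_per_patient : int
        Number of consciousness transitions per patient; each contributes
        one conscious and one unconscious data point.
    sweeps_per_aep : int
        Number of stimulus-locked sweeps averaged into one AEP.
    stimulus_rate : float
        Auditory stimulus rate in Hz (bookkeeping only; sweeps are
        generated directly in their post-stimulus windows).
    aep_window_ms : (float, float)
        Post-stimulus sweep window in ms; must cover the mid-latency
        range 20-120 ms.
    eeg_effect : float
        Dimensionless separation of the spectral mixing weight between
        states (0 = no EEG state effect, 1 = maximal).
    aep_amplitude_effect : float
        Fractional attenuation of the mid-latency deflections when
        unconscious (0-1).
    aep_latency_effect : float
        Latency delay of the deflections in ms when unconscious.
    between_patient_sd : float
        SD of the per-patient offsets on the spectral mixing weight and
        (log) AEP amplitude.
    patient_sensitivity_sd : float
        SD of the per-patient multiplicative sensitivity of each
        modality's state effect.  The EEG and AEP sensitivities are
        drawn independently, so a patient may separate well in one
        modality and poorly in the other — the situation a combined
        index exploits.
    artifact_rate : float
        Probability that :func:`inject_artifacts` corrupts an epoch.
    seed : int
        Root seed; expands into independent per-patient substreams.
    """

    n_patients: int = 40
    sampling_rate: float = 1000.0
    epoch_duration: float = 10.0
    events_per_patient: int = 4
    sweeps_per_aep: int = 256
    stimulus_rate: float = 3.9
    aep_window_ms: Tuple[float, float] = (0.0, 256.0)
    eeg_effect: float = 0.15
    aep_amplitude_effect: float = 0.25
    aep_latency_effect: float = 4.0
    between_patient_sd: float = 0.08
    patient_sensitivity_sd: float = 0.55
    artifact_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        n = self.epoch_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9 or n < 2:
            raise ValueError(
                "epoch_duration x sampling_rate must be an integer sample count"
            )
        if self.events_per_patient < 1:
            raise ValueError("events_per_patient must be >= 1")
        if self.sweeps_per_aep < 1:
            raise ValueError("sweeps_per_aep must be >= 1")
        for name in ("eeg_effect", "aep_amplitude_effect", "aep_latency_effect",
                     "between_patient_sd", "patient_sensitivity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        lo, hi = self.aep_window_ms
        if not (lo <= 20.0 and hi >= 120.0):
            raise ValueError("aep_window_ms must cover the mid-latency range 20-120 ms")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sampling_rate))


@dataclass
class EpochedSignal:
    """A fixed-rate signal segment with provenance labels."""

    samples: np.ndarray          # muV
    sampling_rate: float         # Hz
    patient_id: str
    event_label: str             # LOC1 / ROC1 / LOC2 / ROC2 / ...
    state: str                   # conscious | unconscious
    channel_label: str = "AT1-Fpz"
    artifact_truth: Optional[str] = None   # set by inject_artifacts; None = clean

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class AEPSweepSet:
    """Stimulus-locked AEP sweeps for one data point.

    ``sweeps`` is a 2-D array (n_sweeps, n_samples); ``window`` gives the
    (pre-stimulus, post-stimulus) extent in ms.
    """

    sweeps: np.ndarray
    sampling_rate: float
    window: Tuple[float, float]
    patient_id: str
    event_label: str
    state: str
    channel_label: str = "M2-Fpz"

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))


def event_sequence(n_events: int) -> List[str]:
    """LOC1, ROC1, LOC2, ROC2, LOC3, ... for ``n_events`` transitions."""
    return [("LOC" if i % 2 == 0 else "ROC") + str(i // 2 + 1)
            for i in range(n_events)]


# ---------------------------------------------------------------------------
# Spectral shapes of the two canonical states (unit total power each).
# Conscious: residual delta + alpha peak + beta/gamma plateau out to ~80 Hz.
# Unconscious: dominant delta/theta, weak alpha, negligible gamma.
# ---------------------------------------------------------------------------

def _gauss(f: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((f - mu) / sd) ** 2)


def _plateau(f: np.ndarray, lo: float, hi: float, soft: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(f - lo) / soft)) / (1.0 + np.exp((f - hi) / soft))


def _shape_conscious(f: np.ndarray) -> np.ndarray:
    s = (0.25 / (1.0 + (f / 4.0) ** 4)
         + 0.35 * _gauss(f, 10.0, 3.0)
         + 0.50 * _plateau(f, 15.0, 70.0, 4.0))
    return s


def _shape_unconscious(f: np.ndarray) -> np.ndarray:
    s = (1.60 / (1.0 + (f / 3.5) ** 4)
         + 0.10 * _gauss(f, 8.0, 3.0)
         + 0.015 * _plateau(f, 10.0, 45.0, 4.0))
    return s


def _mixture_density(freqs: np.ndarray, w: float) -> np.ndarray:
    """Spectral density of the state mixture; w = 1 fully conscious."""
    band = (freqs >= 0.5) & (freqs <= 400.0)
    con = _shape_conscious(freqs) * band
    unc = _shape_unconscious(freqs) * band
    # normalize each shape to unit power so w trades shape, not variance
    con /= max(con.sum(), 1e-300)
    unc /= max(unc.sum(), 1e-300)
    return w * con + (1.0 - w) * unc


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  density: np.ndarray, target_sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * np.sqrt(density)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd > 0:
        x *= target_sd / sd
    return x


def _mixing_weight(state: str, cfg: CohortConfig, patient_offset: float,
                   epoch_jitter: float, sensitivity: float = 1.0) -> float:
    sign = 1.0 if state == "conscious" else -1.0
    w = (0.5 + sign * sensitivity * cfg.eeg_effect / 2.0
         + patient_offset + epoch_jitter)
    return float(np.clip(w, 0.0, 1.0))


def _eeg_epoch(rng: np.random.Generator, cfg: CohortConfig, w: float) -> np.ndarray:
    n = cfg.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.sampling_rate)
    density = _mixture_density(freqs, w)
    # deeper anesthesia -> larger slow-wave amplitude
    target_sd = 10.0 + 5.0 * (1.0 - w)
    return _shaped_noise(rng, n, cfg.sampling_rate, density, target_sd)


def _aep_template(t_ms: np.ndarray, amp: float, lat_shift: float) -> np.ndarray:
    """Two mid-latency Gabor deflections: positive ~30 ms, negative ~45 ms."""
    pa = amp * 1.5 * _gauss(t_ms, 30.0 + lat_shift, 6.0) * np.cos(
        2 * np.pi * 0.035 * (t_ms - 30.0 - lat_shift))
    nb = -amp * 1.2 * _gauss(t_ms, 45.0 + lat_shift, 7.0) * np.cos(
        2 * np.pi * 0.030 * (t_ms - 45.0 - lat_shift))
    return pa + nb


def _aep_sweeps(rng: np.random.Generator, cfg: CohortConfig, state: str,
                w: float, amp_factor: float, lat_offset: float,
                sensitivity: float = 1.0) -> np.ndarray:
    lo, hi = cfg.aep_window_ms
    n = int(round((hi - lo) * cfg.sampling_rate / 1000.0))
    t_ms = lo + np.arange(n) * 1000.0 / cfg.sampling_rate
    if state == "unconscious":
        attenuation = min(sensitivity * cfg.aep_amplitude_effect, 1.0)
        amp = amp_factor * (1.0 - attenuation)
        lat = lat_offset + sensitivity * cfg.aep_latency_effect
    else:
        amp = amp_factor
        lat = lat_offset
    template = _aep_template(t_ms, amp, lat)
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.sampling_rate)
    density = _mixture_density(freqs, w)
    white = rng.standard_normal((cfg.sweeps_per_aep, n))
    noise = np.fft.irfft(np.fft.rfft(white, axis=1) * np.sqrt(density), n,
                         axis=1)
    sd = noise.std(axis=1, keepdims=True)
    noise *= np.where(sd > 0, 12.0 / np.maximum(sd, 1e-300), 0.0)
    return template + noise


def generate_cohort(
    config: CohortConfig,
) -> Tuple[List[EpochedSignal], List[AEPSweepSet]]:
    """Generate labeled EEG epochs and AEP sweep sets for a cohort.

    Returns exactly ``n_patients x events_per_patient x 2`` epochs and the
    matching sweep sets, balanced between states.  Fully reproducible for
    a fixed config: the root seed expands into one independent substream
    per patient, so any patient subset can be regenerated bit-identically.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients)
    events = event_sequence(config.events_per_patient)

    epochs: List[EpochedSignal] = []
    sweep_sets: List[AEPSweepSet] = []
    for p_idx, pseed in enumerate(patient_seeds):
        rng = np.random.default_rng(pseed)
        pid = f"P{p_idx + 1:03d}"
        w_offset = rng.normal(0.0, config.between_patient_sd)
        amp_factor = float(np.exp(rng.normal(0.0, config.between_patient_sd)))
        lat_offset = rng.normal(0.0, 1.5)
        sens_eeg = max(rng.normal(1.0, config.patient_sensitivity_sd), 0.0)
        sens_aep = max(rng.normal(1.0, config.patient_sensitivity_sd), 0.0)
        for event in events:
            for state in STATES:
                jitter = rng.normal(0.0, 0.06)
                w = _mixing_weight(state, config, w_offset, jitter, sens_eeg)
                eeg = _eeg_epoch(rng, config, w)
                epochs.append(EpochedSignal(
                    samples=eeg, sampling_rate=config.sampling_rate,
                    patient_id=pid, event_label=event, state=state))
                sweeps = _aep_sweeps(rng, config, state, w, amp_factor,
                                     lat_offset, sens_aep)
                sweep_sets.append(AEPSweepSet(
                    sweeps=sweeps, sampling_rate=config.sampling_rate,
                    window=config.aep_window_ms, patient_id=pid,
                    event_label=event, state=state))
    return epochs, sweep_sets


# ---------------------------------------------------------------------------
# Artifact injection (fixtures for the automatic artifact detector)
# ---------------------------------------------------------------------------

def _corrupt_flat(rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
    return np.full_like(x, float(np.median(x)))


def _corrupt_range(rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
    y = x.copy()
    width = 15
    start = int(rng.integers(0, max(len(y) - width, 1)))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    y[start:start + width] = sign * rng.uniform(260.0, 400.0)
    return y


def _corrupt_slope(rng: np.random.Generator, x: np.ndarray,
                   fs: float) -> np.ndarray:
    # triangular excursion: +-90 muV over 0.5 s ramps -> 180 muV within 1 s,
    # exceeding the 140 muV/s criterion but staying inside the +-250 range
    y = x.copy()
    half = int(round(0.5 * fs))
    seg = np.concatenate([np.linspace(0, 90.0, half),
                          np.linspace(90.0, -90.0, 2 * half),
                          np.linspace(-90.0, 0.0, half)])
    start = int(rng.integers(0, max(len(y) - len(seg), 1)))
    y[start:start + len(seg)] += seg[: len(y) - start]
    return y


_CORRUPTIONS = (("flat", _corrupt_flat),
                ("range", _corrupt_range),
                ("slope", _corrupt_slope))


def inject_artifacts(
    epochs: Sequence[EpochedSignal],
    config: CohortConfig,
) -> List[EpochedSignal]:
    """Corrupt a random ``artifact_rate`` fraction of epochs.

    Each corrupted epoch receives exactly one artifact class — flat line,
    amplitude excursion beyond +-250 muV, or a ramp exceeding 140 muV/s —
    and carries the ground-truth class in ``artifact_truth`` so detector
    sensitivity can be audited.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0xA2F,)))
    out: List[EpochedSignal] = []
    for ep in epochs:
        if rng.random() < config.artifact_rate:
            kind_idx = int(rng.integers(0, len(_CORRUPTIONS)))
            name, fn = _CORRUPTIONS[kind_idx]
            if name == "slope":
                samples = fn(rng, ep.samples, ep.sampling_rate)
            else:
                samples = fn(rng, ep.samples)
            out.append(replace(ep, samples=samples, artifact_truth=name))
        else:
            out.append(replace(ep, samples=ep.samples.copy()))
    return out
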