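"""Mid-latency AEP averaging, wavelet decomposition and parameter catalog.

The averaged auditory evoked potential is decomposed with an orthogonal
discrete wavelet transform (Daubechies-4, periodized, depth 5 at 1 kHz),
placing the mid-latency 20-45 ms oscillatory content in the D4/D5
detail levels while D3 captures the 62-125 Hz band.  Five parameter
families are derived per level:

* raw wavelet coefficients (a selected subset),
* amplitude and latency of the largest |coefficient|,
* level energy (sum of squared coefficients),
* maximum amplitude of the single-level reconstruction
  ("retransformed" AEP),
* variance of the second finite difference of the coefficient sequence.

The default catalog enumerates 80 named AEP parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt

from .cohort import AEPSweepSet
from .preprocess import highpass

__all__ = [
    "AveragedAEP",
    "WaveletDecomposition",
    "average_sweeps",
    "decompose",
    "retransform_level",
    "aep_parameters",
    "default_aep_catalog",
    "aep_feature_matrix",
]

DEFAULT_WAVELET = "db4"
DEFAULT_DEPTH = 5
DEFAULT_MODE = "periodization"

#: raw-coefficient subset of the default catalog: all coefficients of the
#: slow levels plus the leading D3 coefficients, 50 in total
_RAW_COEF_PLAN: Tuple[Tuple[str, int], ...] = (
    ("A5", 8), ("D5", 8), ("D4", 16), ("D3", 18),
)


@dataclass
class AveragedAEP:
    """An averaged evoked response over the post-stimulus window."""

    waveform: np.ndarray
    sampling_rate: float
    n_sweeps_used: int
    window: Tuple[float, float]       # ms

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.n_sweeps_used < 1:
            raise ValueError("n_sweeps_used must be >= 1")


@dataclass
class WaveletDecomposition:
    """DWT coefficients by level label (D1..Dk are details, Ak approximation)."""

    levels: Dict[str, np.ndarray]
    wavelet: str
    mode: str
    depth: int
    sampling_rate: float
    window: Tuple[float, float]

    def coefficient_times_ms(self, label: str) -> np.ndarray:
        """Center-of-support time (ms post-stimulus) of each coefficient."""
        k = self.depth if label.startswith("A") else int(label[1:])
        stride = 2 ** k
        n = len(self.levels[label])
        return self.window[0] + (np.arange(n) + 0.5) * stride * 1000.0 / self.sampling_rate


def average_sweeps(sweeps: AEPSweepSet,
                   highpass_hz: Optional[float] = 25.0) -> AveragedAEP:
    """Per-sweep high-pass (default 25 Hz) followed by the pointwise mean."""
    arr = sweeps.sweeps
    if arr.size == 0 or arr.shape[0] < 1:
        raise ValueError("empty sweep set")
    if arr.ndim != 2:
        raise ValueError("ragged sweep lengths; all sweeps must be equal length")
    if highpass_hz is not None:
        arr = highpass(arr, sweeps.sampling_rate, cutoff=highpass_hz)
    return AveragedAEP(waveform=arr.mean(axis=0),
                       sampling_rate=sweeps.sampling_rate,
                       n_sweeps_used=arr.shape[0], window=sweeps.window)


def decompose(aep: AveragedAEP, wavelet: str = DEFAULT_WAVELET,
              depth: int = DEFAULT_DEPTH,
              mode: str = DEFAULT_MODE) -> WaveletDecomposition:
    """Discrete wavelet transform of the averaged waveform.

    For orthogonal families with periodized boundaries the level energies
    sum to the waveform energy (Parseval).
    """
    x = aep.waveform
    wav = pywt.Wavelet(wavelet)
    max_depth = pywt.dwt_max_level(len(x), wav.dec_len)
    if depth > max_depth:
        raise ValueError(f"depth {depth} too large for waveform length "
                         f"{len(x)} (max {max_depth})")
    coeffs = pywt.wavedec(x, wav, mode=mode, level=depth)
    levels = {f"A{depth}": coeffs[0]}
    for i, d in enumerate(coeffs[1:]):
        levels[f"D{depth - i}"] = d
    return WaveletDecomposition(levels=levels, wavelet=wavelet, mode=mode,
                                depth=depth, sampling_rate=aep.sampling_rate,
                                window=aep.window)


def retransform_level(dec: WaveletDecomposition, label: str) -> np.ndarray:
    """Inverse transform keeping only one level's coefficients."""
    order = [f"A{dec.depth}"] + [f"D{k}" for k in range(dec.depth, 0, -1)]
    coeffs = [dec.levels[lab] if lab == label else np.zeros_like(dec.levels[lab])
              for lab in order]
    return pywt.waverec(coeffs, pywt.Wavelet(dec.wavelet), mode=dec.mode)


def _level_order(depth: int) -> List[str]:
    return [f"D{k}" for k in range(1, depth + 1)] + [f"A{depth}"]


def aep_parameters(dec: WaveletDecomposition,
                   aep: AveragedAEP) -> Dict[str, float]:
    """Extract the named AEP parameter set from one decomposition.

    Latencies are in ms post-stimulus, mapped to the center of the
    coefficient support; an all-zero level has no defined latency and
    reports NaN (missing), never 0.
    """
    out: Dict[str, float] = {}
    for label, k in _RAW_COEF_PLAN:
        c = dec.levels[label]
        if len(c) < k:
            raise ValueError(f"level {label} has {len(c)} coefficients, "
                             f"catalog needs {k}")
        for i in range(k):
            out[f"aep_coef_{label}_{i}"] = float(c[i])
    for label in _level_order(dec.depth):
        c = dec.levels[label]
        absc = np.abs(c)
        amax = float(absc.max()) if len(c) else 0.0
        out[f"aep_amp_{label}"] = amax
        if amax > 0:
            t = dec.coefficient_times_ms(label)
            out[f"aep_lat_{label}"] = float(t[int(np.argmax(absc))])
        else:
            out[f"aep_lat_{label}"] = float("nan")
        out[f"aep_energy_{label}"] = float(np.sum(c ** 2))
        recon = retransform_level(dec, label)
        out[f"aep_reconmax_{label}"] = float(np.max(np.abs(recon)))
        out[f"aep_d2var_{label}"] = (float(np.var(np.diff(c, 2)))
                                     if len(c) >= 3 else float("nan"))
    return out


def default_aep_catalog(depth: int = DEFAULT_DEPTH) -> List[str]:
    """The 80 named parameters of the default AEP catalog, in order."""
    names = [f"aep_coef_{label}_{i}" for label, k in _RAW_COEF_PLAN
             for i in range(k)]
    for label in _level_order(depth):
        names += [f"aep_amp_{label}", f"aep_lat_{label}",
                  f"aep_energy_{label}", f"aep_reconmax_{label}",
                  f"aep_d2var_{label}"]
    return names


def aep_feature_matrix(
    sweep_sets: Sequence[AEPSweepSet],
    highpass_hz: Optional[float] = 25.0,
    wavelet: str = DEFAULT_WAVELET,
    depth: int = DEFAULT_DEPTH,
) -> pd.DataFrame:
    """Average, decompose and parameterize every sweep set.

    Returns metadata columns (patient_id, event, state) followed by the
    80 catalog columns.
    """
    names = default_aep_catalog(depth)
    rows = []
    for ss in sweep_sets:
        avg = average_sweeps(ss, highpass_hz)
        dec = decompose(avg, wavelet=wavelet, depth=depth)
        row: Dict[str, object] = {"patient_id": ss.patient_id,
                                  "event": ss.event_label, "state": ss.state}
        row.update(aep_parameters(dec, avg))
        rows.append(row)
    cols = ["patient_id", "event", "state"] + names
    return pd.DataFrame(rows, columns=cols)
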