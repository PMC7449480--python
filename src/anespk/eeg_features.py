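"""The seven EEG signal measures and the default 23-column catalog.

Measures
--------
WSMF   weighted spectral median frequency (Hz)
qWSMF  quotient of two WSMF values on different bands
SEn    spectral entropy, normalized to [0, 1]
HEx    Hurst exponent from rescaled-range (R/S) scaling
ApEn   approximate entropy (Pincus, self-matches included)
LZc    Lempel-Ziv complexity (LZ76 word count, normalized)
PeEn   permutation entropy, normalized to [0, 1]

Each measure is exposed as a plain function over a 1-D sample array (or a
:class:`SpectralEstimate` for the spectral ones);
:func:`eeg_feature_matrix` maps a catalog of measure x filter-variant
specs over labeled epochs to produce the EEG columns of the feature
table.  The default catalog crosses the seven measures with the three
low-pass variants f_high = 30, 49, 90 Hz and adds two band-restricted
spectral columns, giving 23 named parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import EpochedSignal
from .preprocess import ArtifactCriteria, FilterSpec, apply_filter, detect_artifacts

__all__ = [
    "SpectralEstimate",
    "EEGFeatureSpec",
    "estimate_spectrum",
    "wsmf",
    "qwsmf",
    "spectral_entropy",
    "hurst_exponent",
    "approximate_entropy",
    "lz76_word_count",
    "lempel_ziv_complexity",
    "permutation_entropy",
    "default_eeg_catalog",
    "eeg_feature_matrix",
    "EEG_FEATURE_FHIGH",
]

log = logging.getLogger(__name__)


@dataclass
class SpectralEstimate:
    """Welch spectral density restricted to a band."""

    frequencies: np.ndarray
    power: np.ndarray
    band: Tuple[float, float]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def estimate_spectrum(x: np.ndarray, sampling_rate: float,
                      band: Tuple[float, float],
                      nperseg: int = 2048) -> SpectralEstimate:
    """Welch-averaged periodogram restricted to ``band``.

    The density integrates (sum x df) to the band-limited signal
    variance, up to windowing leakage.
    """
    lo, hi = band
    if hi > sampling_rate / 2.0 or lo < 0:
        raise ValueError("band outside the Nyquist range")
    x = np.asarray(x, dtype=float)
    nper = min(nperseg, len(x))
    freqs, psd = sps.welch(x, fs=sampling_rate, nperseg=nper)
    sel = (freqs >= lo) & (freqs <= hi)
    return SpectralEstimate(freqs[sel], psd[sel], band)


def wsmf(spectrum: SpectralEstimate,
         weighting: Optional[np.ndarray] = None) -> float:
    """Weighted spectral median frequency.

    Smallest frequency at which the cumulative (weighted) power reaches
    half of the total, with linear interpolation inside the crossing bin.
    Default weighting is uniform, i.e. the plain spectral median.
    """
    p = spectrum.power.copy()
    if weighting is not None:
        w = np.asarray(weighting, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weighting must match the number of bins")
        p = p * w
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total weighted power (degenerate epoch)")
    cum = np.cumsum(p)
    half = total / 2.0
    i = min(int(np.searchsorted(cum, half)), len(cum) - 1)
    f = spectrum.frequencies
    if i == 0:
        prev = 0.0
        f_lo = spectrum.band[0]
    else:
        prev = cum[i - 1]
        f_lo = f[i - 1]
    frac = (half - prev) / max(cum[i] - prev, 1e-300)
    return float(f_lo + frac * (f[i] - f_lo))


def qwsmf(x: np.ndarray, sampling_rate: float,
          band_a: Tuple[float, float], band_b: Tuple[float, float],
          weighting: Optional[np.ndarray] = None,
          nperseg: int = 2048) -> float:
    """Quotient of two WSMF values computed on different bands."""
    sa = estimate_spectrum(x, sampling_rate, band_a, nperseg)
    sb = estimate_spectrum(x, sampling_rate, band_b, nperseg)
    return wsmf(sa, weighting) / wsmf(sb, weighting)


def spectral_entropy(spectrum: SpectralEstimate) -> float:
    """Shannon entropy of the normalized band power, scaled to [0, 1]."""
    p = spectrum.power
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total power")
    if len(p) < 2:
        return 0.0
    q = p / total
    nz = q[q > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / np.log(len(p)))


def hurst_exponent(x: np.ndarray, min_window: int = 16,
                   min_length: int = 128) -> float:
    """Hurst exponent from rescaled-range (R/S) scaling.

    Fits the slope of log(R/S) against log(window size) over a dyadic
    ladder of window sizes from ``min_window`` up to length/4.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < min_length:
        raise ValueError(f"need at least {min_length} samples")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has no R/S scaling")
    sizes = []
    s = min_window
    while s <= n // 4:
        sizes.append(s)
        s *= 2
    log_rs = []
    for size in sizes:
        k = n // size
        seg = x[: k * size].reshape(k, size)
        dev = seg - seg.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        sd = seg.std(axis=1)
        ok = sd > 0
        if not np.any(ok):
            continue
        log_rs.append(np.log(np.mean(r[ok] / sd[ok])))
    if len(log_rs) < 2:
        raise ValueError("not enough valid window sizes")
    slope = np.polyfit(np.log(sizes[: len(log_rs)]), log_rs, 1)[0]
    return float(slope)


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r: Optional[float] = None) -> float:
    """Pincus approximate entropy ApEn(m, r).

    Chebyshev distance, self-matches included.  ``r`` defaults to
    0.2 x SD of the input.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError("sequence too short for the embedding dimension")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    # within-tolerance matrix at embedding 1; higher embeddings are
    # logical ANDs of shifted diagonals, so the O(n^2) outer difference
    # is computed once
    close = np.abs(x[:, None] - x[None, :]) <= r

    def phi(match: np.ndarray) -> float:
        n_vec = match.shape[0]
        counts = np.count_nonzero(match, axis=1)
        return float(np.mean(np.log(counts / n_vec)))

    match_m = close[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        match_m &= close[k: n - m + 1 + k, k: n - m + 1 + k]
    match_m1 = match_m[:-1, :-1] & close[m: n, m: n]
    return phi(match_m) - phi(match_m1)


def lz76_word_count(bits: Sequence[int]) -> int:
    """Number of words in the exhaustive LZ76 parse of a binary sequence."""
    s = bytes(int(b) for b in bits)
    n = len(s)
    if n == 0:
        return 0
    c = 1
    i = 1          # start of the current word
    k = 1          # current word length
    while i + k <= n:
        # is s[i:i+k] a substring of s[0:i+k-1] ?
        if s.find(s[i:i + k], 0, i + k - 1) != -1:
            k += 1
        else:
            c += 1
            i += k
            k = 1
    if k > 1:
        c += 1
    return c


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalized LZ76 complexity of the median-binarized signal.

    Returns c(n) * log2(n) / n, which tends to 1 for i.i.d. binary noise.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    bits = (x > np.median(x)).astype(np.uint8)
    c = lz76_word_count(bits)
    return float(c * np.log2(n) / n)


def permutation_entropy(x: np.ndarray, order: int = 3, lag: int = 1) -> float:
    """Normalized permutation entropy of ordinal patterns.

    Shannon entropy of the distribution of order-``order`` ordinal
    patterns at the given lag, scaled by log(order!) to [0, 1].  Equal
    values are broken by position (stable argsort), the common
    convention for noisy real-valued signals.
    """
    x = np.asarray(x, dtype=float)
    if order < 2:
        raise ValueError("order must be >= 2")
    n_pat = len(x) - (order - 1) * lag
    if n_pat < 1:
        raise ValueError("sequence too short for the given order and lag")
    idx = np.arange(n_pat)[:, None] + lag * np.arange(order)[None, :]
    windows = x[idx]
    ranks = np.argsort(windows, axis=1, kind="stable")
    codes = (ranks * (order ** np.arange(order))[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(math.factorial(order)))


# ---------------------------------------------------------------------------
# Catalog machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGFeatureSpec:
    """One named EEG parameter: a measure under a filter variant."""

    name: str
    measure: str                       # WSMF | qWSMF | SEn | HEx | ApEn | LZc | PeEn
    filter: FilterSpec = FilterSpec()
    band: Optional[Tuple[float, float]] = None   # spectral band override
    params: Tuple[Tuple[str, float], ...] = ()

    @property
    def param_dict(self) -> Dict[str, float]:
        return dict(self.params)


_FHIGH_VARIANTS = (30.0, 49.0, 90.0)
_MEASURES = ("WSMF", "qWSMF", "SEn", "HEx", "ApEn", "LZc", "PeEn")

# ApEn is computed on the epoch decimated to ~250 Hz: at monitoring epoch
# lengths the O(n^2) template matching is otherwise prohibitive, and the
# regularity contrast between states survives decimation.
_APEN_TARGET_FS = 250.0


def default_eeg_catalog(
    f_highs: Sequence[float] = _FHIGH_VARIANTS,
) -> List[EEGFeatureSpec]:
    """The default 23-parameter EEG catalog.

    Seven measures x the f_high filter variants (21 columns for the
    default three variants), plus two band-restricted spectral columns
    (WSMF and SEn over 8-30 Hz under the widest filter).
    """
    specs: List[EEGFeatureSpec] = []
    for fh in f_highs:
        filt = FilterSpec(low_cut=0.5, high_cut=fh)
        tag = f"f{int(fh)}"
        for meas in _MEASURES:
            specs.append(EEGFeatureSpec(name=f"{meas}_{tag}", measure=meas,
                                        filter=filt))
    widest = FilterSpec(low_cut=0.5, high_cut=max(f_highs))
    wtag = f"f{int(max(f_highs))}"
    specs.append(EEGFeatureSpec(name="WSMF_band8_30", measure="WSMF",
                                filter=widest, band=(8.0, 30.0)))
    specs.append(EEGFeatureSpec(name="SEn_band8_30", measure="SEn",
                                filter=widest, band=(8.0, 30.0)))
    return specs


#: map feature name -> f_high variant it belongs to (for filter sweeps)
EEG_FEATURE_FHIGH: Dict[str, float] = {
    s.name: (s.filter.high_cut if s.band is None else max(_FHIGH_VARIANTS))
    for s in default_eeg_catalog()
}


def _compute_measure(spec: EEGFeatureSpec, filtered: np.ndarray,
                     fs: float) -> float:
    band = spec.band or (spec.filter.low_cut, spec.filter.high_cut)
    p = spec.param_dict
    if spec.measure == "WSMF":
        return wsmf(estimate_spectrum(filtered, fs, band))
    if spec.measure == "qWSMF":
        num = spec.band or (8.0, 30.0)
        den = (spec.filter.low_cut, spec.filter.high_cut)
        return qwsmf(filtered, fs, num, den)
    if spec.measure == "SEn":
        return spectral_entropy(estimate_spectrum(filtered, fs, band))
    if spec.measure == "HEx":
        return hurst_exponent(filtered)
    if spec.measure == "ApEn":
        dec = max(1, int(round(fs / _APEN_TARGET_FS)))
        return approximate_entropy(filtered[::dec],
                                   m=int(p.get("m", 2)),
                                   r=p.get("r"))
    if spec.measure == "LZc":
        return lempel_ziv_complexity(filtered)
    if spec.measure == "PeEn":
        return permutation_entropy(filtered, order=int(p.get("order", 3)),
                                   lag=int(p.get("lag", 1)))
    raise ValueError(f"unknown measure {spec.measure!r}")


META_COLUMNS = ["patient_id", "event", "state"]


def eeg_feature_matrix(
    epochs: Sequence[EpochedSignal],
    specs: Optional[Sequence[EEGFeatureSpec]] = None,
    criteria: ArtifactCriteria = ArtifactCriteria(),
    reject_artifacts: bool = True,
) -> pd.DataFrame:
    """Compute the EEG feature columns for a list of labeled epochs.

    Returns a DataFrame with the metadata columns (patient_id, event,
    state) followed by one column per spec.  Epochs flagged by the
    artifact detector are dropped (the whole data-point row), as are
    rows where any measure fails; both removals are logged.
    """
    if specs is None:
        specs = default_eeg_catalog()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in the spec list")
    if len(epochs) == 0:
        return pd.DataFrame(columns=META_COLUMNS + names)

    rows = []
    for ep in epochs:
        if reject_artifacts:
            report = detect_artifacts(ep, criteria)
            if report.flagged:
                log.info("epoch %s/%s/%s rejected: %s", ep.patient_id,
                         ep.event_label, ep.state, sorted(report.reasons))
                continue
        filtered_cache: Dict[FilterSpec, np.ndarray] = {}
        row: Dict[str, object] = {"patient_id": ep.patient_id,
                                  "event": ep.event_label, "state": ep.state}
        ok = True
        for spec in specs:
            if spec.filter not in filtered_cache:
                filtered_cache[spec.filter] = apply_filter(ep, spec.filter).samples
            try:
                row[spec.name] = _compute_measure(
                    spec, filtered_cache[spec.filter], ep.sampling_rate)
            except (ValueError, FloatingPointError) as exc:
                log.warning("epoch %s/%s/%s: measure %s failed (%s); row "
                            "dropped", ep.patient_id, ep.event_label,
                            ep.state, spec.name, exc)
                ok = False
                break
        if ok:
            rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + names)
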