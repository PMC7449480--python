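"""Epoch extraction, filtering variants and automatic artifact rejection.

Artifact rules follow standard EEG monitoring practice: flat-line
segments, excursions beyond the +-250 muV measuring range, and rapid
amplitude changes exceeding 140 muV/s.  The rate criterion is applied as
a peak-to-peak excursion within any sliding 1 s window, which is robust
to sampling jitter and matches the stated units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Set

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .cohort import EpochedSignal

__all__ = [
    "FilterSpec",
    "ArtifactCriteria",
    "ArtifactReport",
    "Recording",
    "detect_artifacts",
    "apply_filter",
    "highpass",
    "cut_transition_epochs",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase band-pass specification.

    ``high_cut`` is the f_high low-pass variant (30, 49 or 90 Hz for the
    EEG feature catalog; 400 Hz for the acquisition band).
    """

    low_cut: float = 0.5
    high_cut: float = 49.0
    order: int = 4

    def validate(self, sampling_rate: float) -> None:
        if not 0.0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut > sampling_rate / 2.0:
            raise ValueError(
                f"high_cut {self.high_cut} Hz exceeds Nyquist "
                f"({sampling_rate / 2.0} Hz)")


@dataclass(frozen=True)
class ArtifactCriteria:
    """Thresholds of the automatic artifact detector."""

    max_abs_uv: float = 250.0        # measuring range, peak
    slope_uv_per_s: float = 140.0    # max peak-to-peak change per window
    slope_window_s: float = 1.0
    flat_run_s: float = 0.1          # shortest flagged run of identical values


@dataclass
class ArtifactReport:
    flagged: bool
    reasons: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.flagged = bool(self.reasons)


def _longest_constant_run(x: np.ndarray) -> int:
    if len(x) == 0:
        return 0
    change = np.flatnonzero(np.diff(x) != 0)
    edges = np.concatenate([[-1], change, [len(x) - 1]])
    return int(np.max(np.diff(edges)))


def detect_artifacts(
    epoch: EpochedSignal,
    criteria: ArtifactCriteria = ArtifactCriteria(),
) -> ArtifactReport:
    """Apply the three automatic rejection rules to one epoch.

    Reasons reported: ``constant_amplitude`` (a run of identical samples
    of at least ``flat_run_s``), ``range_exceeded`` (any |sample| above
    ``max_abs_uv``), ``slope_exceeded`` (peak-to-peak change within any
    sliding ``slope_window_s`` window above
    ``slope_uv_per_s * slope_window_s``).
    """
    x = np.asarray(epoch.samples, dtype=float)
    if len(x) < 2:
        raise ValueError("epoch must have at least 2 samples")
    fs = epoch.sampling_rate
    if not fs or fs <= 0:
        raise ValueError("epoch sampling rate missing or invalid")

    reasons: Set[str] = set()
    run = max(int(round(criteria.flat_run_s * fs)), 2)
    if _longest_constant_run(x) >= run:
        reasons.add("constant_amplitude")
    if np.any(np.abs(x) > criteria.max_abs_uv):
        reasons.add("range_exceeded")
    win = max(int(round(criteria.slope_window_s * fs)), 2)
    win = min(win, len(x))
    ptp = maximum_filter1d(x, win) - minimum_filter1d(x, win)
    # interior windows only: the filter pads at the edges
    h = win // 2
    core = ptp[h: len(x) - (win - 1 - h)] if len(x) > win else ptp[h:h + 1]
    limit = criteria.slope_uv_per_s * criteria.slope_window_s
    if core.size and np.max(core) > limit:
        reasons.add("slope_exceeded")
    return ArtifactReport(flagged=bool(reasons), reasons=reasons)


def apply_filter(epoch: EpochedSignal, spec: FilterSpec) -> EpochedSignal:
    """Zero-phase Butterworth band-pass; output length equals input."""
    spec.validate(epoch.sampling_rate)
    sos = sps.butter(spec.order, [spec.low_cut, spec.high_cut],
                     btype="bandpass", fs=epoch.sampling_rate, output="sos")
    x = np.asarray(epoch.samples, dtype=float)
    # the low cut sets the transient scale; default padding is too short
    padlen = int(min(len(x) - 1, 3 * epoch.sampling_rate / spec.low_cut))
    y = sps.sosfiltfilt(sos, x, padlen=padlen)
    return replace(epoch, samples=y)


def highpass(x: np.ndarray, sampling_rate: float, cutoff: float = 25.0,
             order: int = 2) -> np.ndarray:
    """Zero-phase high-pass used before AEP averaging."""
    if cutoff >= sampling_rate / 2.0:
        raise ValueError("cutoff above Nyquist")
    sos = sps.butter(order, cutoff, btype="highpass", fs=sampling_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class Recording:
    """A continuous single-channel recording for one patient."""

    samples: np.ndarray
    sampling_rate: float
    patient_id: str
    channel_label: str = "AT1-Fpz"


def cut_transition_epochs(
    recording: Recording,
    annotations: pd.DataFrame,
    epoch_duration: float = 10.0,
) -> List[EpochedSignal]:
    """Cut one conscious and one unconscious epoch around each transition.

    ``annotations`` must hold one row per event with columns
    ``event``, ``last_response_time_s``, ``first_no_response_time_s``
    (times of the last successful and the first failed hand-squeeze
    request; for ROC events the failed request precedes the successful
    one).  For a LOC event the conscious epoch *ends* at the last
    response and the unconscious epoch *starts* at the first failure;
    for a ROC event the unconscious epoch ends at the last failure and
    the conscious epoch starts at the first response.  The uncertain
    interval between the two requests is never sampled.

    An event with only one side annotated yields a single epoch and a
    warning; out-of-order annotations raise an error naming the event.
    """
    fs = recording.sampling_rate
    n_epoch = int(round(epoch_duration * fs))
    x = np.asarray(recording.samples, dtype=float)
    out: List[EpochedSignal] = []

    def cut(t_end_or_start: float, side: str) -> Optional[np.ndarray]:
        if side == "before":
            stop = int(round(t_end_or_start * fs))
            start = stop - n_epoch
        else:
            start = int(round(t_end_or_start * fs))
            stop = start + n_epoch
        if start < 0 or stop > len(x):
            return None
        return x[start:stop]

    for _, row in annotations.iterrows():
        event = str(row["event"])
        t_resp = row.get("last_response_time_s", np.nan)
        t_fail = row.get("first_no_response_time_s", np.nan)
        is_loc = event.upper().startswith("LOC")
        have_resp = np.isfinite(t_resp)
        have_fail = np.isfinite(t_fail)
        if have_resp and have_fail:
            # gray zone must be a forward interval
            if is_loc and t_fail < t_resp:
                raise ValueError(
                    f"event {event}: first failed request precedes the "
                    "last successful one")
            if not is_loc and t_resp < t_fail:
                raise ValueError(
                    f"event {event}: first successful request precedes "
                    "the last failed one")
        if not (have_resp and have_fail):
            warnings.warn(f"event {event}: only one transition side "
                          "annotated; emitting a single epoch")

        pieces = []
        if have_resp:
            side = "before" if is_loc else "after"
            pieces.append(("conscious", cut(float(t_resp), side)))
        if have_fail:
            side = "after" if is_loc else "before"
            pieces.append(("unconscious", cut(float(t_fail), side)))
        for state, seg in pieces:
            if seg is None:
                warnings.warn(f"event {event}: {state} epoch falls outside "
                              "the recording; skipped")
                continue
            out.append(EpochedSignal(
                samples=seg.copy(), sampling_rate=fs,
                patient_id=recording.patient_id, event_label=event,
                state=state, channel_label=recording.channel_label))
    return out
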