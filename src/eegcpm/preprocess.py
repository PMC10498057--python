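"""Automatable resting-state EEG preprocessing.

Covers the rule-based steps of a standard pipeline: average re-referencing,
50 Hz notch plus 0.1-30 Hz band-pass filtering (zero-phase), and
amplitude-based exclusion screening. Visual bad-channel interpolation and
ICA artifact removal are manual/toolbox procedures and intentionally not
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import Recording

__all__ = ["rereference_average", "apply_filters", "flag_exclusions", "ExclusionReport", "preprocess_recording"]


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract the per-sample channel mean.

    Idempotent and linear; after the call the across-channel mean is zero at
    every time point (to numerical tolerance).
    """
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    return rec.with_samples(rec.samples - rec.samples.mean(axis=0, keepdims=True))


def apply_filters(
    rec: Recording,
    band_lo: float = 0.1,
    band_hi: float = 30.0,
    notch: float = 50.0,
    notch_q: float = 30.0,
    order: int = 4,
) -> Recording:
    """Notch out line noise, then band-pass; both zero-phase (forward-backward).

    Defaults: 50 Hz notch (second-order IIR, Q=30) followed by a 0.1-30 Hz
    Butterworth band-pass of order 4. Output length equals input length.
    """
    nyq = rec.rate / 2
    if not (0 < band_lo < band_hi < nyq):
        raise ValueError(f"need 0 < band_lo < band_hi < Nyquist={nyq} Hz")
    if not (0 < notch < nyq):
        raise ValueError(f"notch frequency must lie below Nyquist={nyq} Hz")
    b, a = signal.iirnotch(notch, notch_q, fs=rec.rate)
    x = signal.filtfilt(b, a, rec.samples, axis=-1)
    sos = signal.butter(order, [band_lo, band_hi], btype="bandpass", fs=rec.rate, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    return rec.with_samples(x)


@dataclass
class ExclusionReport:
    """Amplitude-screening outcome for one subject.

    ``channel_fractions`` holds, per channel, the fraction of samples whose
    absolute amplitude exceeds the threshold; a channel is flagged when that
    fraction strictly exceeds ``time_frac``. The subject-level rule applies
    the same criterion to the across-channel maximum-amplitude trace.
    """

    subject_id: str
    amp_thresh: float
    time_frac: float
    channel_fractions: np.ndarray
    flagged_channels: list[str]
    subject_fraction: float
    subject_excluded: bool

    def to_frame(self, channel_labels: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "channel": channel_labels,
                "frac_above": self.channel_fractions,
                "flagged": [lab in self.flagged_channels for lab in channel_labels],
            }
        )


def flag_exclusions(
    rec: Recording, amp_thresh: float = 100.0, time_frac: float = 0.5
) -> ExclusionReport:
    """Screen a recording against the amplitude/time exclusion rule.

    The boundary is strict ("more than half of the total time"): a fraction
    of exactly ``time_frac`` is retained. The decision is invariant to sign
    flips of the data since only ``|amplitude|`` is compared.
    """
    if amp_thresh <= 0:
        raise ValueError("amp_thresh must be positive")
    if not 0 < time_frac <= 1:
        raise ValueError("time_frac must be in (0, 1]")
    above = np.abs(rec.samples) > amp_thresh
    channel_fractions = above.mean(axis=1)
    flagged = [
        lab for lab, frac in zip(rec.channel_labels, channel_fractions) if frac > time_frac
    ]
    subject_fraction = float((np.abs(rec.samples).max(axis=0) > amp_thresh).mean())
    return ExclusionReport(
        subject_id=rec.subject_id,
        amp_thresh=amp_thresh,
        time_frac=time_frac,
        channel_fractions=channel_fractions,
        flagged_channels=flagged,
        subject_fraction=subject_fraction,
        subject_excluded=subject_fraction > time_frac,
    )


def preprocess_recording(
    rec: Recording,
    band_lo: float = 0.1,
    band_hi: float = 30.0,
    notch: float = 50.0,
) -> Recording:
    """Average reference followed by notch + band-pass filtering."""
    return apply_filters(rereference_average(rec), band_lo=band_lo, band_hi=band_hi, notch=notch)
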