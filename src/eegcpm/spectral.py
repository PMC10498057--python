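"""Power spectra, the alpha-band arousal index, and the median split.

Resting alpha power (8-13 Hz) is the classic spectral index of cortical
arousal: lower alpha means stronger arousal. The index here is the power
spectral density averaged over the alpha bins and over all channels,
expressed in dB (10*log10 of absolute power in uV^2/Hz — the dB reference
is absolute power and configurable in the sense that any reference shifts
all subjects equally and leaves the median split unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import Recording

__all__ = ["PowerSpectrum", "welch_psd", "band_power", "alpha_power_db", "median_split"]


@dataclass
class PowerSpectrum:
    """Per-channel PSD on a regular frequency grid (uV^2/Hz)."""

    subject_id: str
    freqs: np.ndarray  # Hz, strictly increasing, constant step
    power: np.ndarray  # channels x freqs
    channel_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.power.T, columns=self.channel_labels)
        frame.insert(0, "freq", self.freqs)
        return frame


def welch_psd(
    rec: Recording,
    window: float = 2.0,
    f_lo: float = 1.0,
    f_hi: float = 30.0,
) -> PowerSpectrum:
    """Welch PSD from Hann-tapered, non-overlapping windows.

    A 2-s window yields a 0.5 Hz grid; the returned grid is restricted to
    ``[f_lo, f_hi]`` (default 1-30 Hz, 59 bins). Density scaling preserves
    Parseval: the integral of the PSD over frequency matches the windowed
    signal variance.
    """
    nperseg = window * rec.rate
    if abs(nperseg - round(nperseg)) > 1e-9:
        raise ValueError("window x rate must be an integer number of samples")
    nperseg = int(round(nperseg))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording ({rec.duration:g} s) shorter than one window ({window:g} s)"
        )
    freqs, power = signal.welch(
        rec.samples,
        fs=rec.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=0,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    keep = (freqs >= f_lo - 1e-9) & (freqs <= f_hi + 1e-9)
    return PowerSpectrum(
        subject_id=rec.subject_id,
        freqs=freqs[keep],
        power=power[:, keep],
        channel_labels=list(rec.channel_labels),
    )


def band_power(psd: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Mean PSD over the band's bins, per channel (uV^2/Hz)."""
    lo, hi = band
    keep = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
    if not keep.any():
        raise ValueError(f"band {band} contains no frequency bins of the grid")
    return psd.power[:, keep].mean(axis=1)


def alpha_power_db(psd: PowerSpectrum, band: tuple[float, float] = (8.0, 13.0)) -> float:
    """Alpha arousal index: band-mean power, channel-averaged, in dB.

    Averaging happens in linear power (band bins, then channels) before the
    log. Invariant under channel permutation; adding a silent channel
    strictly lowers the index.
    """
    mean_power = float(band_power(psd, band).mean())
    if mean_power <= 0:
        raise ValueError("non-positive band power; cannot take dB")
    return 10.0 * np.log10(mean_power)


def median_split(values: np.ndarray | list[float], labels: list[str]) -> pd.DataFrame:
    """Split subjects at the median arousal index.

    Values strictly below the median are the *high*-arousal group (low alpha
    = high arousal); values at or above the median are the *low*-arousal
    group. With distinct values and even n this is an equal split; the
    median element of an odd-n sample falls in the low-arousal group.
    Returns a table with columns subject_id, alpha_db, group.
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(labels):
        raise ValueError("values and labels must align")
    if values.size < 2:
        raise ValueError("median split requires at least 2 subjects")
    if np.ptp(values) == 0:
        raise ValueError("all values identical: median split undefined")
    med = float(np.median(values))
    group = np.where(values < med, "high", "low")
    return pd.DataFrame({"subject_id": labels, "alpha_db": values, "group": group})
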