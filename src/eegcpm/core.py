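"""Shared domain containers: recordings and frequency-band definitions.

All sample data are held as ``channels x time`` float arrays in microvolts.
Band edges follow the conventional EEG partition used throughout the
package: delta 1-4 Hz, theta 4-7 Hz, alpha 8-13 Hz, beta 13-30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo, hi]`` in Hz with ``0 < lo < hi``."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: need 0 < lo < hi, got ({self.lo}, {self.hi})")

    def validate_for_rate(self, rate: float) -> None:
        if self.hi > rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.hi} Hz exceeds Nyquist ({rate / 2} Hz)"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass
class Recording:
    """One subject's multichannel EEG.

    Parameters
    ----------
    subject_id : str
        Subject label.
    channel_labels : list of str
        One label per row of ``samples``.
    rate : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts. Missing values are rejected at construction.
    """

    subject_id: str
    channel_labels: list[str] = field(repr=False)
    rate: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"recording {self.subject_id} contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with ``samples`` replaced."""
        return replace(self, samples=samples)
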