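"""Seeded synthetic resting-state EEG cohorts with known ground truth.

The generator produces multichannel recordings whose statistical structure
matches what the downstream analysis assumes, so that every stage — spectral
arousal indexing, WPLI connectome estimation, group statistics and
connectome-based prediction — can be exercised and validated without any
real data.

Each channel is the sum of

* pink (1/f) background noise, and
* one narrow-band oscillation per configured band, synthesised as
  band-pass-filtered white noise so that instantaneous phase is
  non-degenerate across epochs (a pure sinusoid would make the WPLI
  denominator vanish within epochs).

Phase coupling is injected on designated channel pairs: for an edge
``(i, j, band, lag, strength)`` the band component of channel ``j`` is a
mixture ``kappa * shift(x_i, lag) + (1 - kappa) * own_j`` where ``shift``
rotates the analytic signal by a constant phase ``lag``. ``kappa = 0`` is no
coupling; ``kappa = 1`` reproduces channel ``i``'s phase exactly, the
analytic maximum of the WPLI estimator. A lag of 0 or pi makes the
imaginary cross-spectrum vanish and WPLI undefined by construction; the
generator warns in that case.

Behavior scores follow a linear model on the subject-wise sum of realized
edge strengths, with Gaussian noise, affinely mapped onto the 1-7 Likert
scale used for attractiveness ratings.

All draws are controlled by ``(seed, subject_index)`` so cohorts are
bit-reproducible, and the random stream layout does not depend on parameter
values — sweeping a coupling strength at fixed seed varies only the mixing
proportion, giving common-random-number coupled simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import DEFAULT_BANDS, BandDefinition, Recording

__all__ = [
    "CouplingEdge",
    "SyntheticSpec",
    "gen_recording",
    "gen_cohort",
    "realized_edge_strengths",
    "select_percentile_band",
]

# stream tags for per-subject random substreams
_STREAM_BACKGROUND = 0
_STREAM_OSCILLATION = 1
_STREAM_ALPHA_FACTOR = 2
_STREAM_STRENGTH = 3
_STREAM_BEHAVIOR = 4
_STREAM_AGE = 5


@dataclass(frozen=True)
class CouplingEdge:
    """Constant-phase-lag coupling from channel ``i`` to channel ``j``.

    ``strength`` (kappa) in [0, 1] is the amplitude mixing proportion of the
    lag-shifted copy of channel ``i``'s band component in channel ``j``.
    """

    i: int
    j: int
    band: str = "alpha"
    lag: float = np.pi / 2
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("coupling edge requires two distinct channels")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"coupling strength must be in [0, 1], got {self.strength}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the acquisition and cohort of the emulated study: 75
    subjects (48 men, 27 women), 64 channels at 500 Hz for 200 s, the four
    conventional bands, and ratings on a 1-7 scale.
    """

    n_subjects: int = 75
    n_channels: int = 64
    rate: float = 500.0
    duration: float = 200.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    coupling_edges: tuple[CouplingEdge, ...] = ()
    coupling_spread: float = 0.0  # half-width of per-subject strength jitter
    alpha_power_spread: float = 3.0  # between-subject SD of alpha amplitude, dB
    behavior_effect: float = 0.0  # rating units per unit summed edge strength
    behavior_noise: float = 0.8  # rating units
    sex_counts: tuple[int, int] | None = None  # (n_male, n_female); None = 48:27 proportion
    age_range: tuple[int, int] = (18, 30)
    background_rms: float = 10.0  # microvolts
    arousal_band: str = "alpha"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ValueError("need at least one subject and one channel")
        if self.sex_counts is None:
            # cohort sex ratio of the emulated study (48 men : 27 women)
            n_male = int(round(self.n_subjects * 48 / 75))
            object.__setattr__(self, "sex_counts", (n_male, self.n_subjects - n_male))
        if sum(self.sex_counts) != self.n_subjects:
            raise ValueError(
                f"sex_counts {self.sex_counts} do not sum to n_subjects={self.n_subjects}"
            )
        n = self.duration * self.rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x rate must be an integer number of samples")
        if not 0.0 <= self.coupling_spread <= 1.0:
            raise ValueError("coupling_spread must be in [0, 1]")
        band_names = {b.name for b in self.bands}
        for b in self.bands:
            b.validate_for_rate(self.rate)
        for e in self.coupling_edges:
            if not (0 <= e.i < self.n_channels and 0 <= e.j < self.n_channels):
                raise ValueError(f"coupling edge ({e.i}, {e.j}) outside channel range")
            if e.band not in band_names:
                raise ValueError(f"coupling edge band {e.band!r} not among configured bands")
        if self.behavior_effect != 0.0 and not self.coupling_edges:
            raise ValueError("behavior_effect without coupling_edges: the effect has no carrier")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    @property
    def channel_labels(self) -> list[str]:
        return [f"CH{i:02d}" for i in range(self.n_channels)]


def _rng(spec: SyntheticSpec, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, subject_index, stream])


def _pink_noise(rng: np.random.Generator, n: int, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n)
    return x / x.std()


def _band_sos(band: BandDefinition, rate: float, order: int = 4) -> np.ndarray:
    return signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=rate, output="sos")


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Rotate the analytic signal of ``x`` by a constant phase ``lag``."""
    return np.real(signal.hilbert(x) * np.exp(-1j * lag))


def realized_edge_strengths(spec: SyntheticSpec, subject_index: int) -> np.ndarray:
    """Per-subject coupling strengths actually used for ``subject_index``.

    Each edge's nominal strength is jittered by a uniform draw of half-width
    ``coupling_spread`` and clipped to [0, 1]; with the default spread of 0
    the nominal strengths are used exactly. Deterministic given
    ``(seed, subject_index)``.
    """
    rng = _rng(spec, subject_index, _STREAM_STRENGTH)
    u = rng.uniform(-1.0, 1.0, size=len(spec.coupling_edges))
    kappa = np.array([e.strength for e in spec.coupling_edges], dtype=float)
    return np.clip(kappa + spec.coupling_spread * u, 0.0, 1.0)


def gen_recording(spec: SyntheticSpec, subject_index: int) -> Recording:
    """Synthesise one subject's recording. Deterministic given (seed, index)."""
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside cohort of {spec.n_subjects}")
    n = spec.n_samples
    rng_bg = _rng(spec, subject_index, _STREAM_BACKGROUND)
    rng_osc = _rng(spec, subject_index, _STREAM_OSCILLATION)
    rng_alpha = _rng(spec, subject_index, _STREAM_ALPHA_FACTOR)

    alpha_factor = 10.0 ** (rng_alpha.normal(0.0, spec.alpha_power_spread) / 20.0)
    strengths = realized_edge_strengths(spec, subject_index)

    background = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        background[c] = _pink_noise(rng_bg, n) * spec.background_rms

    # Per band: oscillation = filtered white noise scaled to the background's
    # in-band RMS (1:1 in-band SNR), alpha additionally scaled per subject.
    osc: dict[str, np.ndarray] = {}
    for band in spec.bands:
        sos = _band_sos(band, spec.rate)
        bg_band = signal.sosfiltfilt(sos, background, axis=-1)
        target_rms = np.sqrt(np.mean(bg_band**2, axis=-1))
        comp = signal.sosfiltfilt(sos, rng_osc.standard_normal((spec.n_channels, n)), axis=-1)
        comp *= (target_rms / np.sqrt(np.mean(comp**2, axis=-1)))[:, None]
        if band.name == spec.arousal_band:
            comp *= alpha_factor
        osc[band.name] = comp

    for edge, kappa in zip(spec.coupling_edges, strengths):
        if kappa > 0 and (abs(edge.lag) < 1e-9 or abs(abs(edge.lag) - np.pi) < 1e-9):
            warnings.warn(
                f"coupling edge ({edge.i}, {edge.j}) has lag {edge.lag:g}: the imaginary "
                "cross-spectrum vanishes and WPLI is undefined by construction",
                stacklevel=2,
            )
        comp = osc[edge.band]
        own = comp[edge.j]
        shifted = _phase_shift(comp[edge.i], edge.lag)
        mixed = kappa * shifted + (1.0 - kappa) * own
        rms = np.sqrt(np.mean(mixed**2))
        if rms > 0:
            mixed *= np.sqrt(np.mean(own**2)) / rms
        comp[edge.j] = mixed

    samples = background + sum(osc.values())
    return Recording(
        subject_id=f"S{subject_index:03d}",
        channel_labels=spec.channel_labels,
        rate=spec.rate,
        samples=samples,
    )


def gen_cohort(spec: SyntheticSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate all recordings plus the behavior table.

    Rating for subject ``s`` is ``4 + beta * (S_s - E[S]) + eps`` clipped to
    [1, 7], where ``S_s`` is the subject's summed realized edge strength,
    ``E[S]`` the nominal (population) sum, and ``eps ~ N(0, behavior_noise)``.
    Centering on the scale midpoint makes clipping rare at realistic noise
    levels while keeping the score-strength correlation intact.
    """
    recordings = [gen_recording(spec, s) for s in range(spec.n_subjects)]
    table = gen_behavior_table(spec)
    return recordings, table


def gen_behavior_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Behavior table alone (no EEG synthesis); same draws as gen_cohort."""
    nominal_sum = float(sum(e.strength for e in spec.coupling_edges))
    ratings = np.empty(spec.n_subjects)
    ages = np.empty(spec.n_subjects, dtype=int)
    for s in range(spec.n_subjects):
        strength_sum = float(realized_edge_strengths(spec, s).sum())
        noise = _rng(spec, s, _STREAM_BEHAVIOR).normal(0.0, spec.behavior_noise)
        raw = 4.0 + spec.behavior_effect * (strength_sum - nominal_sum) + noise
        ratings[s] = np.clip(raw, 1.0, 7.0)
        ages[s] = _rng(spec, s, _STREAM_AGE).integers(spec.age_range[0], spec.age_range[1] + 1)
    n_male, _ = spec.sex_counts
    return pd.DataFrame(
        {
            "subject_id": [f"S{s:03d}" for s in range(spec.n_subjects)],
            "sex": ["M"] * n_male + ["F"] * (spec.n_subjects - n_male),
            "age": ages,
            "rating": ratings,
        }
    )


def select_percentile_band(
    ratings: np.ndarray | list[float], lo_pct: float, hi_pct: float
) -> np.ndarray:
    """Indices of items whose rating falls in a central percentile band.

    Percentiles use the linear-interpolation convention of
    :func:`numpy.percentile`; both bounds are inclusive. Used to pick
    middle-attractive stimuli (e.g. the 27th-73rd percentile band of a
    pre-rated item pool).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size == 0:
        raise ValueError("empty ratings")
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError(f"need 0 <= lo_pct < hi_pct <= 100, got ({lo_pct}, {hi_pct})")
    lo = np.percentile(ratings, lo_pct)
    hi = np.percentile(ratings, hi_pct)
    return np.flatnonzero((ratings >= lo) & (ratings <= hi))
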