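"""Canonical synthetic study conditions used for validation.

These presets pin down the cohorts on which the package's statistical
properties are demonstrated; tests and the reproduction script both build
on them so the conditions are defined exactly once.

Problem sizes are scaled-down analogues of a full resting-state study
(which would be 64 channels, 500 Hz, 200 s): fewer channels and shorter
recordings at 250 Hz keep whole-cohort simulations tractable on a single
CPU while preserving every statistical feature the checks exercise — the
2-s epoch grid, the four-band structure, narrow-band coupling, and the
edge-sum behavior model.
"""

from __future__ import annotations

import numpy as np

from .core import BandDefinition
from .simulate import CouplingEdge, SyntheticSpec

ALPHA = BandDefinition("alpha", 8.0, 13.0)

# Behavior-effect sizing: realized edge strengths are kappa +- U(-spread,
# spread), so the strength sum over E edges has variance E * (2*spread)^2/12.
# Choosing beta = noise_sd / sd(strength sum) makes signal variance equal
# noise variance, i.e. a population R^2 of 0.5 between the edge-strength sum
# and the behavior score.


def cpm_recovery_spec(seed: int) -> SyntheticSpec:
    """Cohort with a real connectivity->behavior effect (population R^2 = 0.5).

    75 subjects, 16 channels, five coupled alpha edges on disjoint channel
    pairs with per-subject strengths U(0.1, 0.9); 60-s recordings at 250 Hz
    (30 two-second epochs). Used to show the CPM protocol recovers a known
    effect. Subject-level alpha-power heterogeneity is disabled so the
    cohort varies only in the parameter under recovery (between-subject
    amplitude jitter changes in-band SNR and therefore attenuates the
    WPLI-strength mapping; that separate mechanism is exercised by the
    arousal-index checks).
    """
    edges = tuple(
        CouplingEdge(i=2 * k, j=2 * k + 1, band="alpha", lag=np.pi / 2, strength=0.5)
        for k in range(5)
    )
    spread = 0.4
    noise_sd = 0.8
    strength_sd = np.sqrt(len(edges) * (2 * spread) ** 2 / 12.0)
    return SyntheticSpec(
        n_subjects=75,
        n_channels=16,
        rate=250.0,
        duration=60.0,
        bands=(ALPHA,),
        coupling_edges=edges,
        coupling_spread=spread,
        alpha_power_spread=0.0,
        behavior_effect=noise_sd / strength_sd,
        behavior_noise=noise_sd,
        seed=seed,
    )


def cpm_null_spec(seed: int) -> SyntheticSpec:
    """Cohort with coupling but a zero behavior effect (beta = 0).

    30 subjects, 8 channels, 20-s recordings at 250 Hz. Behavior is pure
    noise around the scale midpoint, so any CPM "prediction" is spurious;
    used for permutation-p calibration and type-I error checks.
    """
    edges = (
        CouplingEdge(i=0, j=1, band="alpha", lag=np.pi / 2, strength=0.5),
        CouplingEdge(i=2, j=3, band="alpha", lag=np.pi / 2, strength=0.5),
    )
    return SyntheticSpec(
        n_subjects=30,
        n_channels=8,
        rate=250.0,
        duration=20.0,
        bands=(ALPHA,),
        coupling_edges=edges,
        coupling_spread=0.4,
        behavior_effect=0.0,
        behavior_noise=0.8,
        seed=seed,
    )


def wpli_sweep_spec(kappa: float, seed: int) -> SyntheticSpec:
    """Two-channel cohort with one alpha edge of strength ``kappa``.

    100-s recordings at 250 Hz (50 two-second epochs); subject-level alpha
    heterogeneity disabled so the sweep isolates the coupling strength.
    """
    return SyntheticSpec(
        n_subjects=1,
        n_channels=2,
        rate=250.0,
        duration=100.0,
        bands=(ALPHA,),
        coupling_edges=(CouplingEdge(0, 1, "alpha", np.pi / 2, kappa),),
        alpha_power_spread=0.0,
        seed=seed,
    )
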