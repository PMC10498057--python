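"""WPLI estimator: analytic limits, invariances, and epoching."""

import numpy as np
import pytest
from scipy.signal import hilbert

from eegcpm.connectivity import bandpass_band, connectome_per_band, make_epochs, wpli_matrix
from eegcpm.core import DEFAULT_BANDS, BandDefinition
from eegcpm.simulate import gen_recording
from eegcpm.scenarios import wpli_sweep_spec

from conftest import ALPHA, make_recording


def narrowband_pair(seed, n=25000, rate=250.0):
    """Two independent alpha-filtered white-noise channels."""
    rng = np.random.default_rng(seed)
    rec = make_recording(rng.standard_normal((2, n)), rate=rate)
    return bandpass_band(rec, ALPHA)


class TestAnalyticLimits:
    def test_identical_channels_give_zero(self, rng):
        x = bandpass_band(make_recording(rng.standard_normal(10000)), ALPHA).samples[0]
        rec = make_recording(np.vstack([x, x]))
        conn = wpli_matrix(make_epochs(rec, 2.0, band=ALPHA))
        assert conn.matrix[0, 1] == 0.0

    def test_quadrature_pair_gives_one(self, rng):
        x = bandpass_band(make_recording(rng.standard_normal(25000)), ALPHA).samples[0]
        quad = np.imag(hilbert(x))  # constant pi/2 lag
        rec = make_recording(np.vstack([x, quad]))
        conn = wpli_matrix(make_epochs(rec, 2.0, band=ALPHA))
        assert conn.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_independent_narrowband_noise_near_zero(self):
        values = []
        for seed in range(5):
            rec = narrowband_pair(seed, n=50000)  # 100 epochs
            values.append(wpli_matrix(make_epochs(rec, 2.0, band=ALPHA)).matrix[0, 1])
        assert np.mean(values) < 0.2

    def test_lag_sign_does_not_matter(self, rng):
        x = bandpass_band(make_recording(rng.standard_normal(25000)), ALPHA).samples[0]
        quad = np.imag(hilbert(x))
        up = wpli_matrix(make_epochs(make_recording(np.vstack([x, quad])), 2.0, band=ALPHA))
        down = wpli_matrix(make_epochs(make_recording(np.vstack([quad, x])), 2.0, band=ALPHA))
        assert up.matrix[0, 1] == pytest.approx(down.matrix[0, 1], abs=1e-12)


class TestInvariances:
    def test_symmetric_bounded_zero_diagonal(self, noise_recording):
        conn = connectome_per_band(noise_recording, (ALPHA,))[0]
        m = conn.matrix
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert (m >= 0).all() and (m <= 1).all()
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_per_channel_amplitude_rescaling_is_ignored(self, noise_recording):
        base = connectome_per_band(noise_recording, (ALPHA,))[0].matrix
        scaled = noise_recording.with_samples(
            noise_recording.samples * np.array([1.0, 7.0, 0.3, 100.0])[:, None]
        )
        rescaled = connectome_per_band(scaled, (ALPHA,))[0].matrix
        np.testing.assert_allclose(base, rescaled, atol=1e-9)

    def test_global_time_shift_leaves_wpli_unchanged(self):
        rec = narrowband_pair(3, n=50000)
        rolled = rec.with_samples(np.roll(rec.samples, 500, axis=-1))
        a = wpli_matrix(make_epochs(rec, 2.0, band=ALPHA)).matrix[0, 1]
        b = wpli_matrix(make_epochs(rolled, 2.0, band=ALPHA)).matrix[0, 1]
        assert a == pytest.approx(b, abs=0.05)

    def test_null_estimate_tightens_with_more_epochs(self):
        short, long_ = [], []
        for seed in range(10):
            short.append(
                wpli_matrix(
                    make_epochs(narrowband_pair(seed, n=12500), 2.0, band=ALPHA)
                ).matrix[0, 1]
            )  # 25 epochs
            long_.append(
                wpli_matrix(
                    make_epochs(narrowband_pair(seed, n=50000), 2.0, band=ALPHA)
                ).matrix[0, 1]
            )  # 100 epochs
        assert np.std(long_) < np.std(short)
        assert np.mean(long_) < np.mean(short)

    def test_coupling_strength_sweep_is_monotone(self):
        for seed in range(5):
            values = []
            for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
                rec = gen_recording(wpli_sweep_spec(kappa, seed), 0)
                values.append(connectome_per_band(rec, (ALPHA,))[0].matrix[0, 1])
            assert np.all(np.diff(values) >= 0), values


class TestEstimatorVariants:
    def test_epoch_mean_variant_is_biased_up_on_null_edges(self):
        epochs = make_epochs(narrowband_pair(0, n=50000), 2.0, band=ALPHA)
        pooled = wpli_matrix(epochs, estimator="pooled").matrix[0, 1]
        epoch_mean = wpli_matrix(epochs, estimator="epoch-mean").matrix[0, 1]
        assert epoch_mean > pooled
        assert 0 <= epoch_mean <= 1

    def test_unknown_estimator_rejected(self):
        epochs = make_epochs(narrowband_pair(0, n=5000), 2.0, band=ALPHA)
        with pytest.raises(ValueError, match="estimator"):
            wpli_matrix(epochs, estimator="median")

    def test_broadband_input_warns(self, noise_recording):
        with pytest.warns(UserWarning, match="broadband"):
            wpli_matrix(make_epochs(noise_recording, 2.0))


class TestEpoching:
    def test_200_seconds_gives_100_two_second_epochs(self, rng):
        rec = make_recording(rng.standard_normal((2, 50000)), rate=250.0)
        assert make_epochs(rec, 2.0).n_epochs == 100

    def test_trailing_remainder_dropped(self, rng):
        rec = make_recording(rng.standard_normal((2, 1250)), rate=250.0)  # 5 s
        assert make_epochs(rec, 2.0).n_epochs == 2

    def test_epoch_equal_to_duration_gives_single_epoch(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)), rate=250.0)
        assert make_epochs(rec, 4.0).n_epochs == 1

    def test_nonpositive_length_rejected(self, noise_recording):
        with pytest.raises(ValueError):
            make_epochs(noise_recording, 0.0)


class TestPerBand:
    def test_default_band_set_yields_four_connectomes(self, rng):
        rec = make_recording(rng.standard_normal((3, 25000)), rate=250.0)
        conns = connectome_per_band(rec, DEFAULT_BANDS)
        assert [c.band.name for c in conns] == ["delta", "theta", "alpha", "beta"]

    def test_edge_vector_length_is_n_choose_2(self, rng):
        rec = make_recording(rng.standard_normal((8, 5000)), rate=250.0)
        conn = connectome_per_band(rec, (ALPHA,))[0]
        assert conn.edge_vector().shape == (8 * 7 // 2,)

    def test_empty_band_list_gives_empty_result(self, noise_recording):
        assert connectome_per_band(noise_recording, ()) == []

    def test_band_above_nyquist_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)), rate=50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            connectome_per_band(rec, (BandDefinition("beta", 13.0, 30.0),))
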