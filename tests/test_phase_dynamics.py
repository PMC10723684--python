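"""Filter, phase, coherence and leading-eigenvector tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dynstates.phase_dynamics import (
    AcquisitionSpec,
    align_eigenvector_sequence,
    bandpass_filter,
    coherence_leading_eigenvectors,
    edge_trim_count,
    instantaneous_phase,
    leading_eigenvector,
    leida_transform,
    phase_coherence_matrix,
)
from dynstates.synthetic_cohort import SimulationConfig, simulate_ic_timecourses

SPEC = AcquisitionSpec()


def _sinusoid(freq_hz: float, n: int = 400, tr: float = 1.6) -> np.ndarray:
    t = np.arange(n) * tr
    return np.sin(2 * np.pi * freq_hz * t)


class TestEdgeTrim:
    @pytest.mark.parametrize(
        "f_min, tr, expected",
        [(0.038, 1.6, 17), (0.5, 1.0, 2), (0.04, 2.0, 13)],
    )
    def test_cycle_count(self, f_min, tr, expected):
        assert edge_trim_count(f_min, tr) == expected

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            edge_trim_count(0.0, 1.6)
        with pytest.raises(ValueError):
            edge_trim_count(0.04, -1.0)


class TestBandpass:
    def test_dc_rejected(self):
        x = np.ones((400, 1))
        y = bandpass_filter(x, SPEC)
        assert np.max(np.abs(y)) < 1e-6

    def test_passband_transparent_and_zero_phase(self):
        # closed-form |H|^2 for a forward-backward 7th-order Butterworth
        # band-pass is ~1 at mid-band, so amplitude should be preserved
        x = _sinusoid(0.055)
        y = bandpass_filter(x[:, None], SPEC)[:, 0]
        core = slice(100, 300)  # steady state, clear of filter transients
        ratio = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert 0.95 <= ratio <= 1.05
        xc = np.correlate(y[core], x[core], mode="full")
        assert np.argmax(xc) == len(x[core]) - 1  # peak at lag 0

    def test_stopband_attenuated(self):
        x = _sinusoid(0.20)
        y = bandpass_filter(x[:, None], SPEC)[:, 0]
        assert np.abs(y[50:350]).max() / np.abs(x).max() < 0.05

    def test_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="timepoints"):
            bandpass_filter(np.random.default_rng(0).normal(size=(20, 3)), SPEC)


class TestInstantaneousPhase:
    def test_cosine_phase_closed_form(self):
        omega = 2 * np.pi * 0.055
        t = np.arange(400) * 1.6
        x = np.cos(omega * t)
        phase = instantaneous_phase(x[:, None])[:, 0]
        expected = np.angle(np.exp(1j * omega * t))
        err = np.abs(np.angle(np.exp(1j * (phase - expected))))
        assert err[30:-30].max() < 0.05

    def test_sine_lags_cosine_by_half_pi(self):
        omega = 2 * np.pi * 0.05
        t = np.arange(400) * 1.6
        x = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        phase = instantaneous_phase(x)
        diff = np.angle(np.exp(1j * (phase[:, 0] - phase[:, 1])))
        assert np.abs(diff[30:-30] - np.pi / 2).max() < 0.05

    def test_identical_columns_have_zero_phase_difference(self):
        x = _sinusoid(0.05)[:, None]
        phase = instantaneous_phase(np.hstack([x, x]))
        assert np.all(phase[:, 0] == phase[:, 1])

    def test_zero_column_rejected(self):
        x = np.column_stack([_sinusoid(0.05), np.zeros(400)])
        with pytest.raises(ValueError, match="zero"):
            instantaneous_phase(x)


class TestPhaseCoherence:
    def test_equal_phases_give_all_ones(self):
        m = phase_coherence_matrix(np.full(5, 0.7))
        assert np.allclose(m, 1.0)

    @pytest.mark.parametrize("delta, value", [(np.pi, -1.0), (np.pi / 3, 0.5)])
    def test_pairwise_cosine(self, delta, value):
        m = phase_coherence_matrix(np.array([0.0, delta]))
        assert m[0, 1] == pytest.approx(value, abs=1e-12)

    def test_invariants(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 12)
        m = phase_coherence_matrix(theta)
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= -1.0 and m.max() <= 1.0


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        n = 6
        v = leading_eigenvector(np.ones((n, n)))
        assert np.allclose(np.abs(v), 1 / np.sqrt(n))
        assert np.allclose(np.ones((n, n)) @ v, n * v)

    def test_two_block_antiphase_sign_split(self):
        u = np.array([1, 1, 1, -1, -1, -1], dtype=float)
        m = phase_coherence_matrix(np.where(u > 0, 0.0, np.pi))
        v = leading_eigenvector(m)
        assert np.array_equal(np.sign(v), u) or np.array_equal(np.sign(v), -u)

    def test_matches_dense_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(size=(10, 10))
            m = a + a.T
            v = leading_eigenvector(m)
            w, vec = np.linalg.eigh(m)
            oracle = vec[:, -1]
            assert min(
                np.abs(v - oracle).max(), np.abs(v + oracle).max()
            ) < 1e-8

    def test_non_symmetric_rejected(self):
        m = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            leading_eigenvector(m)

    def test_rank_two_fast_path_matches_general_route(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(40, 9))
        fast = coherence_leading_eigenvectors(theta)
        for t in range(40):
            slow = leading_eigenvector(phase_coherence_matrix(theta[t]))
            assert min(
                np.abs(fast[t] - slow).max(), np.abs(fast[t] + slow).max()
            ) < 1e-8


class TestAlignment:
    def test_injected_flips_removed(self, rng):
        v = rng.normal(size=8)
        v /= np.linalg.norm(v)
        if v.sum() > 0:
            v = -v
        seq = np.array([v * ((-1) ** t) for t in range(10)])
        aligned = align_eigenvector_sequence(seq)
        assert np.allclose(aligned, np.tile(v, (10, 1)))

    def test_idempotent_on_consistent_sequence(self, rng):
        raw = rng.normal(size=(20, 6))
        aligned = align_eigenvector_sequence(raw)
        again = align_eigenvector_sequence(aligned)
        assert np.array_equal(aligned, again)

    @given(seed=hst.integers(0, 99))
    @settings(max_examples=100)
    def test_consecutive_inner_products_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(30, 5))
        aligned = align_eigenvector_sequence(raw)
        dots = np.einsum("ij,ij->i", aligned[1:], aligned[:-1])
        assert np.all(dots >= 0)
        assert aligned[0].sum() <= 0


class TestLeidaTransform:
    def test_retained_row_count_default_and_override(self):
        cfg = SimulationConfig(n_subjects_per_group=1, n_volumes=400, seed=0)
        tcs, _ = simulate_ic_timecourses(cfg)
        tc = next(iter(tcs.values()))
        out = leida_transform(tc, SPEC)
        assert out.shape == (400 - 2 * 17, 53)
        assert np.allclose(np.linalg.norm(out.to_numpy(), axis=1), 1.0, atol=1e-9)
        forced = leida_transform(tc, SPEC, retained_volumes=361)
        assert forced.shape == (361, 53)

    def test_noiseless_two_regime_bipartition_recovery(self):
        """Away from regime switches, the aligned eigenvector sign
        pattern equals the planted bipartition at >= 99% of timepoints."""
        # minority communities of 4/20 components: pairwise-positive
        # regime inner products, as the default generator guarantees
        signs = -np.ones((2, 20), dtype=int)
        signs[0, :4] = 1
        signs[1, 4:8] = 1
        cfg = SimulationConfig(
            n_subjects_per_group=1,
            n_components=20,
            n_volumes=400,
            k_true=2,
            regime_signs=signs,
            noise_sd=0.0,
            seed=4,
        )
        tcs, truth = simulate_ic_timecourses(cfg)
        tc = next(iter(tcs.values()))
        seq = next(iter(truth.regime_sequences.values()))
        out = leida_transform(tc.to_numpy(), SPEC)
        trim = SPEC.trim_volumes
        retained = np.arange(trim, 400 - trim)
        switches = np.nonzero(np.diff(seq))[0]
        if switches.size:
            dist = np.min(np.abs(retained[:, None] - switches[None, :]), axis=1)
        else:
            dist = np.full(retained.size, np.inf)
        interior = dist >= 8
        planted = signs[seq[retained] - 1]
        match = np.all(np.sign(out) == planted, axis=1)
        assert match[interior].mean() >= 0.99
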