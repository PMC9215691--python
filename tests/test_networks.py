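"""Functional-network inference: phases, PLV, IAAFT surrogates, thresholding."""

import numpy as np
import pytest
from scipy import signal as sps

from ictonet import (
    CHANNELS_1020,
    EEGSegment,
    FunctionalNetwork,
    build_network,
    default_coupling_spec,
    generate_segment,
    iaaft_surrogate,
    instantaneous_phase,
    plv_pair,
    preprocess_segment,
    surrogate_threshold,
)


class TestInstantaneousPhase:
    def test_tone_phase_advances_at_carrier_rate(self, tone_segment):
        ph = instantaneous_phase(tone_segment)
        mid = slice(200, -200)
        slope = np.diff(np.unwrap(ph.phases[0]))[mid].mean() * tone_segment.fs
        assert slope == pytest.approx(2 * np.pi * 7.0, rel=0.01)

    def test_quadrature_pair_offset_is_half_pi(self, tone_segment):
        ph = instantaneous_phase(tone_segment)
        mid = slice(200, -200)
        diff = np.angle(np.exp(1j * (ph.phases[0] - ph.phases[1])))[mid]
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.02)

    def test_phases_within_principal_interval(self, strong_pair_segment):
        ph = instantaneous_phase(strong_pair_segment)
        assert ph.phases.max() <= np.pi
        assert ph.phases.min() > -np.pi

    def test_constant_channel_rejected(self):
        seg = EEGSegment(
            data=np.vstack([np.zeros(100), np.random.default_rng(0).normal(size=100)]),
            fs=100.0, channel_labels=("flat", "ok"),
        )
        with pytest.raises(ValueError, match="flat"):
            instantaneous_phase(seg)


class TestPlvPair:
    def test_identical_series_fully_locked_zero_lag(self):
        ph = np.random.default_rng(0).uniform(-np.pi, np.pi, 500)
        plv, tau = plv_pair(ph, ph)
        assert plv == pytest.approx(1.0)
        assert tau == pytest.approx(0.0)

    def test_constant_offset_gives_offset_lag(self):
        ph = np.random.default_rng(1).uniform(-np.pi, np.pi, 500)
        plv, tau = plv_pair(ph + np.pi / 2, ph)
        assert plv == pytest.approx(1.0)
        assert tau == pytest.approx(np.pi / 2)

    def test_independent_phases_match_rayleigh_expectation(self):
        # E[PLV] for independent uniform phases = sqrt(pi)/(2*sqrt(Nt))
        rng = np.random.default_rng(2)
        nt = 5000
        vals = [
            plv_pair(rng.uniform(-np.pi, np.pi, nt), rng.uniform(-np.pi, np.pi, nt))[0]
            for _ in range(300)
        ]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(nt))
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            plv_pair(np.array([]), np.array([]))


class TestIaaft:
    def test_sorted_values_preserved_exactly(self):
        x = np.random.default_rng(3).normal(size=512)
        s = iaaft_surrogate(x, seed=1)
        np.testing.assert_array_equal(np.sort(s), np.sort(x))

    def test_spectral_mismatch_shrinks_with_iterations(self):
        # AR(1) input: periodogram error after 10 iterations is well below
        # the error of the randomly permuted start, decreasing on the way
        rng = np.random.default_rng(4)
        x = sps.lfilter([1.0], [1.0, -0.9], rng.normal(size=1024))
        target = np.abs(np.fft.rfft(x))
        errs = []
        for n_it in range(0, 11, 2):
            s = iaaft_surrogate(x, n_iterations=n_it, seed=5)
            errs.append(np.linalg.norm(np.abs(np.fft.rfft(s)) - target))
        assert errs[-1] < 0.2 * errs[0]
        assert all(b <= a * 1.10 for a, b in zip(errs, errs[1:]))

    def test_ar1_autocorrelation_approximately_preserved(self):
        rng = np.random.default_rng(6)
        x = sps.lfilter([1.0], [1.0, -0.8], rng.normal(size=4096))

        def rho1(v):
            v = v - v.mean()
            return np.dot(v[:-1], v[1:]) / np.dot(v, v)

        rhos = [rho1(iaaft_surrogate(x, seed=k)) for k in range(5)]
        assert np.mean(rhos) == pytest.approx(rho1(x), rel=0.1)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(7).normal(size=256)
        np.testing.assert_array_equal(
            iaaft_surrogate(x, seed=9), iaaft_surrogate(x, seed=9)
        )


class TestSurrogateThreshold:
    @pytest.mark.parametrize(
        "n_exceeded, expected", [(99, True), (95, True), (94, False), (0, False)]
    )
    def test_decision_boundary_at_95_of_99(self, n_exceeded, expected):
        surr = np.linspace(0.1, 0.8, 99)
        observed = (
            surr[n_exceeded - 1] + 1e-9 if n_exceeded > 0 else surr[0]
        )
        assert surrogate_threshold(observed, surr) is expected

    def test_tie_with_minimum_rejected(self):
        surr = np.linspace(0.1, 0.8, 99)
        assert surrogate_threshold(surr[0], surr) is False


class TestBuildNetwork:
    def test_duplicated_channel_rejected_by_zero_lag_rule(self):
        rng = np.random.default_rng(8)
        base = sps.sosfiltfilt(
            sps.butter(4, [6, 9], btype="bandpass", fs=250.0, output="sos"),
            rng.normal(size=(4, 2500)),
        )
        base[1] = base[0]  # exact copy: PLV = 1, tau = 0
        seg = EEGSegment(data=base, fs=250.0, channel_labels=("a", "b", "c", "d"))
        net = build_network(seg, n_surrogates=19, seed=0)
        plv, tau = plv_pair(*instantaneous_phase(seg).phases[:2])
        assert plv == pytest.approx(1.0)
        assert net.weights[0, 1] == 0.0

    def test_strong_coupled_pair_survives(self, strong_pair_segment):
        net = build_network(strong_pair_segment, n_surrogates=99, seed=1)
        i, j = CHANNELS_1020.index("O1"), CHANNELS_1020.index("O2")
        assert net.weights[i, j] > 0.8
        assert abs(net.lags[i, j] - np.pi / 4) < 0.1

    def test_symmetry_zero_diagonal_and_lag_floor(self, baseline_network):
        w = baseline_network.weights
        np.testing.assert_array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        zero_lag = 2 * np.pi / 125.0
        surviving = w > 0
        assert np.all(np.abs(baseline_network.lags[surviving]) > zero_lag)

    def test_null_edge_density_controlled(self):
        densities = []
        for seed in range(3):
            spec = default_coupling_spec(seed=seed, fs=125.0, duration=10.0)
            seg = preprocess_segment(generate_segment(spec), target_fs=125.0)
            net = build_network(seg, n_surrogates=19, seed=seed + 40)
            n = net.n_nodes
            densities.append((net.weights > 0).sum() / (n * (n - 1)))
        assert np.mean(densities) <= 0.10

    def test_channel_permutation_permutes_network(self, strong_pair_spec):
        seg = preprocess_segment(generate_segment(strong_pair_spec))
        net = build_network(seg, n_surrogates=19, seed=5)
        perm = np.random.default_rng(0).permutation(seg.n_channels)
        seg_p = EEGSegment(
            data=seg.data[perm], fs=seg.fs,
            channel_labels=tuple(seg.channel_labels[k] for k in perm),
        )
        net_p = build_network(seg_p, n_surrogates=19, seed=5)
        np.testing.assert_allclose(
            net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-12
        )

    def test_surrogate_destroys_coupling_of_strong_pair(self,
                                                        strong_pair_segment):
        # PLV of a channel against its partner's IAAFT surrogate must fall
        # well below the PLV with the original partner
        from ictonet.preprocess import bandpass_low_alpha

        i, j = CHANNELS_1020.index("O1"), CHANNELS_1020.index("O2")
        seg = strong_pair_segment
        ph = instantaneous_phase(seg)
        plv_orig, _ = plv_pair(ph.phases[i], ph.phases[j])
        surr_plvs = []
        for seed in range(5):
            surr = iaaft_surrogate(seg.data[j], seed=seed)
            surr_seg = EEGSegment(
                data=np.vstack([seg.data[i], surr]), fs=seg.fs,
                channel_labels=("a", "b"),
            )
            surr_seg = bandpass_low_alpha(surr_seg)
            sp = instantaneous_phase(surr_seg)
            surr_plvs.append(plv_pair(sp.phases[0], sp.phases[1])[0])
        assert max(surr_plvs) < plv_orig

    def test_roundtrip_tsv_json(self, baseline_network, tmp_path):
        prefix = str(tmp_path / "net")
        baseline_network.save(prefix)
        loaded = FunctionalNetwork.load(prefix)
        np.testing.assert_allclose(loaded.weights, baseline_network.weights,
                                   atol=1e-7)
        np.testing.assert_allclose(loaded.lags, baseline_network.lags)
        assert loaded.channel_labels == baseline_network.channel_labels

    def test_remove_node(self, baseline_network):
        reduced = baseline_network.remove_node("O1")
        assert reduced.n_nodes == 19
        assert "O1" not in reduced.channel_labels
        keep = [i for i, c in enumerate(baseline_network.channel_labels)
                if c != "O1"]
        np.testing.assert_array_equal(
            reduced.weights, baseline_network.weights[np.ix_(keep, keep)]
        )
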