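import numpy as np
import pytest

from entrack.errors import (AlignmentError, ParameterError,
                            UndefinedCorrelationError)
from entrack.rsa import (RDM, average_rdms, band_rsa, compare_rdms,
                         compute_rdm, electrode_rsa, layer_profile,
                         noise_ceiling, rank_transform, response_vector)
from entrack.signal_prep import EEGEpoch


def random_rdm(rng, n=6):
    vecs = {f"s{i}": rng.standard_normal(8) for i in range(n)}
    return compute_rdm(vecs)


def spearman_oracle(x, y):
    """Independent oracle: average-tie ranks, then Pearson by hand."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = np.array(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))


class TestResponseVector:
    def make_epoch(self, data, rate=250.0):
        return EEGEpoch(data, rate, (-100.0, 600.0))

    def test_channel_major_order(self):
        data = np.zeros((2, 175))
        data[0, 25:28] = [1, 2, 3]
        data[1, 25:28] = [4, 5, 6]
        ep = self.make_epoch(data)
        v = response_vector(ep, [0, 1], (0.0, 0.012))
        assert np.allclose(v, [1, 2, 3, 4, 5, 6])

    def test_single_channel_is_series(self, rng):
        data = rng.standard_normal((3, 175))
        ep = self.make_epoch(data)
        v = response_vector(ep, [1], (0.0, 0.4))
        assert np.allclose(v, data[1, 25:125])

    def test_common_window_truncation(self, rng):
        # epochs of different extents give equal-length vectors once the
        # common window applies
        short = self.make_epoch(rng.standard_normal((2, 175)))
        long = EEGEpoch(rng.standard_normal((2, 300)), 250.0,
                        (-100.0, 1100.0))
        v1 = response_vector(short, [0, 1], (0.0, 0.25))
        v2 = response_vector(long, [0, 1], (0.0, 0.25))
        assert len(v1) == len(v2) == 2 * int(0.25 * 250)

    def test_window_outside_epoch_raises(self, rng):
        ep = self.make_epoch(rng.standard_normal((2, 175)))
        with pytest.raises(AlignmentError):
            response_vector(ep, [0], (0.0, 2.0))


class TestComputeRDM:
    def test_identical_vectors_zero(self):
        v = np.arange(5.0)
        rdm = compute_rdm({"a": v, "b": v.copy(), "c": v.copy()})
        assert np.allclose(rdm.matrix, 0.0)

    def test_single_coordinate_difference(self):
        a = np.zeros(4)
        b = np.zeros(4)
        b[2] = 2.5
        rdm = compute_rdm({"a": a, "b": b})
        assert rdm.matrix[0, 1] == pytest.approx(2.5)

    def test_matches_loop_oracle(self, rng):
        vecs = {f"s{i}": rng.standard_normal(7) for i in range(5)}
        rdm = compute_rdm(vecs)
        ids = list(vecs)
        for i in range(5):
            for j in range(5):
                d = np.sqrt(sum((vecs[ids[i]][k] - vecs[ids[j]][k]) ** 2
                                for k in range(7)))
                assert rdm.matrix[i, j] == pytest.approx(d, abs=1e-10)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(AlignmentError):
            compute_rdm({"a": rng.standard_normal(5),
                         "b": rng.standard_normal(6)})

    def test_single_stimulus_raises(self, rng):
        with pytest.raises(ParameterError):
            compute_rdm({"a": rng.standard_normal(5)})


class TestAverageRDMs:
    def test_single_identity(self, rng):
        r = random_rdm(rng)
        out = average_rdms([r])
        assert np.allclose(out.matrix, r.matrix)

    def test_scaling(self, rng):
        r = random_rdm(rng)
        r3 = RDM(3.0 * r.matrix, r.stimulus_order)
        out = average_rdms([r, r3])
        assert np.allclose(out.matrix, 2.0 * r.matrix)

    def test_matches_loop_oracle(self, rng):
        rdms = [random_rdm(rng) for _ in range(4)]
        out = average_rdms(rdms)
        n = rdms[0].n_stimuli
        for i in range(n):
            for j in range(n):
                assert out.matrix[i, j] == pytest.approx(
                    sum(r.matrix[i, j] for r in rdms) / 4.0, abs=1e-12)

    def test_order_mismatch_raises(self, rng):
        a = random_rdm(rng)
        b = RDM(a.matrix, tuple(reversed(a.stimulus_order)))
        with pytest.raises(AlignmentError):
            average_rdms([a, b])


class TestCompareRDMs:
    def test_self_correlation_is_one(self, rng):
        r = random_rdm(rng)
        assert compare_rdms(r, r) == pytest.approx(1.0)

    def test_monotone_invariance(self, rng):
        r = random_rdm(rng)
        sq = RDM(r.matrix ** 2, r.stimulus_order)
        assert compare_rdms(r, sq) == pytest.approx(1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        for _ in range(20):
            a, b = random_rdm(rng, 4), random_rdm(rng, 4)
            b = RDM(b.matrix, a.stimulus_order)
            rho = compare_rdms(a, b)
            assert rho == pytest.approx(
                spearman_oracle(a.lower_triangle(), b.lower_triangle()),
                abs=1e-12)

    def test_constant_triangle_raises(self):
        m = np.ones((4, 4)) - np.eye(4)
        r = RDM(m, ("a", "b", "c", "d"))
        other = random_rdm(np.random.default_rng(0), 4)
        other = RDM(other.matrix, r.stimulus_order)
        with pytest.raises(UndefinedCorrelationError):
            compare_rdms(r, other)

    def test_order_mismatch_raises(self, rng):
        a = random_rdm(rng)
        b = RDM(a.matrix, tuple(reversed(a.stimulus_order)))
        with pytest.raises(AlignmentError):
            compare_rdms(a, b)


class TestRankTransform:
    def test_distinct_values(self):
        m = np.zeros((3, 3))
        m[1, 0] = m[0, 1] = 1.0
        m[2, 0] = m[0, 2] = 5.0
        m[2, 1] = m[1, 2] = 9.0
        out = rank_transform(RDM(m, ("a", "b", "c")))
        assert out.matrix[1, 0] == 0.0
        assert out.matrix[2, 0] == 0.5
        assert out.matrix[2, 1] == 1.0

    def test_all_ties_half(self):
        m = np.ones((4, 4)) - np.eye(4)
        out = rank_transform(RDM(m, tuple("abcd")))
        tri = out.lower_triangle()
        assert np.allclose(tri, 0.5)

    def test_monotone_with_input(self, rng):
        r = random_rdm(rng, 7)
        out = rank_transform(r)
        assert spearman_oracle(r.lower_triangle(),
                               out.lower_triangle()) == pytest.approx(1.0)

    def test_preserves_rdm_invariants(self, rng):
        out = rank_transform(random_rdm(rng))
        assert np.allclose(out.matrix, out.matrix.T)
        assert np.allclose(np.diag(out.matrix), 0.0)
        assert out.matrix.min() >= 0.0 and out.matrix.max() <= 1.0


class TestNoiseCeiling:
    def test_identical_participants(self, rng):
        r = random_rdm(rng)
        nc = noise_ceiling([r, RDM(r.matrix, r.stimulus_order),
                            RDM(r.matrix, r.stimulus_order)])
        assert nc.lower == pytest.approx(1.0)
        assert nc.upper == pytest.approx(1.0)

    def test_lower_below_upper_fuzzed(self, rng):
        for _ in range(30):
            shared = random_rdm(rng, 6)
            rdms = []
            for _p in range(4):
                noise = np.abs(rng.standard_normal(shared.matrix.shape))
                noise = (noise + noise.T) / 2
                np.fill_diagonal(noise, 0.0)
                rdms.append(RDM(shared.matrix + noise, shared.stimulus_order))
            nc = noise_ceiling(rdms)
            assert nc.lower <= nc.upper + 1e-12

    def test_bounds_decrease_with_noise(self, rng):
        shared = random_rdm(rng, 8)
        lowers, uppers = [], []
        for level in [0.1, 0.5, 1.0, 2.0, 4.0]:
            ls, us = [], []
            for _ in range(20):
                rdms = []
                for _p in range(4):
                    noise = np.abs(rng.standard_normal(shared.matrix.shape))
                    noise = (noise + noise.T) / 2 * level
                    np.fill_diagonal(noise, 0.0)
                    rdms.append(RDM(shared.matrix + noise,
                                    shared.stimulus_order))
                nc = noise_ceiling(rdms)
                ls.append(nc.lower)
                us.append(nc.upper)
            lowers.append(np.mean(ls))
            uppers.append(np.mean(us))
        assert np.all(np.diff(lowers) < 0)
        assert np.all(np.diff(uppers) < 0)

    def test_single_participant_raises(self, rng):
        with pytest.raises(ParameterError):
            noise_ceiling([random_rdm(rng)])


def _structured_rdms(rng, n_participants=4, n=8, noise=0.3):
    shared = random_rdm(rng, n)
    out = []
    for _ in range(n_participants):
        pert = np.abs(rng.standard_normal(shared.matrix.shape)) * noise
        pert = (pert + pert.T) / 2
        np.fill_diagonal(pert, 0.0)
        out.append(RDM(shared.matrix + pert, shared.stimulus_order))
    return shared, out


class TestLayerProfile:
    def test_untrained_equals_trained_gives_zero_t(self, rng):
        shared, eeg_rdms = _structured_rdms(rng)
        layers = {k: random_rdm(rng, 8) for k in range(1, 6)}
        for k in layers:
            layers[k] = RDM(layers[k].matrix, shared.stimulus_order)
        prof = layer_profile(eeg_rdms, layers, [layers])
        for t in prof.tests:
            assert t.t_statistic == pytest.approx(0.0, abs=1e-10) or \
                t.p_value == 1.0

    def test_more_similar_trained_layer_detected(self, rng):
        shared, eeg_rdms = _structured_rdms(rng, n_participants=6)
        trained = {}
        untrained = {}
        for k in range(1, 6):
            pert = np.abs(rng.standard_normal(shared.matrix.shape)) * 0.2
            pert = (pert + pert.T) / 2
            np.fill_diagonal(pert, 0.0)
            trained[k] = RDM(shared.matrix + pert, shared.stimulus_order)
            rnd = random_rdm(rng, 8)
            untrained[k] = RDM(rnd.matrix, shared.stimulus_order)
        prof = layer_profile(eeg_rdms, trained, [untrained])
        assert np.all(prof.mean_rho_trained > prof.mean_rho_untrained)
        for t in prof.tests:
            assert t.t_statistic > 0

    def test_two_sample_df(self, rng):
        shared, eeg_rdms = _structured_rdms(rng, n_participants=15)
        layers = {k: RDM(random_rdm(rng, 8).matrix, shared.stimulus_order)
                  for k in range(1, 6)}
        prof = layer_profile(eeg_rdms, layers, [layers])
        assert all(t.df == 28 for t in prof.tests)

    def test_too_few_participants_raises(self, rng):
        shared, eeg_rdms = _structured_rdms(rng, n_participants=1)
        layers = {k: RDM(random_rdm(rng, 8).matrix, shared.stimulus_order)
                  for k in range(1, 6)}
        with pytest.raises(ParameterError):
            layer_profile(eeg_rdms, layers, [layers])


def _epochs_by_participant(rng, n_participants=3, n_stimuli=5, n_reps=2,
                           n_channels=4, signal=None, signal_channels=()):
    """White-noise epochs, optionally with a per-stimulus signal planted
    into selected channels."""
    out = {}
    n_t = 250
    for p in range(n_participants):
        by_stim = {}
        for s in range(n_stimuli):
            reps = []
            for r in range(n_reps):
                data = rng.standard_normal((n_channels, n_t))
                if signal is not None:
                    for ch in signal_channels:
                        data[ch, 50:50 + signal.shape[1]] += signal[s]
                reps.append(EEGEpoch(data, 250.0, (-200.0, 800.0),
                                     participant_id=f"p{p}",
                                     stimulus_id=f"s{s}",
                                     repetition_index=r))
            by_stim[f"s{s}"] = reps
        out[p] = by_stim
    return out


class TestBandRSA:
    def test_shape_and_null_behavior(self, rng):
        epochs = _epochs_by_participant(rng)
        layers = {k: random_rdm(rng, 5) for k in range(1, 6)}
        for k in layers:
            layers[k] = RDM(layers[k].matrix,
                            tuple(f"s{i}" for i in range(5)))
        bands = [(0.0, 2.0), (2.0, 4.0), (4.0, 6.0)]
        table = band_rsa(epochs, [0, 1], (0.0, 0.6), bands, layers)
        assert table.shape == (3, 5)
        # white-noise EEG: no strong similarity to arbitrary layer RDMs
        assert np.all(np.abs(table) < 0.9)

    def test_signal_band_peaks(self, rng):
        # per-stimulus signal confined to 4-6 Hz; layer RDM built from
        # the same signals -> |rho| peaks in the 4-6 Hz band
        n_stimuli = 6
        t = np.arange(200) / 250.0
        sig = np.stack([np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi))
                        * rng.uniform(1.0, 3.0) for _ in range(n_stimuli)])
        sig *= 3.0
        epochs = _epochs_by_participant(rng, n_stimuli=n_stimuli,
                                        signal=sig, signal_channels=(0, 1))
        ids = tuple(f"s{i}" for i in range(n_stimuli))
        layer_rdm = compute_rdm({ids[i]: sig[i] for i in range(n_stimuli)})
        layers = {4: RDM(layer_rdm.matrix, ids)}
        bands = [(0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0), (8.0, 10.0)]
        table = band_rsa(epochs, [0, 1], (0.0, 0.6), bands, layers)
        assert np.argmax(np.abs(table[:, 0])) == 2

    def test_ten_bands_layout(self, rng):
        epochs = _epochs_by_participant(rng, n_participants=2, n_stimuli=4,
                                        n_reps=1)
        ids = tuple(f"s{i}" for i in range(4))
        layers = {k: RDM(random_rdm(rng, 4).matrix, ids) for k in range(1, 6)}
        bands = [(float(lo), float(lo + 2)) for lo in range(0, 20, 2)]
        table = band_rsa(epochs, [0], (0.0, 0.6), bands, layers)
        assert table.shape == (10, 5)


class TestElectrodeRSA:
    def test_masked_zero_contract(self, rng):
        epochs = _epochs_by_participant(rng, n_participants=4, n_channels=6)
        ids = tuple(f"s{i}" for i in range(5))
        trained = {4: RDM(random_rdm(rng, 5).matrix, ids)}
        untrained = [{4: RDM(random_rdm(rng, 5).matrix, ids)}]
        emap = electrode_rsa(epochs, 6, (0.0, 0.6), trained, untrained)
        assert emap.masked_rho[~emap.mask].tolist() == [0.0] * int(
            (~emap.mask).sum())
        assert np.allclose(emap.masked_rho[emap.mask],
                           emap.rho[emap.mask])

    def test_planted_channels_flagged(self, rng):
        n_stimuli = 6
        sig = rng.standard_normal((n_stimuli, 200)) * 3.0
        epochs = _epochs_by_participant(rng, n_participants=6, n_stimuli=6,
                                        n_channels=8, signal=sig,
                                        signal_channels=(0, 1))
        ids = tuple(f"s{i}" for i in range(n_stimuli))
        layer_rdm = compute_rdm({ids[i]: sig[i] for i in range(n_stimuli)})
        trained = {4: RDM(layer_rdm.matrix, ids)}
        untrained = [{4: RDM(random_rdm(rng, 6).matrix, ids)}
                     for _ in range(2)]
        emap = electrode_rsa(epochs, 8, (0.0, 0.6), trained, untrained)
        assert emap.mask[0, 0] and emap.mask[1, 0]

    def test_too_few_participants_raises(self, rng):
        epochs = _epochs_by_participant(rng, n_participants=1)
        ids = tuple(f"s{i}" for i in range(5))
        trained = {4: RDM(random_rdm(rng, 5).matrix, ids)}
        with pytest.raises(ParameterError):
            electrode_rsa(epochs, 4, (0.0, 0.6), trained, [trained])


class TestRDMType:
    def test_symmetry_enforced(self):
        m = np.zeros((3, 3))
        m[0, 1] = 1.0
        with pytest.raises(ParameterError):
            RDM(m, ("a", "b", "c"))

    def test_diagonal_enforced(self):
        m = np.eye(3)
        with pytest.raises(ParameterError):
            RDM(m, ("a", "b", "c"))

    def test_shape_mismatch(self):
        with pytest.raises(AlignmentError):
            RDM(np.zeros((3, 3)), ("a", "b"))
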