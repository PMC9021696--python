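"""FastICA decomposition, component selection and channel-matching tests."""

import numpy as np
import pytest

from rcspe.containers import EpochWindow, TrialSet
from rcspe.errors import InvalidInputError
from rcspe.ica_matching import (
    ChannelCorrespondence,
    ComponentSelection,
    ICADecomposition,
    best_fnirs_decomposition,
    derive_correspondence,
    fastica_decompose,
    match_channels,
    rank_channels_by_weight,
    select_discriminative_components_eeg,
    select_task_components_fnirs,
    welch_psd,
)


def make_decomp(mixing, sources, fs=10.0, n_trials=1, names=None):
    mixing = np.asarray(mixing, dtype=float)
    sources = np.asarray(sources, dtype=float)
    n_ch = mixing.shape[0]
    return ICADecomposition(
        mixing=mixing,
        unmixing=np.linalg.pinv(mixing),
        sources=sources,
        mean=np.zeros(n_ch),
        channel_names=names or [f"ch{i}" for i in range(n_ch)],
        fs=fs,
        n_trials=n_trials,
        n_samples=sources.shape[1] // n_trials,
    )


class TestFastICA:
    def test_recovers_independent_sources(self, rng):
        n = 20000
        s_true = np.vstack([
            rng.uniform(-1, 1, n),
            rng.laplace(size=n),
        ])
        a = np.array([[1.0, 0.6], [0.4, 1.0]])
        x = (a @ s_true)[None, :, :]
        trials = TrialSet(x, 100.0, ["c1", "c2"])
        dec = fastica_decompose(trials, seed=0)
        # best |correlation| against truth up to permutation/sign
        cors = np.abs(np.corrcoef(np.vstack([dec.sources, s_true]))[:2, 2:])
        assert cors.max(axis=1).min() >= 0.95
        assert set(np.argmax(cors, axis=1)) == {0, 1}

    def test_seeded_and_deterministic(self, small_session):
        d1 = fastica_decompose(small_session.eeg, seed=4)
        d2 = fastica_decompose(small_session.eeg, seed=4)
        np.testing.assert_array_equal(d1.mixing, d2.mixing)

    def test_mixing_unmixing_inverse_on_subspace(self, small_session):
        dec = fastica_decompose(small_session.eeg, seed=1)
        prod = dec.unmixing @ dec.mixing
        np.testing.assert_allclose(prod, np.eye(dec.n_components), atol=1e-6)

    def test_sources_unit_variance_and_ev_ordering(self, small_session):
        dec = fastica_decompose(small_session.eeg, seed=1)
        np.testing.assert_allclose(dec.sources.var(axis=1), 1.0, rtol=1e-2)
        norms = np.linalg.norm(dec.mixing, axis=0)
        assert np.all(np.diff(norms) <= 1e-12)

    def test_too_few_samples_rejected(self):
        trials = TrialSet(np.random.default_rng(0).standard_normal((1, 8, 4)),
                          10.0, [f"c{i}" for i in range(8)])
        with pytest.raises(InvalidInputError):
            fastica_decompose(trials)


class TestWelchPsd:
    def test_white_noise_parseval(self, rng):
        x = rng.standard_normal(8192)
        freqs, psd = welch_psd(x, fs=100.0, segment_len=1024)
        integral = np.trapezoid(psd, freqs)
        assert integral == pytest.approx(x.var(), rel=0.05)

    def test_pure_tone_peak(self):
        t = np.arange(0, 20, 0.01)
        freqs, psd = welch_psd(np.sin(2 * np.pi * 10 * t), 100.0, 1000)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0, abs=0.2)

    def test_amplitude_ratio_squares_in_power(self):
        t = np.arange(0, 40, 0.01)
        x = 2 * np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 25 * t)
        freqs, psd = welch_psd(x, 100.0, 4000)
        p10 = psd[np.argmin(np.abs(freqs - 10))]
        p25 = psd[np.argmin(np.abs(freqs - 25))]
        assert p10 / p25 == pytest.approx(4.0, rel=0.1)

    def test_segment_too_long_rejected(self):
        with pytest.raises(InvalidInputError):
            welch_psd(np.zeros(10), 1.0, 20)


class TestEegSelection:
    def _session_decomp(self, rng, n_trials=40, n_samp=400, fs=100.0):
        """Hand-built decomposition: comp0 has class-dependent band power,
        comp1 weak dependence, comp2 none."""
        labels = np.repeat([1, 2], n_trials // 2)
        srcs = np.zeros((3, n_trials, n_samp))
        for i, lab in enumerate(labels):
            gain0 = 2.0 if lab == 1 else 0.5
            gain1 = 1.2 if lab == 1 else 0.8
            # broadband class-dependent gain: every band bin carries contrast
            srcs[0, i] = gain0 * rng.standard_normal(n_samp)
            srcs[1, i] = gain1 * rng.standard_normal(n_samp)
            srcs[2, i] = rng.standard_normal(n_samp)
        mixing = np.eye(3)
        dec = make_decomp(mixing, srcs.reshape(3, -1), fs=fs, n_trials=n_trials)
        return dec, labels

    def test_strongest_class_contrast_wins(self, rng):
        dec, labels = self._session_decomp(rng)
        sel = select_discriminative_components_eeg(dec, labels)
        assert sel.indices[0] == 0
        assert sel.scores[0] > sel.scores[2]

    def test_identical_class_spectra_score_near_zero(self, rng):
        dec, labels = self._session_decomp(rng)
        assert sel_score_zeroish(dec, labels)

    def test_single_class_rejected(self, rng):
        dec, labels = self._session_decomp(rng)
        with pytest.raises(InvalidInputError):
            select_discriminative_components_eeg(dec, np.ones_like(labels))

    def test_sign_flip_invariance(self, rng):
        dec, labels = self._session_decomp(rng)
        flipped = make_decomp(
            dec.mixing * np.array([-1, 1, -1]),
            dec.sources * np.array([[-1], [1], [-1]]),
            fs=dec.fs, n_trials=dec.n_trials,
        )
        s1 = select_discriminative_components_eeg(dec, labels)
        s2 = select_discriminative_components_eeg(flipped, labels)
        np.testing.assert_allclose(s1.scores, s2.scores, atol=1e-10)


def sel_score_zeroish(dec, labels):
    sel = select_discriminative_components_eeg(dec, labels)
    # comp2 is class-independent noise: tiny PSD distance
    return sel.scores[2] < 0.3 * sel.scores[0]


class TestFnirsSelection:
    def _decomp(self, rng, responsive=(0,), n_trials=30, n_samp=100, fs=10.0):
        srcs = np.zeros((3, n_trials, n_samp))
        resp = np.linspace(0, 1, n_samp)
        for i in range(n_trials):
            for j in range(3):
                base = 0.2 * rng.standard_normal(n_samp)
                srcs[j, i] = base + (resp if j in responsive else 0.0)
        return make_decomp(np.eye(3), srcs.reshape(3, -1), fs=fs,
                           n_trials=n_trials)

    def test_stationary_component_scores_low(self, rng):
        dec = self._decomp(rng, responsive=(0, 1))
        sel = select_task_components_fnirs(
            dec, EpochWindow(5, 10), EpochWindow(0, 2.5)
        )
        assert set(sel.indices) == {0, 1}
        assert sel.scores[2] < 0.2 * max(sel.scores[0], sel.scores[1])

    def test_overlapping_windows_rejected(self, rng):
        dec = self._decomp(rng)
        with pytest.raises(InvalidInputError):
            select_task_components_fnirs(
                dec, EpochWindow(2, 8), EpochWindow(0, 4)
            )

    def test_tie_breaks_to_lower_index(self):
        srcs = np.zeros((3, 2, 10))
        dec = make_decomp(np.eye(3), srcs.reshape(3, -1), fs=1.0, n_trials=2)
        sel = select_task_components_fnirs(
            dec, EpochWindow(5, 10), EpochWindow(0, 4)
        )
        assert sel.indices == (0, 1)


class TestRanking:
    def test_single_column_sort(self):
        mixing = np.array([[0.9, 0.9], [0.1, 0.1], [0.5, 0.5]])
        dec = make_decomp(mixing, np.zeros((2, 10)), names=["ch1", "ch2", "ch3"])
        sel = ComponentSelection(indices=(0, 1), scores=np.array([1.0, 0.5]))
        assert rank_channels_by_weight(dec, sel) == ["ch1", "ch3", "ch2"]

    def test_equal_weights_keep_original_order(self):
        mixing = np.ones((4, 2))
        dec = make_decomp(mixing, np.zeros((2, 10)))
        sel = ComponentSelection(indices=(0, 1), scores=np.array([1.0, 0.5]))
        assert rank_channels_by_weight(dec, sel) == ["ch0", "ch1", "ch2", "ch3"]

    def test_reproduces_reference_motor_ordering(self):
        """A mixing whose weights decrease along the published example order
        yields exactly that channel ranking."""
        order = ["FCC5h", "FCC6h", "CCP4h", "CCP5h", "FCC3h", "FCC4h",
                 "CCP6h", "CCP3h"]
        names = sorted(order)  # arbitrary storage order
        weights = {ch: 1.0 - 0.1 * i for i, ch in enumerate(order)}
        col = np.array([weights[ch] for ch in names])
        mixing = np.column_stack([col, col])
        dec = make_decomp(mixing, np.zeros((2, 10)), names=names)
        sel = ComponentSelection(indices=(0, 1), scores=np.array([1.0, 0.5]))
        assert rank_channels_by_weight(dec, sel) == order

    def test_channel_permutation_equivariance(self, rng):
        mixing = rng.standard_normal((5, 2))
        dec = make_decomp(mixing, np.zeros((2, 10)))
        sel = ComponentSelection(indices=(0, 1), scores=np.array([1.0, 0.5]))
        base = rank_channels_by_weight(dec, sel)
        perm = [3, 0, 4, 1, 2]
        dec_p = make_decomp(mixing[perm], np.zeros((2, 10)),
                            names=[dec.channel_names[i] for i in perm])
        assert rank_channels_by_weight(dec_p, sel) == base


class TestMatching:
    def test_identity_pairing(self):
        corr = match_channels(list("abc"), list("abc"))
        assert corr.pairs == (("a", "a"), ("b", "b"), ("c", "c"))

    def test_top_k_of_larger_modality(self):
        eeg = [f"e{i}" for i in range(8)]
        fnirs = [f"f{i}" for i in range(24)]
        corr = match_channels(eeg, fnirs, n_pairs=8)
        assert corr.n_pairs == 8
        assert corr.fnirs_channels == fnirs[:8]

    def test_n_pairs_too_large_rejected(self):
        with pytest.raises(InvalidInputError):
            match_channels(list("ab"), list("abc"), n_pairs=3)

    def test_empty_correspondence_refused_downstream(self, small_session):
        from rcspe.ensemble import fit_rcspe

        empty = ChannelCorrespondence(pairs=())
        with pytest.raises(InvalidInputError):
            fit_rcspe(small_session.fnirs_hbo, small_session.eeg, empty)


class TestGroundTruthRecovery:
    """Single-seed smoke of the full matching chain against generator truth
    (the multi-seed recovery statistics live in the acceptance suite)."""

    def test_selected_components_match_truth(self):
        from rcspe.synthetic import SimConfig, generate_session

        s = generate_session(SimConfig(seed=2, snr_eeg=10.0, snr_fnirs=10.0))
        dec, sel = best_fnirs_decomposition(s.fnirs_hbo, seed=2)
        truth = s.truth.mixing_fnirs[:, :2]
        cors = np.array([
            [abs(np.corrcoef(dec.mixing[:, ci], truth[:, j])[0, 1])
             for j in range(2)]
            for ci in sel.indices
        ])
        assert cors.max(axis=1).min() >= 0.9
        assert set(np.argmax(cors, axis=1)) == {0, 1}

    def test_derive_correspondence_shape(self):
        from rcspe.synthetic import SimConfig, generate_session

        s = generate_session(SimConfig(seed=2, n_trials_per_class=10,
                                       snr_eeg=10.0, snr_fnirs=5.0))
        corr = derive_correspondence(s.eeg, s.fnirs_hbo, labels=s.labels, seed=0)
        assert corr.n_pairs == 8
        assert len(set(corr.eeg_channels)) == 8
        assert len(set(corr.fnirs_channels)) == 8
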