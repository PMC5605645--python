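import numpy as np
import pytest

from conftest import small_sim_config
from hybridbci import hrf
from hybridbci import preprocess as pre
from hybridbci.features import (
    FeatureSet,
    eeg_features,
    fuse,
    initial_dip_features,
    minmax_normalize,
    pca_filter_epochs,
    pca_trial_filter,
)
from hybridbci.preprocess import HbEpochs, epoch, mbll
from hybridbci.select import ChannelSelection, SelectedPair
from hybridbci.synthetic import generate_session


def make_selection(left_ch=12, right_ch=29, left_el="FCC3h", right_el="FCC4h"):
    return ChannelSelection(
        left=SelectedPair(left_ch, -5.0, left_el),
        right=SelectedPair(right_ch, 5.0, right_el),
        alpha=0.05, dof=100)


@pytest.fixture(scope="module")
def run(default_run):
    return default_run


class TestEegFeatures:
    def test_dimension_contract(self, run):
        fs = eeg_features(run["eeg_epochs"], run["selection"])
        assert fs.F.shape == (50, 44)
        assert fs.modality == "EEG"

    def test_zero_epochs_zero_features(self, run):
        eps = run["eeg_epochs"]
        zero = pre.EpochSet(np.zeros_like(eps.data), eps.fs, eps.window_s,
                            eps.labels, eps.baseline_window_s, "EEG",
                            eps.channel_names)
        fs = eeg_features(zero, run["selection"])
        assert np.all(fs.F == 0)

    def test_order_equivariance(self, run, rng):
        eps = run["eeg_epochs"]
        perm = rng.permutation(eps.data.shape[0])
        shuffled = pre.EpochSet(eps.data[perm], eps.fs, eps.window_s,
                                eps.labels[perm], eps.baseline_window_s, "EEG",
                                eps.channel_names)
        a = eeg_features(eps, run["selection"])
        b = eeg_features(shuffled, run["selection"])
        np.testing.assert_allclose(b.F, a.F[perm], atol=1e-12)

    def test_missing_electrode_raises(self, run):
        sel = make_selection(left_el="XXX")
        with pytest.raises(KeyError, match="XXX"):
            eeg_features(run["eeg_epochs"], sel)


class TestPcaTrialFilter:
    def test_rank_one_identity(self, rng):
        w = rng.standard_normal(30)
        amps = rng.random(8) + 0.5
        X = np.outer(w, amps)
        recon, evr, _ = pca_trial_filter(X, R=1, return_info=True)
        np.testing.assert_allclose(recon, X, atol=1e-9)
        assert evr == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_error_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((20, 10))
        recon = pca_trial_filter(X, R=1)
        # oracle: full eigendecomposition of the trial covariance
        Xc = X - X.mean(axis=1, keepdims=True)
        cov = Xc @ Xc.T / (10 - 1)
        eigvals = np.linalg.eigvalsh(cov)[::-1]
        discarded = eigvals[1:].sum()
        err = ((X - recon) ** 2).sum()
        assert err == pytest.approx(discarded * (10 - 1), rel=1e-9)

    def test_full_rank_identity(self, rng):
        X = rng.standard_normal((12, 5))
        np.testing.assert_allclose(pca_trial_filter(X, R=5), X, atol=1e-9)

    def test_energy_conservation(self, rng):
        X = rng.standard_normal((15, 7))
        _, _, eigvals = pca_trial_filter(X, R=1, return_info=True)
        Xc = X - X.mean(axis=1, keepdims=True)
        total = (Xc ** 2).sum() / (7 - 1)
        assert eigvals.sum() == pytest.approx(total, rel=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            pca_trial_filter(np.zeros((10, 4)))

    def test_single_trial_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            pca_trial_filter(np.ones((10, 1)))


def hb_epochs_from_arrays(hbo, hbr, fs, labels, names):
    """Build an HbEpochs container directly from trial arrays."""
    def mk(data, modality):
        return pre.EpochSet(data, fs, (0.0, data.shape[1] / fs), labels,
                            (0.0, 0.0001), modality, names)
    return HbEpochs(hbo=mk(hbo, "HbO"), hbr=mk(hbr, "HbR"))


class TestInitialDipFeatures:
    fs = 7.81

    def _names(self):
        return [f"ch{c:02d}" for c in (12, 29)]

    def test_zero_epochs_zero_features(self):
        labels = np.array(["left", "right"] * 3, dtype=object)
        n = int(20 * self.fs)
        z = np.zeros((6, n, 2))
        eps = hb_epochs_from_arrays(z, z.copy(), self.fs, labels, self._names())
        sel = make_selection()
        fs_ = initial_dip_features(eps, sel)
        assert fs_.F.shape == (6, 4)
        assert np.all(fs_.F == 0)

    def test_ramp_mean_matches_direct_average_oracle(self):
        labels = np.array(["left", "right"], dtype=object)
        n = int(20 * self.fs)
        t = np.arange(n) / self.fs
        hbo = np.zeros((2, n, 2))
        ramp = np.where(t < 2.0, -t / 2.0, 0.0)  # 0 .. -1 µmol/L over [0,2)
        hbo[0, :, 0] = ramp
        eps = hb_epochs_from_arrays(hbo, np.zeros_like(hbo), self.fs, labels,
                                    self._names())
        feats = initial_dip_features(eps, sel := make_selection())
        oracle = ramp[:15].mean()  # floor(2 * 7.81) samples from t = 0
        assert feats.F[0, 0] == pytest.approx(oracle, abs=1e-12)
        assert sel.left.fnirs_channel == 12

    def test_feature_order(self):
        labels = np.array(["left", "right"], dtype=object)
        n = int(20 * self.fs)
        hbo = np.zeros((2, n, 2))
        hbr = np.zeros((2, n, 2))
        hbo[:, :, 0] = 1.0   # ch12 HbO
        hbr[:, :, 0] = 2.0   # ch12 HbR
        hbo[:, :, 1] = 3.0   # ch29 HbO
        hbr[:, :, 1] = 4.0   # ch29 HbR
        eps = hb_epochs_from_arrays(hbo, hbr, self.fs, labels, self._names())
        feats = initial_dip_features(eps, make_selection())
        np.testing.assert_allclose(feats.F[0], [1.0, 2.0, 3.0, 4.0])
        assert feats.feature_names == ["fnirsL_hbo_mean", "fnirsL_hbr_mean",
                                       "fnirsR_hbo_mean", "fnirsR_hbr_mean"]

    def test_dip_window_sample_count(self):
        labels = np.array(["left", "right"], dtype=object)
        n = int(25 * self.fs)
        hbo = np.zeros((2, n, 2))
        eps = hb_epochs_from_arrays(hbo, hbo.copy(), self.fs, labels, self._names())
        cropped = eps.hbo.crop(0.0, 2.0)
        assert cropped.data.shape[1] == 15  # floor(2 * 7.81)

    def test_full_size_dimension(self, default_run):
        filtered = pca_filter_epochs(default_run["hb_epochs"],
                                     default_run["selection"])
        feats = initial_dip_features(filtered, default_run["selection"])
        assert feats.F.shape == (50, 4)


class TestEndToEndDip:
    def test_noise_free_dip_mean_matches_analytic(self):
        """Planted dip recovered through MBLL inversion + epoching equals
        the analytic mean of the planted waveform over [0, 2) s."""
        cfg = small_sim_config(n_trials_per_class=1, rest_s=60.0, task_s=5.0,
                               post_s=16.0, eeg_noise=0.0, eeg_drift=0.0,
                               fnirs_noise=0.0, drift_amp=0.0, mayer_amp=0.0,
                               resp_amp=0.0, cardiac_amp=0.0,
                               motion_spike_rate=0.0, seed=2)
        s = generate_session(cfg)
        hb = mbll(s.fnirs_intensity[:, :, 0], s.fnirs_intensity[:, :, 1],
                  s.montage.sd_distance_cm, fs=cfg.fs_fnirs)
        eps = epoch(hb.hbo, cfg.fs_fnirs, s.events, (-5.0, 20.0), (-5.0, 0.0),
                    "HbO", [f"ch{c.id:02d}" for c in s.montage.fnirs_channels])
        hbe = HbEpochs(hbo=eps, hbr=eps)
        feats = initial_dip_features(hbe, make_selection())
        # analytic oracle: the planted waveform samples the crop selects.
        # Kernel sample m sits at absolute index round(onset*fs) + m; the
        # epoch grid starts at round((onset-5)*fs).
        fs = cfg.fs_fnirs
        k_hrf = hrf.hrf_kernel(fs, cfg.task_s)
        k_dip = hrf.dip_kernel(fs)
        nk = max(len(k_hrf), len(k_dip))
        wave = np.zeros(nk)
        wave[:len(k_hrf)] += cfg.hrf_peak_amp * k_hrf
        wave[:len(k_dip)] -= cfg.dip_amp * k_dip
        # left-hand trial activates the right-hemisphere channel (29)
        row = int(np.flatnonzero(s.events.labels == "left")[0])
        onset = s.events.onsets_s[row]
        epoch_t = -5.0 + np.arange(eps.data.shape[1]) / fs
        first = int(np.searchsorted(epoch_t, -1e-9))
        j = np.arange(first, first + 15)
        m = int(np.round((onset - 5.0) * fs)) + j - int(np.round(onset * fs))
        expected = wave[m].mean()
        assert feats.F[row, 2] == pytest.approx(expected, abs=1e-6)

    def test_dip_window_alignment(self):
        """Window sample times relative to onset fall in [0, 2)."""
        cfg = small_sim_config()
        s = generate_session(cfg)
        _, hbe = pre.preprocess_fnirs(s)
        t = hbe.hbo.crop(0.0, 2.0).times_s
        assert np.all((t >= -1e-9) & (t < 2.0))


class TestMinmaxNormalize:
    def test_affine_map(self):
        fs = FeatureSet(np.array([[0.0], [5.0], [10.0]]),
                        np.array(["left", "right", "left"], dtype=object), "EEG")
        out = minmax_normalize(fs)
        np.testing.assert_allclose(out.F[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        fs = FeatureSet(np.full((3, 2), 7.0),
                        np.array(["left", "right", "left"], dtype=object), "EEG")
        out = minmax_normalize(fs)
        assert np.all(out.F == 0)

    def test_bounds_property_random_columns(self, rng):
        for _ in range(20):
            F = rng.standard_normal((10, 3)) * rng.random() * 10
            fs = FeatureSet(F, np.array(["left", "right"] * 5, dtype=object), "EEG")
            out = minmax_normalize(fs)
            np.testing.assert_allclose(out.F.min(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(out.F.max(axis=0), 1.0, atol=1e-12)

    def test_idempotent_in_paper_mode(self, rng):
        F = rng.standard_normal((8, 4))
        fs = FeatureSet(F, np.array(["left", "right"] * 4, dtype=object), "EEG")
        once = minmax_normalize(fs)
        twice = minmax_normalize(once)
        np.testing.assert_allclose(once.F, twice.F, atol=1e-12)

    def test_fold_safe_clips_held_out(self):
        F = np.array([[0.0], [1.0], [2.0], [50.0]])
        fs = FeatureSet(F, np.array(["left", "right", "left", "right"],
                                    dtype=object), "EEG")
        out = minmax_normalize(fs, mode="fold_safe", train_idx=np.array([0, 1, 2]))
        assert out.F[3, 0] == 1.0  # clipped
        np.testing.assert_allclose(out.F[:3, 0], [0.0, 0.5, 1.0])


class TestFuse:
    def _sets(self, n=50):
        labels = np.array(["left", "right"] * (n // 2), dtype=object)
        rng = np.random.default_rng(0)
        eeg = FeatureSet(rng.random((n, 44)), labels, "EEG")
        fnirs = FeatureSet(rng.random((n, 4)), labels, "fNIRS")
        return eeg, fnirs

    def test_hybrid_dimension(self):
        eeg, fnirs = self._sets()
        hyb = fuse(eeg, fnirs)
        assert hyb.F.shape == (50, 48)
        assert hyb.modality == "hybrid"

    def test_layout_contract(self):
        eeg, fnirs = self._sets()
        hyb = fuse(eeg, fnirs)
        np.testing.assert_array_equal(hyb.F[:, 44], fnirs.F[:, 0])
        np.testing.assert_array_equal(hyb.F[:, :44], eeg.F)

    def test_empty_set_raises(self):
        eeg, _ = self._sets()
        empty = FeatureSet(np.empty((0, 4)), np.array([], dtype=object), "fNIRS")
        with pytest.raises(ValueError, match="empty"):
            fuse(eeg, empty)

    def test_label_mismatch_raises(self):
        eeg, fnirs = self._sets()
        fnirs.labels = fnirs.labels[::-1].copy()
        with pytest.raises(ValueError, match="label"):
            fuse(eeg, fnirs)


class TestPcaFilterEpochs:
    def test_paper_mode_uses_own_class(self, default_run):
        filtered = pca_filter_epochs(default_run["hb_epochs"],
                                     default_run["selection"])
        assert filtered.hbo.data.shape == default_run["hb_epochs"].hbo.data.shape

    def test_fold_safe_held_out_independent_of_label(self, default_run):
        """Held-out trial reconstruction must not change when its own label
        flips (no label leakage)."""
        hbe = default_run["hb_epochs"]
        sel = default_run["selection"]
        mask = np.ones(hbe.hbo.data.shape[0], dtype=bool)
        mask[0] = False
        a = pca_filter_epochs(hbe, sel, trial_mask=mask)
        flipped = pre.EpochSet(hbe.hbo.data.copy(), hbe.hbo.fs, hbe.hbo.window_s,
                               hbe.hbo.labels.copy(), hbe.hbo.baseline_window_s,
                               "HbO", hbe.hbo.channel_names)
        flipped.labels[0] = "left" if flipped.labels[0] == "right" else "right"
        hbe2 = HbEpochs(hbo=flipped,
                        hbr=pre.EpochSet(hbe.hbr.data.copy(), hbe.hbr.fs,
                                         hbe.hbr.window_s, flipped.labels,
                                         hbe.hbr.baseline_window_s, "HbR",
                                         hbe.hbr.channel_names))
        b = pca_filter_epochs(hbe2, sel, trial_mask=mask)
        ci = hbe.hbo.channel_names.index("ch12")
        np.testing.assert_allclose(a.hbo.data[0, :, ci], b.hbo.data[0, :, ci],
                                   atol=1e-9)
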