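"""Reconstruction metrics, Welch spectra and the mechanism comparison test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gatewave.evaluation import (
    BANDS,
    ReconReport,
    compare_band_power,
    compare_mechanisms,
    rmse,
    scalp_error_map,
    sign_test,
    spectral_report,
    welch_psd,
)
from gatewave.io import SegmentSet


def make_set(data, fs=160.0, labels=None):
    data = np.asarray(data, dtype=np.float64)
    if labels is None:
        labels = tuple(f"c{i}" for i in range(data.shape[1]))
    return SegmentSet(data=data, labels=labels, fs=fs)


class TestRmse:
    def test_identity_gives_zero_and_full_accuracy(self):
        s = make_set(np.random.default_rng(0).random((4, 3, 16)))
        rep = rmse(s, s)
        assert rep.overall_rmse == 0.0
        assert rep.accuracy_percent == 100.0

    def test_constant_offset_on_one_channel(self):
        orig = make_set(np.zeros((5, 2, 8)))
        recon = make_set(np.concatenate(
            [np.full((5, 1, 8), 0.5), np.zeros((5, 1, 8))], axis=1))
        rep = rmse(orig, recon, dv_labels=["c0"])
        assert rep.per_channel_rmse["c0"] == pytest.approx(0.5)
        assert rep.overall_rmse == pytest.approx(0.5)
        assert rep.accuracy_percent == pytest.approx(50.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((3, 4, 6)), rng.random((3, 4, 6))
        rep = rmse(make_set(a), make_set(b))
        for i, lab in enumerate(rep.per_channel_rmse):
            manual = np.sqrt(np.mean([(a[s, i, t] - b[s, i, t]) ** 2
                                      for s in range(3) for t in range(6)]))
            assert rep.per_channel_rmse[lab] == pytest.approx(manual)

    def test_accuracy_identity_holds(self):
        rng = np.random.default_rng(2)
        rep = rmse(make_set(rng.random((2, 3, 4))), make_set(rng.random((2, 3, 4))))
        assert rep.accuracy_percent + 100 * rep.overall_rmse == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse(make_set(np.zeros((2, 3, 4))), make_set(np.zeros((2, 3, 5))))


class TestWelch:
    def tone_set(self, freq, fs=160.0, amp=1.0, n_seg=8):
        t = np.arange(int(fs * 2)) / fs
        seg = amp * np.sin(2 * np.pi * freq * t)
        data = np.tile(seg, (n_seg, 1, 1))
        return make_set(data, fs=fs)

    def test_pure_tone_peak_location(self):
        f, pxx = welch_psd(self.tone_set(10.0), "c0")
        assert f[np.argmax(pxx)] == pytest.approx(10.0, abs=0.5)

    def test_power_scales_with_amplitude_squared(self):
        f1, p1 = welch_psd(self.tone_set(10.0, amp=1.0), "c0")
        f2, p2 = welch_psd(self.tone_set(10.0, amp=2.0), "c0")
        assert p2.max() == pytest.approx(4 * p1.max(), rel=1e-6)

    def test_white_noise_flatness_improves_with_segments(self):
        def cv(n_seg, seed):
            rng = np.random.default_rng(seed)
            s = make_set(rng.normal(size=(n_seg, 1, 320)))
            f, pxx = welch_psd(s, "c0")
            inner = pxx[1:-1]
            return inner.std() / inner.mean()

        assert cv(100, 3) < cv(5, 3)

    def test_total_power_matches_variance(self):
        """Parseval-style sanity: integrated PSD of unit-variance white noise
        is close to 1 with enough segments."""
        rng = np.random.default_rng(4)
        s = make_set(rng.normal(size=(60, 1, 320)))
        f, pxx = welch_psd(s, "c0")
        total = np.trapezoid(pxx, f)
        assert total == pytest.approx(1.0, rel=0.1)

    def test_segment_shorter_than_window_rejected(self):
        s = make_set(np.zeros((2, 1, 80)))  # 0.5 s at 160 Hz
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(s, "c0")


class TestSpectralReport:
    def noisy_pair(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(20, 3, 320))
        orig = make_set(base)
        recon = make_set(base + noise * rng.normal(size=base.shape))
        return orig, recon

    def test_identity_gives_unit_correlation_zero_nrmse(self):
        orig, recon = self.noisy_pair(noise=0.0)
        rep = spectral_report(orig, recon)
        assert all(r == pytest.approx(1.0) for r in rep.psd_correlation.values())
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rep.band_nrmse.values())

    def test_noise_degrades_correlation(self):
        orig, recon = self.noisy_pair(noise=0.8, seed=1)
        rep = spectral_report(orig, recon)
        assert all(r < 1.0 for r in rep.psd_correlation.values())
        assert all(v > 0 for v in rep.band_nrmse.values())

    def test_three_channel_hand_oracle(self):
        """r and nRMSE match a spreadsheet-style computation on the
        band-power tables the report itself exposes."""
        orig, recon = self.noisy_pair(noise=0.3, seed=2)
        rep = spectral_report(orig, recon)
        labels = list(rep.psd_correlation)
        for band in rep.bands:
            o = np.array([rep.band_power_original[l][band] for l in labels])
            r = np.array([rep.band_power_reconstructed[l][band] for l in labels])
            manual = np.sqrt(((r - o) ** 2).mean()) / o.mean()
            assert rep.band_nrmse[band] == pytest.approx(manual)
        # correlation recomputed from raw Welch output
        f, p_o = welch_psd(orig, labels[0])
        _, p_r = welch_psd(recon, labels[0])
        assert rep.psd_correlation[labels[0]] == pytest.approx(
            stats.pearsonr(p_o, p_r).statistic
        )

    def test_band_power_comparison_pvalues(self):
        orig, recon = self.noisy_pair(noise=0.3, seed=3)
        rep_a = spectral_report(orig, recon)
        rep_b = spectral_report(orig, recon)
        p_same = compare_band_power(rep_a, rep_b)
        assert all(p == 1.0 for p in p_same.values())


def report_with(value, seed=None, mechanism=""):
    return ReconReport(per_channel_rmse={"c0": value}, overall_rmse=value,
                       n_dv=1, dv_labels=("c0",), mechanism=mechanism,
                       run_seed=seed)


class TestCompareMechanisms:
    def test_identical_pairs_degenerate(self):
        pairs = [(report_with(0.05), report_with(0.05)) for _ in range(8)]
        out = compare_mechanisms(pairs)
        assert out["degenerate"] is True
        assert out["p_value"] is None

    def test_consistent_advantage_is_significant(self):
        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(20):
            b = 0.06 + 0.01 * rng.random()
            pairs.append((report_with(b - 0.01), report_with(b)))
        out = compare_mechanisms(pairs)
        assert out["p_value"] < 0.01
        assert out["wins_first"] == 20

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        pairs = [(report_with(0.05 + 0.02 * rng.random()),
                  report_with(0.05 + 0.02 * rng.random())) for _ in range(12)]
        fwd = compare_mechanisms(pairs)
        rev = compare_mechanisms([(b, a) for a, b in pairs])
        assert fwd["p_value"] == pytest.approx(rev["p_value"])
        assert fwd["mean_difference"] == pytest.approx(-rev["mean_difference"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            compare_mechanisms([(report_with(0.1), report_with(0.2))] * 5)

    @pytest.mark.parametrize("n", [8, 10, 12])
    def test_matches_exhaustive_sign_permutation(self, n):
        """The signed-rank p-value equals the exact null obtained by
        enumerating all 2^n sign assignments of the rank statistic."""
        rng = np.random.default_rng(100 + n)
        diffs = rng.normal(loc=-0.004, scale=0.01, size=n)
        while (diffs == 0).any():  # pragma: no cover - vanishing probability
            diffs = rng.normal(loc=-0.004, scale=0.01, size=n)
        pairs = [(report_with(0.05 + d), report_with(0.05)) for d in diffs]
        out = compare_mechanisms(pairs)

        ranks = stats.rankdata(np.abs(diffs))
        w_plus = ranks[diffs > 0].sum()
        null = []
        for signs in itertools.product([0, 1], repeat=n):
            null.append(sum(r for s, r in zip(signs, ranks) if s))
        null = np.array(null)
        w_min = min(w_plus, ranks.sum() - w_plus)
        p_exact = np.mean([
            min(w, ranks.sum() - w) <= w_min + 1e-12 for w in null
        ])
        assert out["p_value"] == pytest.approx(p_exact, rel=1e-9)


class TestSignTest:
    def test_all_negative_differences(self):
        p = sign_test(np.full(10, -0.01), alternative="less")
        assert p == pytest.approx(0.5 ** 10, rel=1e-9)

    def test_balanced_differences_not_significant(self):
        diffs = np.array([-0.01, 0.01] * 5)
        assert sign_test(diffs, alternative="less") > 0.3

    def test_zeros_excluded(self):
        assert sign_test(np.zeros(6)) == 1.0


class TestScalpMap:
    def test_uniform_errors_share_value(self, montage19):
        rep = ReconReport(
            per_channel_rmse={l: 0.07 for l in montage19.labels},
            overall_rmse=0.07, n_dv=19, dv_labels=tuple(montage19.labels))
        rows = scalp_error_map(rep, montage19)
        assert len(rows) == 19
        assert {r[3] for r in rows} == {0.07}

    def test_hot_channel_is_table_max(self, montage19):
        errs = {l: 0.05 for l in montage19.labels}
        errs["T8"] = 0.2
        rep = ReconReport(per_channel_rmse=errs, overall_rmse=0.06,
                          n_dv=19, dv_labels=tuple(montage19.labels))
        rows = scalp_error_map(rep, montage19)
        top = max(rows, key=lambda r: r[3])
        assert top[0] == "T8"
        assert (top[1], top[2]) == montage19.position("T8")

    def test_row_count_equals_dv_channels(self, montage19):
        rep = ReconReport(
            per_channel_rmse={l: 0.05 for l in montage19.labels},
            overall_rmse=0.05, n_dv=2, dv_labels=("Fp1", "Fp2"))
        assert len(scalp_error_map(rep, montage19)) == 2

    def test_unknown_label_rejected(self, montage19):
        from gatewave.montage import MontageError

        rep = ReconReport(per_channel_rmse={"FC3": 0.1}, overall_rmse=0.1,
                          n_dv=1, dv_labels=("FC3",))
        with pytest.raises(MontageError):
            scalp_error_map(rep, montage19)
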