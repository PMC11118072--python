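"""Windowing and the 26 time/frequency-domain features against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from myowrite import (
    EmgRecording,
    FeatureParams,
    FeatureSetSpec,
    build_feature_matrix,
    make_windows,
)
from myowrite.features import (
    FeatureError,
    ar_cc_features,
    ar_coefficients_batch,
    cepstral_from_ar,
    entropy_features,
    fd_features,
    fd_features_batch,
    fuzzy_entropy_batch,
    hist_batch,
    td_features,
    td_features_batch,
    weighted_permutation_entropy_batch,
    set_column_names,
)
from myowrite.synth import ActivationSegment

from .oracles import (
    oracle_ar_yule_walker,
    oracle_cepstrum_from_ar,
    oracle_fd,
    oracle_fuzzy_entropy,
    oracle_hist,
    oracle_td,
    oracle_wpe,
)


def _rec(data, fs=1000.0, label=3):
    return EmgRecording(subject_id="T", word_label=label, data=np.atleast_2d(data), fs=fs)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "seg_len,expected_starts",
        [(150, [0]), (300, [0, 75, 150]), (149, []), (225, [0, 75])],
    )
    def test_window_count_arithmetic(self, seg_len, expected_starts):
        rec = _rec(np.zeros(400))
        wins = make_windows(rec, [ActivationSegment(0, seg_len, 0)])
        assert [w.start_sample for w in wins] == expected_starts
        for w in wins:
            assert w.samples.shape == (1, 150)
            assert w.word_label == 3

    def test_windows_never_cross_segments(self):
        rec = _rec(np.zeros(1000))
        segs = [ActivationSegment(0, 300, 0), ActivationSegment(500, 800, 1)]
        wins = make_windows(rec, segs)
        assert [w.start_sample for w in wins] == [0, 75, 150, 500, 575, 650]

    def test_invalid_win_step(self):
        rec = _rec(np.zeros(400))
        with pytest.raises(ValueError):
            make_windows(rec, [], win=0.05, step=0.075)


class TestTimeDomainExamples:
    def test_hand_arithmetic(self):
        out = td_features([1.0, -1.0, 2.0, -2.0], eps=0.0)
        assert out["IEMG"] == 6.0
        assert out["MAV"] == 1.5
        assert out["WL"] == 9.0
        assert out["ZC"] == 3.0

    def test_constant_window_has_no_variation_features(self):
        out = td_features(np.full(64, 2.5), eps=0.01)
        for key in ("WL", "DAMV", "DASDV", "ZC", "WAMP", "SSC"):
            assert out[key] == 0.0

    def test_rms_of_two_samples(self):
        assert td_features([3.0, 4.0])["RMS"] == pytest.approx(np.sqrt(12.5))

    def test_window_shorter_than_two_rejected(self):
        with pytest.raises(FeatureError):
            td_features_batch(np.ones((1, 1)), eps=0.0)


class TestOracleEquivalence:
    """Every feature matches its independent direct-definition oracle."""

    def test_td_scalars(self, rng_windows):
        eps = 0.05
        batch = td_features_batch(rng_windows, eps)
        for i, x in enumerate(rng_windows):
            expected = oracle_td(x, eps)
            for name, val in expected.items():
                assert batch[name][i] == pytest.approx(val, rel=1e-9, abs=1e-12)

    def test_hist(self, rng_windows):
        batch = hist_batch(rng_windows)
        for i, x in enumerate(rng_windows):
            np.testing.assert_array_equal(batch[i], oracle_hist(x))

    def test_fuzzy_entropy(self, rng_windows):
        batch = fuzzy_entropy_batch(rng_windows[:10])
        for i, x in enumerate(rng_windows[:10]):
            assert batch[i] == pytest.approx(
                oracle_fuzzy_entropy(x), rel=1e-6, abs=1e-9
            )

    def test_weighted_permutation_entropy(self, rng_windows):
        batch = weighted_permutation_entropy_batch(rng_windows)
        for i, x in enumerate(rng_windows):
            assert batch[i] == pytest.approx(oracle_wpe(x), rel=1e-6, abs=1e-9)

    def test_ar_coefficients(self, rng_windows):
        batch = ar_coefficients_batch(rng_windows)
        for i, x in enumerate(rng_windows):
            np.testing.assert_allclose(
                batch[i], oracle_ar_yule_walker(x), rtol=1e-9, atol=1e-12
            )

    def test_ar_against_statsmodels(self, rng_windows):
        statsmodels = pytest.importorskip("statsmodels.regression.linear_model")
        for x in rng_windows[:10]:
            rho, _ = statsmodels.yule_walker(x, order=4, method="mle")
            np.testing.assert_allclose(
                ar_coefficients_batch(x[None, :])[0], -rho, rtol=1e-6
            )

    def test_cepstrum_against_fft_route(self, rng_windows):
        a = ar_coefficients_batch(rng_windows)
        cc = cepstral_from_ar(a)
        for i in range(len(a)):
            np.testing.assert_allclose(
                cc[i], oracle_cepstrum_from_ar(a[i]), rtol=1e-6, atol=1e-9
            )

    def test_fd_scalars(self, rng_windows):
        fs = 1000.0
        batch = fd_features_batch(rng_windows, fs)
        for i, x in enumerate(rng_windows):
            expected = oracle_fd(x, fs)
            for name, val in expected.items():
                assert batch[name][i] == pytest.approx(
                    val, rel=1e-9, abs=1e-12
                ), name


class TestFeatureProperties:
    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scale_equivariance(self, scale, seed):
        x = np.random.default_rng(seed).standard_normal((1, 150))
        eps = 0.05
        base = td_features_batch(x, eps)
        scaled = td_features_batch(scale * x, scale * eps)
        for name in ("MAV", "RMS", "WL", "DAMV", "DASDV", "IEMG"):
            assert scaled[name][0] == pytest.approx(scale * base[name][0], rel=1e-9)
        assert scaled["VAR"][0] == pytest.approx(scale**2 * base["VAR"][0], rel=1e-9)
        for name in ("ZC", "SSC", "WAMP", "MYOP"):
            assert scaled[name][0] == base[name][0]
        fd_base = fd_features_batch(x, 1000.0)
        fd_scaled = fd_features_batch(scale * x, 1000.0)
        for name in ("MNF", "MDF", "PKF", "FR", "PSR"):
            assert fd_scaled[name][0] == pytest.approx(fd_base[name][0], rel=1e-9)
        wpe = weighted_permutation_entropy_batch(np.vstack([x, scale * x]))
        assert wpe[1] == pytest.approx(wpe[0], rel=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=2**16),
           n=st.integers(min_value=16, max_value=300))
    def test_hist_counts_sum_to_window_length(self, seed, n):
        x = np.random.default_rng(seed).standard_normal((1, n))
        assert hist_batch(x).sum() == n

    def test_entropy_edge_cases(self):
        ramp = np.arange(150.0)
        assert weighted_permutation_entropy_batch(ramp[None, :])[0] == 0.0
        assert entropy_features(np.full(150, 3.3))["FuzEN"] == 0.0

    def test_wpe_near_one_for_iid_noise(self):
        """Monte-Carlo: mean normalized WPE of white noise exceeds 0.9."""
        rng = np.random.default_rng(77)
        vals = weighted_permutation_entropy_batch(rng.standard_normal((100, 150)))
        assert vals.mean() > 0.9

    def test_ar_consistency_on_ar1_process(self):
        rng = np.random.default_rng(8)
        x = np.zeros(5000)
        for t in range(1, 5000):
            x[t] = 0.5 * x[t - 1] + rng.standard_normal()
        a = ar_cc_features(x)["AR"]
        assert a[0] == pytest.approx(-0.5, abs=0.05)
        assert np.all(np.abs(a[1:]) < 0.05)

    def test_ar_white_noise_coefficients_near_zero(self):
        x = np.random.default_rng(9).standard_normal(5000)
        assert np.all(np.abs(ar_cc_features(x)["AR"]) < 0.05)

    def test_cepstrum_recursion_hand_case(self):
        assert cepstral_from_ar(np.array([-0.5, 0.0, 0.0, 0.0]))[0] == 0.5

    def test_ar_constant_window_rejected(self):
        with pytest.raises(FeatureError):
            ar_coefficients_batch(np.full((1, 150), 1.0))

    def test_fd_sinusoid_peak_and_mean_frequency(self):
        t = np.arange(150) / 1000.0
        out = fd_features(np.sin(2 * np.pi * 100 * t), fs=1000.0)
        bin_width = 1000.0 / 256
        assert abs(out["PKF"] - 100.0) <= bin_width
        assert abs(out["MNF"] - 100.0) < 2.0

    def test_fd_bandpassed_noise_mean_frequency_in_band(self):
        rng = np.random.default_rng(10)
        sos = signal.butter(4, (35, 450), btype="bandpass", fs=1000, output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(2000))[500:650]
        out = fd_features(x, fs=1000.0)
        assert 35.0 < out["MNF"] < 450.0
        assert out["VCF"] >= 0.0
        assert 0.0 <= out["MDF"] <= 500.0

    def test_fd_zero_window_rejected(self):
        with pytest.raises(FeatureError):
            fd_features(np.zeros(150), fs=1000.0)


class TestFeatureMatrix:
    @pytest.mark.parametrize(
        "set_name,width",
        [("Hudgins", 24), ("Du", 36), ("Phinyomark1", 60),
         ("Phinyomark2", 42), ("TDAR", 60), ("ALL", 246)],
    )
    def test_column_counts(self, set_name, width):
        spec = FeatureSetSpec.named(set_name)
        assert len(set_column_names(spec, 6)) == width

    def test_matrix_assembly_and_selection(self, small_recordings):
        recs = small_recordings[:2]
        segs = [r.truth_segments for r in recs]
        fm = build_feature_matrix(recs, segs, "ALL")
        assert fm.X.shape[1] == 246
        assert not fm.X.isna().any().any()
        assert len(fm.y) == fm.n_windows == len(fm.provenance)
        sub = fm.select("TDAR")
        assert sub.X.shape == (fm.n_windows, 60)
        np.testing.assert_array_equal(
            sub.X["MAV_ch1"].to_numpy(), fm.X["MAV_ch1"].to_numpy()
        )
        with pytest.raises(KeyError):
            sub.select("Phinyomark2")  # FuzEN etc. not in TDAR

    def test_matrix_reproducible(self, small_recordings):
        recs = small_recordings[:1]
        segs = [recs[0].truth_segments]
        a = build_feature_matrix(recs, segs, "Hudgins", FeatureParams(eps=0.01))
        b = build_feature_matrix(recs, segs, "Hudgins", FeatureParams(eps=0.01))
        assert a.X.equals(b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_empty_segments_give_empty_matrix_with_schema(self, small_recordings):
        fm = build_feature_matrix(small_recordings[:1], [[]], "Hudgins")
        assert fm.X.shape == (0, 24)
        assert list(fm.X.columns) == set_column_names(FeatureSetSpec.named("Hudgins"), 6)

    def test_mismatched_sampling_rates_rejected(self, small_recordings):
        other = EmgRecording(
            subject_id="T", word_label=1,
            data=np.zeros((6, 1000)), fs=2000.0,
        )
        with pytest.raises(FeatureError):
            build_feature_matrix(
                [small_recordings[0], other],
                [small_recordings[0].truth_segments, []],
                "Hudgins",
            )

    def test_io_roundtrip(self, tmp_path, small_recordings):
        recs = small_recordings[:1]
        fm = build_feature_matrix(recs, [recs[0].truth_segments], "Hudgins")
        out = tmp_path / "features.csv"
        fm.to_csv(out)
        fm.write_params(tmp_path / "features.params.txt")
        import pandas as pd

        back = pd.read_csv(out)
        assert len(back) == fm.n_windows
        assert "MAV_ch1" in back.columns and "label" in back.columns
        assert "eps_rms_factor=0.01" in (tmp_path / "features.params.txt").read_text()
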