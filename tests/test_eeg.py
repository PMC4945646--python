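"""GFP, Zscore, peak counting, group curves, Welch power and feature vectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import physioad.eeg as ee


# -- GFP ---------------------------------------------------------------------

def test_gfp_equipotential_is_zero():
    u = np.full((5, 100), 3.7)
    assert np.allclose(ee.global_field_power(u), 0.0)


def test_gfp_two_electrode_hand_value():
    u = np.array([[0.0], [2.0]])
    # ((0-2)^2 + (2-0)^2) / 2 = 4 -> sqrt = 2
    assert ee.global_field_power(u)[0] == pytest.approx(2.0)


def test_gfp_homogeneity(rng):
    u = rng.standard_normal((8, 50))
    assert np.allclose(ee.global_field_power(3.5 * u), 3.5 * ee.global_field_power(u))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    hnp.arrays(
        float,
        st.tuples(st.integers(2, 12), st.integers(1, 30)),
        elements=st.floats(-100, 100),
    )
)
def test_gfp_matches_pairwise_double_sum_oracle(u):
    """The fast identity form equals the literal double sum over electrode
    pairs, which in turn is sqrt(2*Ne) times the per-instant population SD."""
    got = ee.global_field_power(u)
    ne = u.shape[0]
    brute = np.empty(u.shape[1])
    for t in range(u.shape[1]):
        s = 0.0
        for i in range(ne):
            for j in range(ne):
                s += (u[i, t] - u[j, t]) ** 2
        brute[t] = np.sqrt(s / ne)
    assert np.allclose(got, brute, atol=1e-8)
    assert np.allclose(got, np.sqrt(2 * ne) * u.std(axis=0), atol=1e-8)


def test_gfp_single_electrode_rejected():
    with pytest.raises(ValueError):
        ee.global_field_power(np.ones((1, 10)))


# -- Zscore ------------------------------------------------------------------

def test_zscore_of_baseline_mean_is_zero(rng):
    base = rng.standard_normal(500) + 5
    stim = np.full(100, base.mean())
    assert np.allclose(ee.zscore_series(stim, base), 0.0)


def test_zscore_one_sd_above_is_one(rng):
    base = rng.standard_normal(500)
    stim = np.full(10, base.mean() + base.std())
    assert np.allclose(ee.zscore_series(stim, base), 1.0)


def test_zscore_scale_invariance(rng):
    base = rng.random(300) + 1
    stim = rng.random(80) + 1
    z1 = ee.zscore_series(stim, base)
    z2 = ee.zscore_series(7.3 * stim, 7.3 * base)
    assert np.allclose(z1, z2)


def test_zscore_zero_variance_baseline_raises():
    with pytest.raises(ValueError):
        ee.zscore_series(np.ones(10), np.ones(50))


# -- peaks and interest index ------------------------------------------------

def test_no_excursion_no_peaks():
    z = np.zeros(1000)
    assert ee.count_peaks(z) == (0, 0)


def test_peak_runs_and_brand_attribution():
    fs = 10.0
    z = np.zeros(200)
    # five excursions; apexes at samples 10, 50, 90, 130, 170 (t = apex/10)
    for apex in (10, 50, 90, 130, 170):
        z[apex - 2 : apex + 3] = [3.5, 4, 5, 4, 3.5]
    brand = [(0.8, 1.5), (12.5, 13.5)]  # catches apexes at t=1.0 and t=13.0
    assert ee.count_peaks(z, brand, threshold=3, fs=fs) == (5, 2)


def _brute_force_peaks(z, thr):
    runs = 0
    inside = False
    for v in z:
        if v >= thr and not inside:
            runs += 1
            inside = True
        elif v < thr:
            inside = False
    return runs


@settings(deadline=None, max_examples=50, derandomize=True)
@given(hnp.arrays(float, st.integers(1, 300), elements=st.floats(-5, 8)))
def test_peak_count_matches_run_length_oracle(z):
    total, _ = ee.count_peaks(z, threshold=3)
    assert total == _brute_force_peaks(z, 3)


def test_peak_count_monotone_in_threshold(rng):
    z = rng.standard_normal(5000) * 2
    counts = [ee.count_peaks(z, threshold=t)[0] for t in (1, 2, 3, 4)]
    assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize(
    "brand,total,expected", [(2, 5, 0.4), (0, 7, 0.0)]
)
def test_interest_index_values(brand, total, expected):
    assert ee.interest_index(brand, total) == pytest.approx(expected)


def test_interest_index_no_peaks_is_missing():
    assert np.isnan(ee.interest_index(0, 0))


# -- group curves ------------------------------------------------------------

def test_memorization_constant_gfp_gives_uniform_mi(rng):
    m = 400
    curves = ee.memorization_curves(
        {"a": np.full(m, 2.0), "b": np.full(m, 5.0)},
        {"a": True, "b": False},
        band="theta",
    )
    assert np.allclose(curves["remember"].raw, 1 / m)
    assert np.allclose(curves["forget"].raw, 1 / m)


def test_memorization_per_subject_normalisation(rng):
    gfps = {f"s{i}": rng.random(256) + 0.1 for i in range(4)}
    flags = {k: i % 2 == 0 for i, k in enumerate(gfps)}
    curves = ee.memorization_curves(gfps, flags, "alpha")
    # each group's raw curve is a mean of unit-sum series, so it sums to 1
    assert curves["remember"].raw.sum() == pytest.approx(1.0)
    assert curves["forget"].raw.sum() == pytest.approx(1.0)


def test_memorization_identical_subjects_equal_individual(rng):
    g = rng.random(300) + 0.5
    curves = ee.memorization_curves(
        {"a": g.copy(), "b": g.copy()}, {"a": True, "b": True}, "theta"
    )
    assert np.allclose(curves["remember"].raw, g / g.sum())
    assert curves["forget"] is None


def test_pleasantness_symmetric_inputs_zero(rng):
    g = {f"s{i}": rng.random(200) for i in range(3)}
    flags = {k: True for k in g}
    curves = ee.pleasantness_curves(g, g, flags, "alpha")
    assert np.allclose(curves["like"].raw, 0.0)


def test_pleasantness_swap_flips_sign(rng):
    left = {"a": rng.random(150)}
    right = {"a": rng.random(150)}
    flags = {"a": False}
    c1 = ee.pleasantness_curves(left, right, flags, "theta")["dislike"]
    c2 = ee.pleasantness_curves(right, left, flags, "theta")["dislike"]
    assert np.allclose(c1.raw, -c2.raw)


def test_pleasantness_constant_offset_preserved(rng):
    base = rng.random(300)
    curves = ee.pleasantness_curves(
        {"a": base}, {"a": base + 0.7}, {"a": True}, "alpha"
    )
    assert np.allclose(curves["like"].values, 0.7, atol=1e-6)


# -- Welch power -------------------------------------------------------------

def test_welch_alpha_sine_power_concentrated():
    fs = 256.0
    t = np.arange(0, 8, 1 / fs)
    x = np.sin(2 * np.pi * 10.0 * t)
    total = sum(ee.welch_band_power(x, b, fs) for b in ee.BAND_NAMES if b != "gamma")
    assert ee.welch_band_power(x, "alpha", fs) / total >= 0.90


def test_welch_white_noise_power_proportional_to_bandwidth(rng):
    x = rng.standard_normal(256 * 120)
    p_theta = ee.welch_band_power(x, "theta", 256.0)  # 4-7 Hz
    p_beta = ee.welch_band_power(x, "beta", 256.0)  # 13-24 Hz
    # integrated over inclusive 2-Hz bins: theta spans 2 bins, beta 6
    assert p_beta / p_theta == pytest.approx(3.0, rel=0.2)


def test_welch_zero_signal_zero_power():
    x = np.zeros(1024)
    assert all(ee.welch_band_power(x, b) == 0 for b in ee.BAND_NAMES)


def test_welch_window_is_half_second():
    f, _ = ee.welch_psd(np.random.default_rng(0).standard_normal(2560), 256.0)
    assert f[1] - f[0] == pytest.approx(256.0 / ee.WELCH_NPERSEG)


# -- brainrate ---------------------------------------------------------------

def test_brainrate_all_alpha_is_band_centre():
    psd = {"delta": 0.0, "theta": 0.0, "alpha": 4.2, "beta": 0.0}
    assert ee.brainrate(psd) == pytest.approx(10.0)


def test_brainrate_equal_power_two_bands():
    psd = {"delta": 1.0, "theta": 0.0, "alpha": 1.0, "beta": 0.0}
    assert ee.brainrate(psd) == pytest.approx((2.0 + 10.0) / 2)


def test_brainrate_within_band_centres(rng):
    psd = {b: float(rng.random()) for b in ("delta", "theta", "alpha", "beta")}
    assert 2.0 <= ee.brainrate(psd) <= 18.5


def test_brainrate_zero_power_raises():
    with pytest.raises(ValueError):
        ee.brainrate({"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0})


# -- feature vectors ---------------------------------------------------------

def test_feature_name_groups_have_canonical_sizes():
    names = ee.eeg_feature_names()
    assert len(names["gfp_zscore"]) == 18
    assert len(names["psd"]) == 72
    assert len(names["index"]) == 8
    all_names = names["gfp_zscore"] + names["psd"] + names["index"]
    assert len(all_names) == 98
    assert len(set(all_names)) == 98


def test_feature_vector_on_synthetic_subject(eeg_subject):
    from physioad.pipeline import extract_subject_features

    profile, bundle = eeg_subject.subjects[0]
    feats = extract_subject_features(bundle, profile.subject_id, signals=("eeg",))
    df = feats["eeg"]
    assert df.shape == (9, 98)
    names = ee.eeg_feature_names()
    assert set(df.columns) == set(names["gfp_zscore"] + names["psd"] + names["index"])
    # structural sanity: GFP and PSD entries are non-negative wherever defined
    gfp_cols = [c for c in df.columns if c.startswith("eeg_gfp_mean")]
    psd_cols = [c for c in df.columns if c.startswith("eeg_psd")]
    assert (df[gfp_cols] >= 0).all().all()
    assert (df[psd_cols] >= 0).all().all()
    # peak containment: brand peaks never exceed total peaks
    assert (df["peaks_brand_theta"] <= df["peaks_theta"]).all()
    assert (df["peaks_brand_beta_ext"] <= df["peaks_beta_ext"]).all()
    # interest indexes live in [0, 1] where defined
    for col in ("index_theta", "index_beta"):
        vals = df[col].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()


def test_log_zscore_guard():
    # a negative mean Zscore must yield a missing value, not an exception
    rng = np.random.default_rng(0)
    base = rng.random(512) + 1.0
    stim = np.full(256, base.mean() - 2 * base.std())
    z = ee.zscore_series(stim, base)
    assert z.mean() < 0
    val = float(np.log(z.mean())) if z.mean() > 0 else float("nan")
    assert np.isnan(val)
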