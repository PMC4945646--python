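"""Variant assembly, balancing, cross-validation, selection and the protocol."""

import warnings

import numpy as np
import pandas as pd
import pytest

import physioad.evaluation as ev
from physioad.eeg import eeg_feature_names
from physioad.hrv import HRV_FEATURE_NAMES
from physioad.peripheral import GSR_FEATURE_NAMES, RSP_FEATURE_NAMES

AD_LABELS = {
    "a1": "positive", "a2": "positive", "a3": "positive", "a4": "positive",
    "a5": "neutral", "a6": "neutral", "a7": "negative", "a8": "negative",
    "a9": "unlabeled",
}


def _table(columns, subjects, rng, informative=False):
    """Random feature frame indexed (subject, ad); optionally the first column
    separates the classes."""
    idx = pd.MultiIndex.from_product(
        [[f"s{i}" for i in range(subjects)], list(AD_LABELS)], names=["subject", "ad"]
    )
    X = pd.DataFrame(rng.standard_normal((len(idx), len(columns))), index=idx,
                     columns=columns)
    if informative:
        shift = {"positive": 4.0, "neutral": 0.0, "negative": -4.0, "unlabeled": 4.0}
        X.iloc[:, 0] += [shift[AD_LABELS[a]] for _, a in idx]
    return X


@pytest.fixture()
def fake_tables(rng):
    eeg_names = eeg_feature_names()
    eeg_cols = eeg_names["gfp_zscore"] + eeg_names["psd"] + eeg_names["index"]
    return {
        "gsr": _table(GSR_FEATURE_NAMES, 12, rng, informative=True),
        "hrv": _table(HRV_FEATURE_NAMES, 12, rng, informative=True),
        "rsp": _table(RSP_FEATURE_NAMES, 12, rng),
        "eeg": _table(eeg_cols, 12, rng),
    }


# -- assembly ----------------------------------------------------------------

@pytest.mark.parametrize(
    "variant,n_cols",
    [
        ("GSR", 10), ("RSP", 6), ("HRV", 56),
        ("EEG_GFP-ZSCORE", 18), ("EEG_PSD", 72), ("EEG_IND", 8), ("EEG_ALL", 98),
        ("GSR+HRV", 66), ("GSR+HRV+EEG_IND", 74), ("GSR+HRV+EEG_ALL", 164),
    ],
)
def test_variant_dimensionalities(fake_tables, variant, n_cols):
    t = ev.assemble(variant, fake_tables, AD_LABELS)
    assert t.n_features == n_cols
    assert "unlabeled" not in set(t.y)


def test_combination_intersects_instances(fake_tables):
    # one subject loses ECG: it must vanish from every HRV-bearing combination
    hrv = fake_tables["hrv"]
    fake_tables["hrv"] = hrv[hrv.index.get_level_values("subject") != "s3"]
    t = ev.assemble("GSR+HRV", fake_tables, AD_LABELS)
    assert "s3" not in t.X.index.get_level_values("subject")
    g = ev.assemble("GSR", fake_tables, AD_LABELS)
    assert "s3" in g.X.index.get_level_values("subject")


def test_column_order_deterministic(fake_tables):
    a = ev.assemble("GSR+HRV", fake_tables, AD_LABELS)
    b = ev.assemble("GSR+HRV", fake_tables, AD_LABELS)
    assert list(a.X.columns) == list(b.X.columns)


# -- standardisation ---------------------------------------------------------

def test_standardize_zero_mean_unit_variance(fake_tables):
    t = ev.assemble("GSR", fake_tables, AD_LABELS)
    z = ev.standardize(t)
    assert np.abs(z.X.mean()).max() < 1e-9
    assert np.abs(z.X.var(ddof=0) - 1).max() < 1e-9


def test_standardize_constant_column_warns(fake_tables):
    t = ev.assemble("GSR", fake_tables, AD_LABELS)
    t.X.iloc[:, 2] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        z = ev.standardize(t)
    assert (z.X.iloc[:, 2] == 0).all()


def test_standardize_idempotent(fake_tables):
    t = ev.assemble("RSP", fake_tables, AD_LABELS)
    once = ev.standardize(t)
    twice = ev.standardize(once)
    assert np.allclose(once.X, twice.X, atol=1e-9)


# -- SMOTE -------------------------------------------------------------------

def test_smote_balances_counts(fake_tables):
    t = ev.assemble("GSR", fake_tables, AD_LABELS)
    assert t.class_counts() == {"positive": 48, "neutral": 24, "negative": 24}
    b = ev.smote_balance(t, seed=1)
    assert set(b.class_counts().values()) == {48}


def test_smote_synthetic_points_are_convex_combinations(fake_tables):
    t = ev.assemble("GSR", fake_tables, AD_LABELS)
    b = ev.smote_balance(t, seed=3)
    new = b.X.loc[~b.X.index.isin(t.X.index)]
    labels = b.y.loc[new.index]
    for (row, cls) in zip(new.to_numpy(), labels):
        reals = t.X[t.y == cls].to_numpy()
        best = np.inf
        for i in range(len(reals)):
            d = reals - reals[i]
            norm2 = (d * d).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                u = ((row - reals[i]) @ d.T) / norm2
            u = np.clip(np.nan_to_num(u), 0, 1)
            resid = np.linalg.norm(reals[i] + u[:, None] * d - row, axis=1)
            best = min(best, resid.min())
        assert best < 1e-8


def test_smote_already_balanced_is_identity(rng):
    X = pd.DataFrame(rng.standard_normal((30, 4)))
    y = pd.Series(["a", "b", "c"] * 10)
    t = ev.FeatureTable(X, y)
    b = ev.smote_balance(t, seed=0)
    pd.testing.assert_frame_equal(b.X, t.X)


def test_smote_tiny_class_reduces_k(rng):
    X = pd.DataFrame(rng.standard_normal((23, 3)))
    y = pd.Series(["maj"] * 20 + ["min"] * 3)
    with pytest.warns(UserWarning, match="smaller than k"):
        b = ev.smote_balance(ev.FeatureTable(X, y), k=5, seed=0)
    assert b.class_counts() == {"maj": 20, "min": 20}


# -- cross-validation --------------------------------------------------------

def _balanced_table(rng, n_per_class=20, n_feat=5, separated=True):
    rows, labels = [], []
    shift = {"positive": 6.0, "neutral": 0.0, "negative": -6.0}
    for cls in ("positive", "neutral", "negative"):
        x = rng.standard_normal((n_per_class, n_feat))
        if separated:
            x[:, 0] += shift[cls]
        rows.append(x)
        labels += [cls] * n_per_class
    X = pd.DataFrame(np.vstack(rows))
    return ev.FeatureTable(X, pd.Series(labels))


def test_separable_classes_near_perfect(rng):
    res = ev.cross_validate(_balanced_table(rng), "RF", k=10, seed=0)
    assert res.average >= 95.0


def test_zero_rule_on_balanced_table(rng):
    res = ev.cross_validate(_balanced_table(rng), "ZeroRule", k=10, seed=0)
    per = sorted(res.per_class.values())
    assert per == [0.0, 0.0, 100.0]
    assert res.average == pytest.approx(100.0 / 3, abs=0.01)


def test_label_permutation_stays_at_chance(rng):
    t = _balanced_table(rng, n_per_class=30, separated=True)
    y_perm = pd.Series(rng.permutation(t.y.to_numpy()), index=t.y.index)
    res = ev.cross_validate(ev.FeatureTable(t.X, y_perm), "RF", k=10, seed=0)
    # 95% binomial band around 1/3 for n = 90
    half = 1.96 * np.sqrt((1 / 3) * (2 / 3) / 90) * 100
    assert abs(res.average - 100 / 3) < half + 5


def test_stratified_folds_balanced(rng):
    t = _balanced_table(rng, n_per_class=30)
    res = ev.cross_validate(t, "ZeroRule", k=10, seed=1)
    y = t.y.to_numpy()
    for fold in range(10):
        m = res.folds == fold
        counts = pd.Series(y[m]).value_counts()
        assert counts.max() - counts.min() <= 1


def test_too_few_instances_rejected(rng):
    t = _balanced_table(rng, n_per_class=5)
    with pytest.raises(ValueError):
        ev.cross_validate(t, "RF", k=10, seed=0)


def test_cv_deterministic_under_seed(rng):
    t = _balanced_table(rng)
    a = ev.cross_validate(t, "RF", k=5, seed=3)
    b = ev.cross_validate(t, "RF", k=5, seed=3)
    assert a.per_class == b.per_class


def test_all_cascades_and_baselines_buildable():
    for name in list(ev.CASCADES) + list(ev.BASELINES):
        est = ev.build_classifier(name, seed=0)
        assert hasattr(est, "fit")


# -- wrapper selection -------------------------------------------------------

def test_wrapper_finds_the_informative_feature(rng):
    t = _balanced_table(rng, n_per_class=15, n_feat=6)
    sel = ev.wrapper_select(t, "DecisionTable", seed=0)
    assert "0" in [str(c) for c in sel]
    assert len(sel) <= 3


def test_wrapper_deterministic(rng):
    t = _balanced_table(rng, n_per_class=15, n_feat=5)
    a = ev.wrapper_select(t, "DecisionTable", seed=2)
    b = ev.wrapper_select(t, "DecisionTable", seed=2)
    assert a == b


def test_attribute_selected_classifier_trains_on_subset(rng):
    t = _balanced_table(rng, n_per_class=15, n_feat=6)
    clf = ev.AttributeSelectedClassifier(base="DecisionTable", seed=0)
    clf.fit(t.X.to_numpy(), t.y.to_numpy())
    assert 0 in clf.support_
    pred = clf.predict(t.X.to_numpy())
    assert (pred == t.y.to_numpy()).mean() > 0.9


# -- holdout prediction ------------------------------------------------------

def test_holdout_vote_shares_sum_to_one(rng):
    t = _balanced_table(rng)
    model = ev.build_classifier("RF", 0)
    model.fit(t.X.to_numpy(), t.y.to_numpy())
    hold = ev.predict_holdout(model, t.X.iloc[:7])
    assert sum(hold.vote_shares.values()) == pytest.approx(1.0)
    assert hold.majority in ("positive", "neutral", "negative")


def test_holdout_single_instance_majority_is_its_prediction(rng):
    t = _balanced_table(rng)
    model = ev.build_classifier("RF", 0)
    model.fit(t.X.to_numpy(), t.y.to_numpy())
    hold = ev.predict_holdout(model, t.X.iloc[:1])
    assert hold.majority == hold.predictions.iloc[0]


# -- protocol ----------------------------------------------------------------

def test_protocol_rounds_and_holdout(rng):
    tables = {
        "gsr": _table(GSR_FEATURE_NAMES, 6, rng, informative=True),
        "hrv": _table(HRV_FEATURE_NAMES, 6, rng, informative=True),
        "rsp": _table(RSP_FEATURE_NAMES, 6, rng),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = ev.run_protocol(
            tables, AD_LABELS, round1_specs=("RF",), round3_specs=("RF",), seed=0,
            wrapper_base="DecisionTable",
        )
    assert set(rep.round1) == {"GSR", "HRV", "RSP"}
    assert "GSR" in rep.winners and "HRV" in rep.winners
    assert "RSP" not in rep.winners  # pure noise cannot clear 75%
    assert "GSR+HRV" in rep.round2
    assert set(rep.selected_attributes["GSR+HRV"]) <= set(
        GSR_FEATURE_NAMES + HRV_FEATURE_NAMES
    )
    # the unlabeled ad was generated with positive-class structure
    assert rep.holdout is not None
    assert rep.holdout.majority == "positive"
    doc = rep.to_json()
    assert '"winners"' in doc


def test_low_scoring_variant_excluded_from_round2(rng):
    tables = {
        "gsr": _table(GSR_FEATURE_NAMES, 14, rng, informative=True),
        "hrv": _table(HRV_FEATURE_NAMES, 14, rng, informative=False),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = ev.run_protocol(
            tables, AD_LABELS, round1_specs=("RF",), round3_specs=("RF",), seed=0,
            wrapper_base="DecisionTable",
        )
    assert "HRV" not in rep.winners
    assert rep.round2 == {}  # no GSR+HRV combination without both winners
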