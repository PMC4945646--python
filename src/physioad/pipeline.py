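"""End-to-end feature extraction: cohort of raw bundles -> per-signal tables.

Each table is a DataFrame indexed by (subject, ad) whose columns are the
named features of one signal family: GSR (10), RSP (6), HRV (56) and EEG
(98 = 18 GFP/Zscore + 72 PSD + 8 index features).  Subjects missing a
modality simply contribute no rows to that family's table; dataset variants
later intersect instances across families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import eeg as eegm
from . import hrv as hrvm
from . import peripheral as per
from .preprocess import (
    GSR_ELEMENT_S,
    RSP_ELEMENT_S,
    clean_eeg,
    morphological_filter,
    preprocess_ecg,
)
from .synthetic import Cohort, SignalBundle

__all__ = [
    "extract_subject_features",
    "extract_cohort_features",
]


def _ad_segments(timeline):
    for b in timeline.ad_blocks:
        yield b.ad_id, b.onset, b.end


def _gsr_rows(bundle: SignalBundle) -> dict[str, dict[str, float]]:
    fs = bundle.fs_aux
    smooth = morphological_filter(bundle.gsr, GSR_ELEMENT_S, fs)
    rows = {}
    for ad_id, t0, t1 in _ad_segments(bundle.timeline):
        rows[ad_id] = per.gsr_features(bundle.segment(smooth, fs, t0, t1), fs)
    return rows


def _rsp_rows(bundle: SignalBundle) -> dict[str, dict[str, float]]:
    fs = bundle.fs_aux
    smooth = morphological_filter(bundle.rsp, RSP_ELEMENT_S, fs)
    rows = {}
    for ad_id, t0, t1 in _ad_segments(bundle.timeline):
        rows[ad_id] = per.rsp_features(bundle.segment(smooth, fs, t0, t1), fs)
    return rows


def _hrv_rows(bundle: SignalBundle) -> dict[str, dict[str, float]]:
    fs = bundle.fs_ecg
    clean = preprocess_ecg(bundle.ecg, fs)
    peaks = hrvm.detect_r_peaks(clean, fs)
    tach = hrvm.build_tachogram(peaks)
    rows = {}
    for ad_id, t0, t1 in _ad_segments(bundle.timeline):
        sub = tach.slice(t0, t1)
        rows[ad_id] = hrvm.hrv_feature_vector(sub).to_dict()
    return rows


def _eeg_rows(bundle: SignalBundle, seed: int) -> dict[str, dict[str, float]]:
    fs = bundle.fs_eeg
    cleaned, _qc = clean_eeg(bundle.eeg, fs, bundle.channels, seed=seed)
    from .montage import FRONTAL, indices_of

    frontal = cleaned[indices_of(FRONTAL, bundle.channels)]
    band_filtered = {b: eegm.band_filter(frontal, b, fs) for b in eegm.BAND_NAMES}
    rows = {}
    for ad_id, _t0, _t1 in _ad_segments(bundle.timeline):
        rows[ad_id] = eegm.eeg_feature_vectors(
            cleaned, bundle.timeline, ad_id, fs, bundle.channels, band_filtered
        )
    return rows


def extract_subject_features(
    bundle: SignalBundle, subject_id: str, signals=("eeg", "hrv", "gsr", "rsp"), seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Feature rows for every ad of one subject, per requested signal family."""
    out: dict[str, pd.DataFrame] = {}
    dispatch = {
        "gsr": (bundle.gsr, _gsr_rows),
        "rsp": (bundle.rsp, _rsp_rows),
        "hrv": (bundle.ecg, _hrv_rows),
        "eeg": (bundle.eeg, lambda b: _eeg_rows(b, seed)),
    }
    for name in signals:
        trace, fn = dispatch[name]
        if trace is None:
            continue
        rows = fn(bundle)
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = pd.MultiIndex.from_product(
            [[subject_id], df.index], names=["subject", "ad"]
        )
        out[name] = df
    return out


def extract_cohort_features(
    cohort: Cohort, signals=("eeg", "hrv", "gsr", "rsp"), seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Concatenate per-subject feature rows into one table per signal family."""
    parts: dict[str, list[pd.DataFrame]] = {s: [] for s in signals}
    for profile, bundle in cohort.subjects:
        subj = extract_subject_features(bundle, profile.subject_id, signals, seed=seed)
        for s, df in subj.items():
            parts[s].append(df)
    return {s: pd.concat(dfs) for s, dfs in parts.items() if dfs}
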