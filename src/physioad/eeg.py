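"""EEG-derived quantities: GFP, baseline Zscore, peak-based interest features,
memorization/pleasantness group curves, Welch band power and the canonical
per-instance feature vectors.

Global Field Power here follows the pairwise form

    GFP(t) = sqrt( sum_i sum_j (u_i(t) - u_j(t))^2 / N_e )

which differs from the classical cross-electrode standard deviation only by a
constant factor of ``sqrt(2 * N_e)``; the baseline Zscore is invariant to that
factor.  The Zscore standardises stimulus-period GFP by the mean and SD of GFP
over the two minutes of documentary preceding the ad's block, and a "peak" is
a maximal contiguous excursion of the Zscore at or above threshold (default
3, the p < 0.05 point of a fitted Gaussian), counted once and attributed to a
brand window when its apex falls inside one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import make_smoothing_spline

from .montage import CHANNELS, FRONTAL, indices_of

__all__ = [
    "BANDS",
    "BAND_NAMES",
    "WELCH_NPERSEG",
    "band_filter",
    "global_field_power",
    "zscore_series",
    "count_peaks",
    "interest_index",
    "GroupCurve",
    "memorization_curves",
    "pleasantness_curves",
    "welch_psd",
    "welch_band_power",
    "brainrate",
    "eeg_feature_names",
    "eeg_feature_vectors",
]

#: EEG rhythm bands (Hz).  The gamma band is nominally 25-100 Hz but its
#: effective upper edge is the 40 Hz preprocessing low-pass.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 24.0),
    "beta_ext": (25.0, 40.0),
    "gamma": (25.0, 100.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Welch periodogram window: 128 samples = half a second at 256 Hz, 50% overlap
WELCH_NPERSEG = 128

PEAK_THRESHOLD = 3.0


def band_filter(x: np.ndarray, band: str, fs: float = 256.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass into one of the canonical bands."""
    lo, hi = BANDS[band]
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, float), axis=-1)


def global_field_power(eeg: np.ndarray, electrodes: Sequence[int] | None = None) -> np.ndarray:
    """Instantaneous GFP over an electrode subset (default: all rows given).

    Computed through the algebraic identity
    ``sum_ij (u_i - u_j)^2 = 2 N_e * sum_i (u_i - mean)^2`` so it runs in
    O(N_e) per sample instead of O(N_e^2).
    """
    u = np.asarray(eeg, float)
    if electrodes is not None:
        u = u[np.asarray(electrodes)]
    if u.ndim != 2 or u.shape[0] < 2:
        raise ValueError("need >= 2 electrodes (channels x samples)")
    dev = u - u.mean(axis=0, keepdims=True)
    return np.sqrt(2.0 * np.sum(dev * dev, axis=0))


def zscore_series(gfp_stimulus: np.ndarray, gfp_baseline: np.ndarray) -> np.ndarray:
    """Pointwise (GFP - mean(baseline)) / sd(baseline)."""
    base = np.asarray(gfp_baseline, float)
    sd = base.std()
    if sd == 0:
        raise ValueError("baseline GFP has zero variance")
    return (np.asarray(gfp_stimulus, float) - base.mean()) / sd


def count_peaks(
    zscore: np.ndarray,
    brand_windows: Sequence[tuple[float, float]] = (),
    threshold: float = PEAK_THRESHOLD,
    fs: float = 256.0,
    t0: float = 0.0,
) -> tuple[int, int]:
    """(PN_total, PN_brand): maximal contiguous supra-threshold excursions,
    and those whose apex time falls inside a brand window."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(zscore, float)
    above = z >= threshold
    if not above.any():
        return 0, 0
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.r_[0 if above[0] else [], edges[~above[edges]] + 1].astype(int)
    stops = np.r_[edges[above[edges]] + 1, len(z) if above[-1] else []].astype(int)
    total = len(starts)
    brand = 0
    for a, b in zip(starts, stops):
        apex_t = t0 + (a + int(np.argmax(z[a:b]))) / fs
        if any(lo <= apex_t < hi for lo, hi in brand_windows):
            brand += 1
    return total, brand


def interest_index(pn_brand: int, pn_total: int) -> float:
    """Fraction of supra-threshold peaks inside brand windows; nan when the
    ad produced no peaks at all."""
    if pn_brand < 0 or pn_total < 0 or pn_brand > pn_total:
        raise ValueError("need 0 <= PN_brand <= PN_total")
    if pn_total == 0:
        return float("nan")
    return pn_brand / pn_total


# ---------------------------------------------------------------------------
# group-level curves
# ---------------------------------------------------------------------------

@dataclass
class GroupCurve:
    """A smoothed group-average envelope over stimulus time."""

    band: str
    group: str
    time: np.ndarray
    values: np.ndarray
    raw: np.ndarray


def _smooth(time: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cubic smoothing spline, smoothing parameter chosen by GCV."""
    if len(y) < 4 or np.allclose(y, y[0]):
        return np.asarray(y, float)
    spl = make_smoothing_spline(time, y)
    return spl(time)


def memorization_curves(
    per_subject_gfp: Mapping[str, np.ndarray],
    remember_flags: Mapping[str, bool],
    band: str,
    fs: float = 256.0,
) -> dict[str, Optional[GroupCurve]]:
    """Remember/forget group curves of the per-subject normalised GFP.

    Each subject's stimulus GFP is normalised to sum to one over the stimulus
    before group averaging, so the curve reflects the temporal distribution
    of activity rather than its absolute level.
    """
    if band not in ("theta", "alpha"):
        raise ValueError("memorization curves are defined for theta and alpha")
    groups: dict[str, list[np.ndarray]] = {"remember": [], "forget": []}
    for subj, gfp in per_subject_gfp.items():
        g = np.asarray(gfp, float)
        tot = g.sum()
        if tot <= 0:
            continue
        groups["remember" if remember_flags[subj] else "forget"].append(g / tot)
    out: dict[str, Optional[GroupCurve]] = {}
    for name, members in groups.items():
        if not members:
            out[name] = None
            continue
        raw = np.mean(members, axis=0)
        time = np.arange(len(raw)) / fs
        out[name] = GroupCurve(band, name, time, _smooth(time, raw), raw)
    return out


def pleasantness_curves(
    per_subject_gfp_left: Mapping[str, np.ndarray],
    per_subject_gfp_right: Mapping[str, np.ndarray],
    like_flags: Mapping[str, bool],
    band: str,
    fs: float = 256.0,
) -> dict[str, Optional[GroupCurve]]:
    """Like/dislike right-minus-left frontal asymmetry curves."""
    if band not in ("theta", "alpha"):
        raise ValueError("pleasantness curves are defined for theta and alpha")
    groups: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {"like": [], "dislike": []}
    for subj in per_subject_gfp_left:
        pair = (
            np.asarray(per_subject_gfp_left[subj], float),
            np.asarray(per_subject_gfp_right[subj], float),
        )
        groups["like" if like_flags[subj] else "dislike"].append(pair)
    out: dict[str, Optional[GroupCurve]] = {}
    for name, members in groups.items():
        if not members:
            out[name] = None
            continue
        left = np.mean([m[0] for m in members], axis=0)
        right = np.mean([m[1] for m in members], axis=0)
        raw = right - left
        time = np.arange(len(raw)) / fs
        out[name] = GroupCurve(band, name, time, _smooth(time, raw), raw)
    return out


# ---------------------------------------------------------------------------
# spectral power
# ---------------------------------------------------------------------------

def welch_psd(x: np.ndarray, fs: float = 256.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with 128-sample rectangular windows and 50% overlap.

    The periodogram of each window is the plain ``|FFT|^2 / N`` form, i.e. an
    unweighted (boxcar) taper, averaged across windows.
    """
    x = np.asarray(x, float)
    if x.shape[-1] < WELCH_NPERSEG:
        raise ValueError(f"signal shorter than one {WELCH_NPERSEG}-sample window")
    return sps.welch(
        x,
        fs=fs,
        window="boxcar",
        nperseg=WELCH_NPERSEG,
        noverlap=WELCH_NPERSEG // 2,
        detrend="constant",
        scaling="density",
        axis=-1,
    )


def _integrate_band(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        return np.zeros(psd.shape[:-1])
    df = f[1] - f[0]
    return psd[..., mask].sum(axis=-1) * df


def welch_band_power(x: np.ndarray, band: str, fs: float = 256.0) -> float:
    """Mean Welch power of *x* integrated over one canonical band."""
    f, psd = welch_psd(x, fs)
    lo, hi = BANDS[band]
    return float(_integrate_band(f, psd, lo, hi))


def brainrate(psd_by_band: Mapping[str, float]) -> float:
    """Power-weighted mean of band-centre frequencies (delta..beta).

    An optional spectral-centroid summary; not part of the canonical
    feature vectors.
    """
    names = [b for b in ("delta", "theta", "alpha", "beta") if b in psd_by_band]
    powers = np.array([psd_by_band[b] for b in names], float)
    centers = np.array([(BANDS[b][0] + BANDS[b][1]) / 2 for b in names])
    tot = powers.sum()
    if tot <= 0:
        raise ValueError("zero total power")
    return float((powers * centers).sum() / tot)


# ---------------------------------------------------------------------------
# per-instance feature vectors
# ---------------------------------------------------------------------------

INDEX_FEATURES: tuple[str, ...] = (
    "mean_theta",
    "mean_alpha",
    "index_theta",
    "index_beta",
    "peaks_theta",
    "peaks_brand_theta",
    "peaks_beta_ext",
    "peaks_brand_beta_ext",
)


def eeg_feature_names() -> dict[str, list[str]]:
    """Column names of the three EEG feature families (18 + 72 + 8 = 98)."""
    gfp_z = [f"eeg_{kind}_{b}" for kind in ("gfp_mean", "zscore_mean", "log_zscore") for b in BAND_NAMES]
    psd = [f"eeg_psd_{b}_{ch}" for b in BAND_NAMES for ch in FRONTAL]
    return {"gfp_zscore": gfp_z, "psd": psd, "index": list(INDEX_FEATURES)}


def eeg_feature_vectors(
    eeg_clean: np.ndarray,
    timeline,
    ad_id: str,
    fs: float = 256.0,
    channels: tuple[str, ...] = CHANNELS,
    band_filtered: Mapping[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """All 98 EEG features for one (subject, ad) instance.

    ``band_filtered`` may carry pre-computed band-filtered copies of the
    frontal electrode rows (in FRONTAL order, keyed by band name) so that
    callers iterating over the nine ads of a session filter each band once
    instead of nine times.
    """
    ad = timeline.block_for_ad(ad_id)
    b0, b1 = timeline.baseline_interval(ad_id)
    fr = indices_of(FRONTAL, channels)
    eeg_fr = np.asarray(eeg_clean, float)[fr]

    def seg(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        return x[..., int(round(lo * fs)) : int(round(hi * fs))]

    feats: dict[str, float] = {}
    z_by_band: dict[str, np.ndarray] = {}
    for band in BAND_NAMES:
        xb = band_filtered[band] if band_filtered is not None else band_filter(eeg_fr, band, fs)
        gfp_stim = global_field_power(seg(xb, ad.onset, ad.end))
        gfp_base = global_field_power(seg(xb, b0, b1))
        z = zscore_series(gfp_stim, gfp_base)
        z_by_band[band] = z
        mean_z = float(z.mean())
        feats[f"eeg_gfp_mean_{band}"] = float(gfp_stim.mean())
        feats[f"eeg_zscore_mean_{band}"] = mean_z
        feats[f"eeg_log_zscore_{band}"] = float(np.log(mean_z)) if mean_z > 0 else float("nan")

    # Welch band powers per frontal electrode: one PSD per channel, six bands
    f, psd = welch_psd(seg(eeg_fr, ad.onset, ad.end), fs)
    for bi, band in enumerate(BAND_NAMES):
        lo, hi = BANDS[band]
        powers = _integrate_band(f, psd, lo, hi)
        for ci, ch in enumerate(FRONTAL):
            feats[f"eeg_psd_{band}_{ch}"] = float(powers[ci])

    # peak-based index features
    bw = ad.brand_windows
    for band, tag in (("theta", "theta"), ("beta_ext", "beta_ext")):
        total, brand = count_peaks(z_by_band[band], bw, PEAK_THRESHOLD, fs, t0=ad.onset)
        feats[f"peaks_{tag}"] = float(total)
        feats[f"peaks_brand_{tag}"] = float(brand)
    for band, name in (("theta", "index_theta"), ("beta", "index_beta")):
        total, brand = count_peaks(z_by_band[band], bw, PEAK_THRESHOLD, fs, t0=ad.onset)
        feats[name] = interest_index(brand, total)
    feats["mean_theta"] = float(z_by_band["theta"].mean())
    feats["mean_alpha"] = float(z_by_band["alpha"].mean())
    return feats
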