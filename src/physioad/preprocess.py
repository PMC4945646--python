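"""Raw-trace cleaning: EEG QC/filtering/ICA, ECG filtering, morphological smoothing.

The EEG chain is: mean subtraction and 0.5-40 Hz band-pass; channel QC by
kurtosis outliers and flatness with spatial interpolation of rejected
channels; segmentation into 1-s epochs with kurtosis-based epoch rejection;
ICA with automatic blink-component scoring and removal.  ECG gets a
linear-phase FIR high-pass (0.5 Hz), a 50 Hz notch and a 65 Hz low-pass.
GSR and respiration are smoothed by grayscale morphological opening+closing,
which flattens ripple narrower than the structuring element while leaving
the location of wider peaks untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps
from scipy import stats

from .montage import CHANNELS, channel_positions, frontal_indices

__all__ = [
    "kurtosis",
    "ChannelQCReport",
    "detect_bad_channels",
    "interpolate_channels",
    "filter_eeg",
    "EpochedEEG",
    "epoch_and_reject",
    "ComponentDecomposition",
    "reject_artifact_components",
    "clean_eeg",
    "preprocess_ecg",
    "morphological_filter",
]

EEG_BAND = (0.5, 40.0)

#: morphological structuring-element widths, shorter than the narrowest
#: physiological event each signal carries
GSR_ELEMENT_S = 0.5
RSP_ELEMENT_S = 0.25


def kurtosis(x: np.ndarray) -> float:
    """Fourth standardised moment K = mu4 / sigma^4 (non-excess).

    Returns ``nan`` for zero-variance input — a degenerate channel is a QC
    signal, not an exception.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if np.std(x) == 0:
        return float("nan")
    return float(stats.kurtosis(x, fisher=False, bias=True))


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0 or not np.isfinite(scale):
        return np.zeros_like(values)
    return (values - med) / scale


def _flat_fraction(x: np.ndarray) -> float:
    """Fraction of samples whose first difference is negligible relative to IQR."""
    d = np.abs(np.diff(x))
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    tol = 1e-6 * iqr if iqr > 0 else 1e-12
    return float(np.mean(d < tol))


@dataclass
class ChannelQCReport:
    channels: tuple[str, ...]
    kurtosis: np.ndarray
    flat_fraction: np.ndarray
    rejected: list[int]

    @property
    def rejected_names(self) -> list[str]:
        return [self.channels[i] for i in self.rejected]

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "kurtosis": [None if not np.isfinite(k) else float(k) for k in self.kurtosis],
            "flat_fraction": self.flat_fraction.tolist(),
            "rejected": self.rejected_names,
        }


def detect_bad_channels(
    eeg: np.ndarray,
    kurtosis_z_threshold: float = 3.0,
    flat_fraction_threshold: float = 0.10,
    channels: tuple[str, ...] = CHANNELS,
) -> ChannelQCReport:
    """Flag channels whose kurtosis is an outlier across the montage or that
    are flat for more than 10% of the recording.

    The outlier score is a plain z across channels: with long recordings the
    sampling spread of per-channel kurtosis is tiny, so a MAD-based scale
    would flag the mild, shared elevation that ordinary frontal blink
    contamination produces, which is ICA's job to remove, not QC's.
    """
    eeg = np.asarray(eeg)
    if eeg.ndim != 2 or eeg.shape[0] < 2:
        raise ValueError("need a channels x samples array with >= 2 channels")
    ks = np.array([kurtosis(ch) for ch in eeg])
    flat = np.array([_flat_fraction(ch) for ch in eeg])
    finite = np.isfinite(ks)
    z = np.zeros_like(ks)
    if finite.sum() >= 2 and ks[finite].std() > 0:
        z[finite] = (ks[finite] - ks[finite].mean()) / ks[finite].std()
    rejected = [
        i
        for i in range(eeg.shape[0])
        if (not np.isfinite(ks[i]))
        or abs(z[i]) > kurtosis_z_threshold
        or flat[i] > flat_fraction_threshold
    ]
    return ChannelQCReport(tuple(channels[: eeg.shape[0]]), ks, flat, rejected)


def interpolate_channels(
    eeg: np.ndarray,
    report: ChannelQCReport,
    k: int = 4,
) -> np.ndarray:
    """Replace rejected channels by the inverse-distance-weighted mean of
    their k nearest good electrodes (standard 10-20 positions)."""
    if not report.rejected:
        return eeg
    good = [i for i in range(eeg.shape[0]) if i not in set(report.rejected)]
    if not good:
        raise ValueError("all channels rejected; nothing to interpolate from")
    pos = channel_positions()
    coords = np.array([pos[ch] for ch in report.channels])
    out = np.array(eeg, dtype=eeg.dtype, copy=True)
    for i in report.rejected:
        d = np.linalg.norm(coords[good] - coords[i], axis=1)
        order = np.argsort(d)[: min(k, len(good))]
        w = 1.0 / np.maximum(d[order], 1e-9)
        w /= w.sum()
        out[i] = np.tensordot(w, eeg[[good[j] for j in order]], axes=1)
    return out


def filter_eeg(eeg: np.ndarray, fs: float = 256.0) -> np.ndarray:
    """Per-channel mean subtraction then zero-phase 0.5-40 Hz band-pass."""
    eeg = np.asarray(eeg, float)
    x = eeg - eeg.mean(axis=-1, keepdims=True)
    sos = sps.butter(4, EEG_BAND, btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


@dataclass
class EpochedEEG:
    """Contiguous non-overlapping 1-s epochs with a keep mask."""

    data: np.ndarray  # epochs x channels x samples
    keep: np.ndarray  # boolean per epoch
    fs: float

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.keep]


def _epoch_kurtosis(data: np.ndarray) -> np.ndarray:
    """Vectorised K = mu4/sigma^4 over the last axis (epochs x channels)."""
    mu = data.mean(axis=-1, keepdims=True)
    dev = data - mu
    var = np.mean(dev * dev, axis=-1)
    m4 = np.mean(dev**4, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = m4 / (var * var)
    k[var == 0] = np.nan
    return k


def epoch_and_reject(
    eeg: np.ndarray, fs: float = 256.0, kurtosis_z_threshold: float = 8.0
) -> EpochedEEG:
    """Cut into 1-s epochs; drop epochs where any channel's intra-epoch
    kurtosis is an outlier across that channel's epochs.

    The default threshold is deliberately liberal: epoch rejection targets
    gross damage (spike bursts, amplifier glitches); ordinary blink epochs
    must survive so the later ICA stage can learn the blink subspace.
    """
    eeg = np.asarray(eeg, float)
    step = int(round(fs))
    n_ep = eeg.shape[-1] // step
    if n_ep < 1:
        raise ValueError("signal shorter than one epoch")
    data = eeg[:, : n_ep * step].reshape(eeg.shape[0], n_ep, step).transpose(1, 0, 2)
    ks = _epoch_kurtosis(data)  # epochs x channels
    keep = np.ones(n_ep, bool)
    for c in range(data.shape[1]):
        z = _robust_z(ks[:, c])
        keep &= ~(np.abs(z) > kurtosis_z_threshold) & np.isfinite(ks[:, c])
    return EpochedEEG(data=data, keep=keep, fs=fs)


@dataclass
class ComponentDecomposition:
    mixing: np.ndarray  # channels x components
    unmixing: np.ndarray  # components x channels
    mean: np.ndarray  # per-channel mean removed before unmixing
    scores: np.ndarray  # blink-likeness per component
    rejected: list[int] = field(default_factory=list)


def _blink_likeness(
    sources: np.ndarray, mixing: np.ndarray, fs: float, channels: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Per component: blink-likeness score (spatial frontal concentration x
    (1 + positive excess kurtosis) x max/median epoch-variance ratio) and the
    frontal concentration itself."""
    fr = frontal_indices(channels)
    n_comp = sources.shape[0]
    scores = np.empty(n_comp)
    conc = np.empty(n_comp)
    step = int(round(fs))
    n_ep = max(sources.shape[1] // step, 1)
    for k in range(n_comp):
        col = np.abs(mixing[:, k])
        denom = col.mean()
        conc[k] = col[fr].mean() / denom if denom > 0 else 0.0
        exk = max(stats.kurtosis(sources[k], fisher=True, bias=True), 0.0)
        ep_var = sources[k, : n_ep * step].reshape(n_ep, step).var(axis=1)
        med = np.median(ep_var)
        var_ratio = ep_var.max() / med if med > 0 else 1.0
        scores[k] = conc[k] * (1.0 + exk) * var_ratio
    return scores, conc


#: a blink component must load frontal electrodes at least this much more
#: than the montage average; non-frontal high-kurtosis directions (finite-
#: sample ICA artifacts, muscle bursts) are not blink candidates
MIN_FRONTAL_CONCENTRATION = 1.5


def _split_scores(log_scores: np.ndarray, min_gap: float) -> list[int]:
    """Two-cluster 1-D split of log scores; upper cluster flagged only when
    the between-cluster separation exceeds ``min_gap`` log units."""
    order = np.argsort(log_scores)
    s = log_scores[order]
    n = len(s)
    if n < 2:
        return []
    # best 1-D 2-means split point
    best_cut, best_cost = None, np.inf
    for cut in range(1, n):
        lo, hi = s[:cut], s[cut:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_cut = cost, cut
    lo, hi = s[:best_cut], s[best_cut:]
    if hi.mean() - lo.mean() < min_gap:
        return []
    return sorted(int(i) for i in order[best_cut:])


def reject_artifact_components(
    epoched: EpochedEEG,
    channels: tuple[str, ...] = CHANNELS,
    seed: int = 0,
    min_log_gap: float = 2.5,
) -> tuple[EpochedEEG, ComponentDecomposition]:
    """ICA-based blink removal on epoched EEG.

    The unmixing is learned on the kept epochs only; components are scored
    for blink-likeness and the upper score cluster (if clearly separated) is
    zeroed before back-projection.  On ICA non-convergence the input is
    returned unchanged with a warning.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    kept = epoched.kept_data  # e x c x s
    n_ch = epoched.data.shape[1]
    X = kept.transpose(1, 0, 2).reshape(n_ch, -1)  # channels x time
    if X.shape[1] < n_ch:
        raise ValueError("need at least as many samples as channels")

    mean = X.mean(axis=1)
    # the unmixing matrix is a purely spatial filter, so it can be estimated
    # on a decimated copy; artifact content lives well below the decimated
    # Nyquist frequency
    dec = max(int(X.shape[1] // (n_ch * 2000)), 1)
    Xfit = sps.decimate(X - mean[:, None], dec, ftype="fir", axis=1) if dec > 1 else X - mean[:, None]
    ica = FastICA(n_components=n_ch, random_state=seed, max_iter=200, tol=1e-3)
    with warnings.catch_warnings():
        # the tolerance not being reached within max_iter is routine on EEG
        # whose background subspace is near-Gaussian; the artifact directions
        # stabilise within a few iterations and the estimate remains a valid
        # linear unmixing
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica.fit(Xfit.T)
    if not (np.all(np.isfinite(ica.components_)) and np.all(np.isfinite(ica.mixing_))):
        warnings.warn("ICA failed; returning data unchanged", RuntimeWarning)
        decomp = ComponentDecomposition(
            np.eye(n_ch), np.eye(n_ch), mean, np.zeros(n_ch), []
        )
        return epoched, decomp

    A = ica.mixing_  # channels x components
    W = ica.components_  # components x channels
    S = W @ (X - mean[:, None])  # sources at full rate
    scores, conc = _blink_likeness(S, A, epoched.fs, channels)
    upper = _split_scores(np.log(np.maximum(scores, 1e-12)), min_log_gap)
    rejected = [i for i in upper if conc[i] >= MIN_FRONTAL_CONCENTRATION]

    decomp = ComponentDecomposition(A, W, mean, scores, rejected)
    cleaned = remove_components(
        epoched.data.transpose(1, 0, 2).reshape(n_ch, -1), decomp
    )
    out = EpochedEEG(
        data=cleaned.reshape(n_ch, epoched.data.shape[0], -1).transpose(1, 0, 2),
        keep=epoched.keep.copy(),
        fs=epoched.fs,
    )
    return out, decomp


def remove_components(eeg: np.ndarray, decomp: ComponentDecomposition) -> np.ndarray:
    """Back-project *eeg* with the flagged components zeroed.

    With nothing flagged this is the identity up to numerical tolerance.
    """
    if not decomp.rejected:
        return np.asarray(eeg, float)
    X = np.asarray(eeg, float)
    S = decomp.unmixing @ (X - decomp.mean[:, None])
    S[decomp.rejected] = 0.0
    return decomp.mixing @ S + decomp.mean[:, None]


def clean_eeg(
    eeg: np.ndarray,
    fs: float = 256.0,
    channels: tuple[str, ...] = CHANNELS,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Full EEG chain on a continuous recording, preserving the time axis.

    Filtering, channel QC + interpolation, epoch rejection (recorded in the
    QC dict, the continuous trace keeps every sample so stimulus timing is
    preserved) and ICA blink removal applied to the whole trace.
    """
    filt = filter_eeg(eeg, fs)
    report = detect_bad_channels(filt, channels=channels)
    filt = interpolate_channels(filt, report)
    epoched = epoch_and_reject(filt, fs)
    _, decomp = reject_artifact_components(epoched, channels=channels, seed=seed)
    cleaned = remove_components(filt, decomp)
    qc = {
        "channel_report": report,
        "epoch_keep": epoched.keep,
        "decomposition": decomp,
    }
    return cleaned, qc


# ---------------------------------------------------------------------------
# ECG / peripheral
# ---------------------------------------------------------------------------

def preprocess_ecg(ecg: np.ndarray, fs: float = 256.0) -> np.ndarray:
    """Mean subtraction, linear-phase FIR high-pass at 0.5 Hz, 50 Hz notch,
    65 Hz low-pass — all zero-phase in effect."""
    x = np.asarray(ecg, float)
    x = x - x.mean()

    numtaps = int(6 * fs) + 1  # ~0.5 Hz transition width
    hp = sps.firwin(numtaps, 0.5, pass_zero=False, fs=fs)
    # symmetric FIR applied centred == zero phase
    x = sps.fftconvolve(x, hp, mode="same")

    b, a = sps.iirnotch(50.0, Q=30.0, fs=fs)
    x = sps.filtfilt(b, a, x)

    if fs / 2 > 65.0:
        sos = sps.butter(4, 65.0, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    return x


def morphological_filter(x: np.ndarray, element_width_s: float, fs: float) -> np.ndarray:
    """Grayscale opening followed by closing with a flat structuring element."""
    size = max(int(round(element_width_s * fs)), 2)
    x = np.asarray(x, float)
    opened = ndimage.grey_opening(x, size=size, mode="nearest")
    return ndimage.grey_closing(opened, size=size, mode="nearest")
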