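"""R-peak detection, the RR tachogram and the 56-feature HRV battery.

QRS detection follows the Pan-Tompkins chain: 5-15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, then adaptive dual thresholds
with search-back and a 200 ms refractory period; each detection is refined to
the R apex of the band-passed signal.

The battery spans four domains — time (11), frequency by Welch on a
4 Hz-resampled tachogram (14), frequency by Lomb-Scargle on the raw unevenly
sampled intervals (14), time-frequency as windowed Welch spectra averaged
over 30 s windows (14) — plus three nonlinear metrics (Poincare SD1/SD2 and
Sample Entropy), 56 named values in all.  Entries that cannot be computed on
a given segment are reported as NaN; the vector never shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "RPeakList",
    "Tachogram",
    "detect_r_peaks",
    "build_tachogram",
    "time_domain_features",
    "spectral_features",
    "time_frequency_features",
    "nonlinear_features",
    "sample_entropy",
    "hrv_feature_vector",
    "HRV_FEATURE_NAMES",
    "HRV_BANDS",
]

REFRACTORY_S = 0.200
RR_VALID_MS = (300.0, 2000.0)

#: tachogram spectral bands (Hz); ULF/VLF matter only on day-long records
#: but are retained as features
HRV_BANDS: dict[str, tuple[float, float]] = {
    "ULF": (0.0, 0.033),
    "VLF": (0.033, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, 0.4),
}

SDARR_WINDOW_S = 30.0  # windowed-mean-RR SD; the conventional 5-min window
                       # would exceed a single commercial

_SPECTRAL_NAMES = [
    "peakULF", "peakVLF", "peakLF", "peakHF",
    "aULF", "aVLF", "aLF", "aHF", "aTotal",
    "pLF", "pHF", "nLF", "nHF", "LFHF",
]
_TIME_NAMES = [
    "t_maxRR", "t_minRR", "t_meanRR", "t_medianRR", "t_SDRR", "t_SDARR",
    "t_RMSSD", "t_RR50", "t_pRR50", "t_meanHR", "t_sdHR",
]
HRV_FEATURE_NAMES: list[str] = (
    _TIME_NAMES
    + [f"fw_{n}" for n in _SPECTRAL_NAMES]
    + [f"fl_{n}" for n in _SPECTRAL_NAMES]
    + [f"tf_{n}" for n in _SPECTRAL_NAMES]
    + ["nl_SD1", "nl_SD2", "nl_SampEn"]
)


@dataclass
class RPeakList:
    indices: np.ndarray  # sample indices, strictly increasing
    fs: float

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Tachogram:
    """RR intervals (ms) with each interval's end time (s) and the artifact mask."""

    rr_ms: np.ndarray       # retained intervals
    t_s: np.ndarray         # end time of each retained interval
    raw_rr_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    raw_t_s: np.ndarray = field(default=None)    # type: ignore[assignment]
    kept: np.ndarray = field(default=None)       # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.raw_rr_ms is None:
            self.raw_rr_ms = self.rr_ms
            self.raw_t_s = self.t_s
            self.kept = np.ones(len(self.rr_ms), bool)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("tachogram times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        if len(self.t_s) == 0:
            return 0.0
        start = self.t_s[0] - self.rr_ms[0] / 1000.0
        return float(self.t_s[-1] - start)

    def slice(self, start: float, end: float) -> "Tachogram":
        """Sub-tachogram of intervals ending within [start, end)."""
        m = (self.t_s >= start) & (self.t_s < end)
        return Tachogram(self.rr_ms[m], self.t_s[m])

    def __len__(self) -> int:
        return len(self.rr_ms)


# ---------------------------------------------------------------------------
# Pan-Tompkins
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float = 256.0) -> RPeakList:
    """Pan-Tompkins QRS detection on a preprocessed single-lead ECG."""
    x = np.asarray(ecg, float)
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) == 0:
        return RPeakList(np.array([], int), fs)

    sos = sps.butter(3, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    min_dist = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=min_dist)
    if len(cand) == 0:
        return RPeakList(np.array([], int), fs)

    # adaptive dual thresholds (learning phase on the first two seconds)
    lead = mwi[: int(2 * fs)]
    spki = 0.25 * lead.max()
    npki = 0.5 * lead.mean()
    thr1 = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_hist: list[float] = []
    noise_buf: list[int] = []

    def accept(i: int, peak_val: float) -> None:
        nonlocal spki, thr1
        spki = 0.125 * peak_val + 0.875 * spki
        thr1 = npki + 0.25 * (spki - npki)
        accepted.append(i)

    for i in cand:
        v = mwi[i]
        rr_avg = np.mean(rr_hist[-8:]) if rr_hist else None
        if v > thr1:
            if accepted and (i - accepted[-1]) < min_dist:
                continue
            if accepted:
                rr_hist.append((i - accepted[-1]) / fs)
            accept(i, v)
            noise_buf.clear()
        else:
            npki = 0.125 * v + 0.875 * npki
            thr1 = npki + 0.25 * (spki - npki)
            noise_buf.append(i)
            # search-back: a long gap is re-scanned at half threshold
            if accepted and rr_avg and (i - accepted[-1]) / fs > 1.66 * rr_avg:
                back = [j for j in noise_buf if (j - accepted[-1]) >= min_dist]
                if back:
                    j = max(back, key=lambda j: mwi[j])
                    if mwi[j] > 0.5 * thr1:
                        rr_hist.append((j - accepted[-1]) / fs)
                        accept(j, mwi[j])
                        noise_buf.clear()

    # refine each detection to the R apex of the band-passed signal
    search = int(round(0.10 * fs))
    apexes = []
    for i in accepted:
        j0, j1 = max(i - search, 0), min(i + search + 1, len(bp))
        apexes.append(j0 + int(np.argmax(bp[j0:j1])))
    apexes_arr = np.unique(apexes)
    # enforce refractory on the refined apexes
    out: list[int] = []
    for i in apexes_arr:
        if not out or i - out[-1] >= min_dist:
            out.append(int(i))
    return RPeakList(np.asarray(out, int), fs)


def build_tachogram(rpeaks: RPeakList) -> Tachogram:
    """RR series with the automatic artifact rule: drop intervals outside
    300-2000 ms or deviating more than 20% from the 5-beat local median."""
    if len(rpeaks) < 3:
        raise ValueError("need at least 3 peaks")
    t = rpeaks.times
    rr = np.diff(t) * 1000.0
    ends = t[1:]
    med = pd.Series(rr).rolling(5, center=True, min_periods=1).median().to_numpy()
    keep = (
        (rr >= RR_VALID_MS[0])
        & (rr <= RR_VALID_MS[1])
        & (np.abs(rr - med) <= 0.20 * med)
    )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 intervals retained")
    return Tachogram(rr[keep], ends[keep], raw_rr_ms=rr, raw_t_s=ends, kept=keep)


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_domain_features(tach: Tachogram) -> dict[str, float]:
    rr = tach.rr_ms
    nan = float("nan")
    out = dict.fromkeys(_TIME_NAMES, nan)
    if len(rr) == 0:
        return out
    out["t_maxRR"] = float(rr.max())
    out["t_minRR"] = float(rr.min())
    out["t_meanRR"] = float(rr.mean())
    out["t_medianRR"] = float(np.median(rr))
    hr = 60000.0 / rr
    out["t_meanHR"] = float(hr.mean())
    if len(rr) >= 2:
        out["t_SDRR"] = float(rr.std(ddof=1))
        out["t_sdHR"] = float(hr.std(ddof=1))
        d = np.diff(rr)
        out["t_RMSSD"] = float(np.sqrt(np.mean(d * d)))
        rr50 = int(np.sum(np.abs(d) > 50.0))
        out["t_RR50"] = float(rr50)
        out["t_pRR50"] = float(rr50 / (len(rr) - 1))
    # SD of windowed mean RR
    start = tach.t_s[0] - rr[0] / 1000.0
    edges = np.arange(start, tach.t_s[-1] + SDARR_WINDOW_S, SDARR_WINDOW_S)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (tach.t_s >= lo) & (tach.t_s < hi)
        if m.any():
            means.append(rr[m].mean())
    if len(means) >= 2:
        out["t_SDARR"] = float(np.std(means, ddof=1))
    return out


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def _band_metrics(f: np.ndarray, psd: np.ndarray) -> dict[str, float]:
    nan = float("nan")
    out = dict.fromkeys(_SPECTRAL_NAMES, nan)
    powers = {}
    for name, (lo, hi) in HRV_BANDS.items():
        m = (f >= lo) & (f < hi)
        if m.any():
            df = np.median(np.diff(f))
            powers[name] = float(psd[m].sum() * df)
            out[f"peak{name}"] = float(f[m][np.argmax(psd[m])]) if psd[m].max() > 0 else nan
        else:
            powers[name] = 0.0
    a_total = sum(powers.values())
    for name in HRV_BANDS:
        out[f"a{name}"] = powers[name]
    out["aTotal"] = a_total
    if a_total > 0:
        out["pLF"] = 100.0 * powers["LF"] / a_total
        out["pHF"] = 100.0 * powers["HF"] / a_total
    lf_hf = powers["LF"] + powers["HF"]
    if lf_hf > 0:
        out["nLF"] = powers["LF"] / lf_hf
        out["nHF"] = powers["HF"] / lf_hf
    if powers["HF"] > 0:
        out["LFHF"] = powers["LF"] / powers["HF"]
    return out


def spectral_features(tach: Tachogram, method: str = "welch") -> dict[str, float]:
    """The 14 band-power metrics via Welch (on a 4 Hz cubic-resampled
    tachogram) or Lomb-Scargle (on the raw uneven samples)."""
    if method not in ("welch", "lomb"):
        raise ValueError("method must be 'welch' or 'lomb'")
    prefix = "fw_" if method == "welch" else "fl_"
    empty = {prefix + k: float("nan") for k in _SPECTRAL_NAMES}
    if tach.duration_s < 30.0 or len(tach) < 8:
        return empty
    if method == "welch":
        fs_r = 4.0
        cs = CubicSpline(tach.t_s, tach.rr_ms)
        tt = np.arange(tach.t_s[0], tach.t_s[-1], 1.0 / fs_r)
        if len(tt) < 16:
            return empty
        x = cs(tt)
        nperseg = min(len(x), 256)
        f, psd = sps.welch(
            x, fs=fs_r, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend="constant", scaling="density",
        )
    else:
        dur = tach.t_s[-1] - tach.t_s[0]
        df = 1.0 / (2.0 * dur)
        f = np.arange(df, 0.4 + df / 2, df)
        y = tach.rr_ms - tach.rr_ms.mean()
        p = sps.lombscargle(tach.t_s, y, 2 * np.pi * f)
        psd = 2.0 * p / len(y)  # scale to a density-like quantity
    return {prefix + k: v for k, v in _band_metrics(f, psd).items()}


def time_frequency_features(tach: Tachogram, window_s: float = 30.0) -> dict[str, float]:
    """Welch-path spectral metrics on 50%-overlapping windows, averaged.

    A tachogram no longer than one window degenerates to the plain Welch
    spectral features.
    """
    empty = {"tf_" + k: float("nan") for k in _SPECTRAL_NAMES}
    if len(tach) < 8:
        return empty
    start = tach.t_s[0]
    end = tach.t_s[-1]
    if end - start <= window_s:
        sf = spectral_features(tach, "welch")
        return {"tf_" + k: sf["fw_" + k] for k in _SPECTRAL_NAMES}
    rows = []
    t0 = start
    while t0 < end:
        sub = tach.slice(t0, t0 + window_s + 1e-9)
        if len(sub) >= 8 and sub.duration_s >= 20.0:
            sf = spectral_features(sub, "welch") if sub.duration_s >= 30.0 else None
            if sf is None:
                # short trailing window: Welch directly on the slice
                sf = _tf_short_window(sub)
            rows.append([sf["fw_" + k] for k in _SPECTRAL_NAMES])
        t0 += window_s / 2.0
    if not rows:
        return empty
    mean = np.nanmean(np.asarray(rows, float), axis=0)
    return {"tf_" + k: float(v) for k, v in zip(_SPECTRAL_NAMES, mean)}


def _tf_short_window(sub: Tachogram) -> dict[str, float]:
    fs_r = 4.0
    cs = CubicSpline(sub.t_s, sub.rr_ms)
    tt = np.arange(sub.t_s[0], sub.t_s[-1], 1.0 / fs_r)
    if len(tt) < 16:
        return {"fw_" + k: float("nan") for k in _SPECTRAL_NAMES}
    x = cs(tt)
    nperseg = min(len(x), 256)
    f, psd = sps.welch(x, fs=fs_r, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant", scaling="density")
    return {"fw_" + k: v for k, v in _band_metrics(f, psd).items()}


# ---------------------------------------------------------------------------
# nonlinear
# ---------------------------------------------------------------------------

def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample Entropy: -log of the conditional probability that runs similar
    for m points stay similar for m+1 (Chebyshev distance, self-matches
    excluded).  Zero for a perfectly regular series."""
    x = np.asarray(x, float)
    n = len(x)
    if n < m + 2:
        return float("nan")
    if r is None:
        r = 0.2 * x.std()

    def count(mm: int) -> int:
        # both template lengths range over the same n-m start positions so
        # the conditional probability A/B is well defined
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        k = len(templ)
        # pairwise Chebyshev distances, upper triangle
        c = 0
        for i in range(k - 1):
            d = np.max(np.abs(templ[i + 1 :] - templ[i]), axis=1)
            c += int(np.sum(d <= r))
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return float("nan") if a == 0 and b == 0 else float("inf") if a == 0 else 0.0
    return float(-np.log(a / b))


def nonlinear_features(tach: Tachogram) -> dict[str, float]:
    """Poincare SD1/SD2 and Sample Entropy (m=2, r=0.2*SD)."""
    rr = tach.rr_ms
    nan = float("nan")
    out = {"nl_SD1": nan, "nl_SD2": nan, "nl_SampEn": nan}
    if len(rr) < 3:
        return out
    d = np.diff(rr)
    sd1_sq = 0.5 * d.var()
    sd2_sq = max(2.0 * rr.var() - sd1_sq, 0.0)
    out["nl_SD1"] = float(np.sqrt(sd1_sq))
    out["nl_SD2"] = float(np.sqrt(sd2_sq))
    if len(rr) >= 10:
        se = sample_entropy(rr)
        out["nl_SampEn"] = float(se) if np.isfinite(se) else nan
    return out


def hrv_feature_vector(tach: Tachogram) -> pd.Series:
    """The canonical 56-entry HRV vector; missing entries are NaN."""
    feats: dict[str, float] = {}
    feats.update(time_domain_features(tach))
    feats.update(spectral_features(tach, "welch"))
    feats.update(spectral_features(tach, "lomb"))
    feats.update(time_frequency_features(tach))
    feats.update(nonlinear_features(tach))
    return pd.Series([feats[k] for k in HRV_FEATURE_NAMES], index=HRV_FEATURE_NAMES)
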