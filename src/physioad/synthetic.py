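"""Synthetic cohorts of multimodal physiological sessions.

Every downstream stage of the pipeline (preprocessing, feature extraction,
classification) is exercised on data produced here.  A generated subject
carries four synchronised traces over one session timeline:

* **EEG** — 30 channels at 256 Hz: 1/f background plus band-limited
  oscillators whose frontal theta gain is modulated during ad blocks by an
  ad-class multiplier, plus Poisson-timed blink artifacts (a low-frequency
  raised-cosine deflection decaying from the Fp row towards FC).
* **ECG** — a PQRST template train at 256 Hz whose RR series is
  ``base + LF sinusoid (0.1 Hz) + HF sinusoid (0.25 Hz) + slow drift + noise``
  with class multipliers on the base interval and on the drift amplitude.
* **GSR** — slow tonic level plus discrete bi-exponential sudomotor responses
  at a class-conditional Poisson rate, 32 Hz.
* **RSP** — a frequency-modulated respiratory sinusoid, 32 Hz.

The generator keeps a ledger of every event it injects (blink times, true R
times, SCR onsets) so detectors can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import signal as sps

from .montage import CHANNELS, frontal_indices
from .session import SessionConfig, SessionTimeline, generate_timeline

__all__ = [
    "ClassEffects",
    "SubjectProfile",
    "SignalBundle",
    "Cohort",
    "DropModel",
    "GenConfig",
    "generate_subject",
    "generate_cohort",
]

EEG_FS = 256
ECG_FS = 256
AUX_FS = 32

_CLASSES = ("positive", "neutral", "negative")


@dataclass(frozen=True)
class ClassEffects:
    """Class-conditional physiological response strengths.

    Rates and multipliers apply while an ad of the given class is on screen;
    documentary stretches use the neutral/basal values.  The unlabeled
    holdout ad responds with ``holdout_class`` physiology (its label is
    withheld from the classifier, not from the body).
    """

    gsr_rate_per_min: dict[str, float]
    rr_mean_mult: dict[str, float]
    rr_drift_mult: dict[str, float]
    frontal_gain: dict[str, float]
    holdout_class: str = "positive"

    @classmethod
    def default(cls) -> "ClassEffects":
        """Moderate, physiologically plausible separation between classes."""
        return cls(
            gsr_rate_per_min={"positive": 6.0, "neutral": 3.5, "negative": 2.0},
            rr_mean_mult={"positive": 0.97, "neutral": 1.0, "negative": 1.02},
            rr_drift_mult={"positive": 1.8, "neutral": 1.0, "negative": 0.6},
            frontal_gain={"positive": 1.5, "neutral": 1.0, "negative": 0.8},
        )

    @classmethod
    def strong(cls) -> "ClassEffects":
        """Well-separated effects on GSR event rate and RR drift only.

        EEG and mean heart rate carry no class information in this preset;
        it isolates the sudomotor-rate and slow-HRV channels.
        """
        return cls(
            gsr_rate_per_min={"positive": 12.0, "neutral": 6.0, "negative": 2.0},
            rr_mean_mult={"positive": 1.0, "neutral": 1.0, "negative": 1.0},
            rr_drift_mult={"positive": 3.0, "neutral": 1.5, "negative": 0.5},
            frontal_gain={"positive": 1.0, "neutral": 1.0, "negative": 1.0},
        )

    @classmethod
    def null(cls) -> "ClassEffects":
        """No class-conditional structure anywhere (negative control)."""
        return cls(
            gsr_rate_per_min={c: 3.0 for c in _CLASSES},
            rr_mean_mult={c: 1.0 for c in _CLASSES},
            rr_drift_mult={c: 1.0 for c in _CLASSES},
            frontal_gain={c: 1.0 for c in _CLASSES},
        )

    def effective_class(self, label: str) -> str:
        return self.holdout_class if label == "unlabeled" else label


@dataclass
class GenConfig:
    """Amplitudes, rates and noise levels of the signal generator."""

    # EEG (microvolts)
    eeg_background_std: float = 10.0
    eeg_theta_amp: float = 3.0
    eeg_alpha_amp: float = 4.0
    eeg_beta_amp: float = 2.0
    eeg_betaext_amp: float = 1.0
    blink_rate_hz: float = 0.2
    blink_amp: float = 100.0
    blink_width_s: float = 0.4
    n_corrupt_channels: int = 0
    # ECG (RR in milliseconds, trace in millivolts)
    base_rr_ms: float = 800.0
    rr_lf_amp_ms: float = 25.0
    rr_hf_amp_ms: float = 15.0
    rr_drift_amp_ms: float = 30.0
    rr_drift_freq_hz: float = 0.0035
    rr_noise_ms: float = 5.0
    r_amp_mv: float = 1.0
    ecg_noise_mv: float = 0.02
    ecg_mains_mv: float = 0.0  # optional 50 Hz interference
    ecg_wander_mv: float = 0.0  # optional 0.2 Hz baseline wander
    # GSR (microsiemens)
    gsr_tonic_us: float = 2.0
    gsr_tonic_sin_us: float = 0.2
    gsr_tonic_period_s: float = 600.0
    gsr_base_rate_per_min: float = 1.5
    scr_amp_us: float = 0.35
    scr_rise_s: float = 0.7
    scr_decay_s: float = 3.0
    gsr_noise_us: float = 0.01
    # respiration (arbitrary units)
    rsp_rate_hz: float = 0.25
    rsp_fm_depth_hz: float = 0.04
    rsp_fm_freq_hz: float = 0.01
    rsp_noise: float = 0.02
    # group-membership probabilities by effective ad class
    p_remember: dict[str, float] = field(
        default_factory=lambda: {"positive": 0.75, "neutral": 0.5, "negative": 0.4}
    )
    p_like: dict[str, float] = field(
        default_factory=lambda: {"positive": 0.8, "neutral": 0.5, "negative": 0.2}
    )


@dataclass
class SubjectProfile:
    """Per-subject ground truth: group membership flags and effect sizes."""

    subject_id: str
    remember: dict[str, bool]
    like: dict[str, bool]
    effects: ClassEffects
    rng_seed: int
    has_eeg: bool = True
    has_ecg: bool = True
    has_gsr: bool = True
    has_rsp: bool = True

    def check_against(self, timeline: SessionTimeline) -> None:
        for ad in timeline.ad_ids:
            if ad not in self.remember or ad not in self.like:
                raise ValueError(f"profile missing flags for ad {ad!r}")


@dataclass
class SignalBundle:
    """One subject's synchronised traces plus the injected-event ledger."""

    timeline: SessionTimeline
    channels: tuple[str, ...] = CHANNELS
    eeg: Optional[np.ndarray] = None  # channels x samples, microvolts, 256 Hz
    ecg: Optional[np.ndarray] = None  # millivolts, 256 Hz
    gsr: Optional[np.ndarray] = None  # microsiemens, 32 Hz
    rsp: Optional[np.ndarray] = None  # arbitrary units, 32 Hz
    fs_eeg: int = EEG_FS
    fs_ecg: int = ECG_FS
    fs_aux: int = AUX_FS
    events: dict = field(default_factory=dict)

    def segment(self, trace: np.ndarray, fs: float, start: float, end: float) -> np.ndarray:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        return trace[..., max(i0, 0) : min(i1, trace.shape[-1])]


@dataclass
class Cohort:
    """Subjects plus the session layout and the ad-class label map.

    ``timeline`` is the first subject's session as a layout reference; each
    subject's bundle carries its own timeline whose ad order is an
    independent seeded permutation.
    """

    timeline: SessionTimeline
    subjects: list[tuple[SubjectProfile, SignalBundle]]
    ad_labels: dict[str, str]
    effects: ClassEffects

    def __len__(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class DropModel:
    """How many subjects lose each modality to corrupted recordings."""

    n_eeg: int = 12
    n_ecg_rsp: int = 4
    n_gsr: int = 3

    @classmethod
    def none(cls) -> "DropModel":
        return cls(0, 0, 0)


# ---------------------------------------------------------------------------
# per-modality synthesis
# ---------------------------------------------------------------------------

def _class_envelope(
    timeline: SessionTimeline, values: dict[str, float], effects: ClassEffects,
    ad_labels: dict[str, str], fs: float, n: int, basal: float = 1.0,
) -> np.ndarray:
    env = np.full(n, basal)
    for b in timeline.ad_blocks:
        cls = effects.effective_class(ad_labels[b.ad_id])
        i0, i1 = int(b.onset * fs), int(b.end * fs)
        env[i0:i1] = values[cls]
    return env


def _pink_noise(rng: np.random.Generator, n: int, fs: float, std: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x * (std / s) if s > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def _blink_template(fs: float, width_s: float) -> np.ndarray:
    m = max(int(round(width_s * fs)), 3)
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / (m - 1)))  # raised cosine, peak 1


#: blink spatial pattern: strong on the Fp row, halved on F, quartered on FC
_BLINK_GAIN_BY_ROW = {"FP": 1.0, "F": 0.5, "FC": 0.25}


def _blink_gains(channels: tuple[str, ...]) -> np.ndarray:
    g = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        u = ch.upper()
        if u.startswith("FP"):
            g[i] = _BLINK_GAIN_BY_ROW["FP"]
        elif u.startswith("FC"):
            g[i] = _BLINK_GAIN_BY_ROW["FC"]
        elif u.startswith("F"):
            g[i] = _BLINK_GAIN_BY_ROW["F"]
    return g


def synth_eeg(
    timeline: SessionTimeline,
    ad_labels: dict[str, str],
    effects: ClassEffects,
    cfg: GenConfig,
    rng: np.random.Generator,
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[np.ndarray, dict]:
    fs = EEG_FS
    n = int(round(timeline.total_duration * fs))
    n_ch = len(channels)
    eeg = np.empty((n_ch, n), dtype=np.float32)

    theta_env = _class_envelope(timeline, effects.frontal_gain, effects, ad_labels, fs, n)
    fr_idx = set(frontal_indices(channels).tolist())

    for c in range(n_ch):
        x = _pink_noise(rng, n, fs, cfg.eeg_background_std)
        th = cfg.eeg_theta_amp * _band_noise(rng, n, fs, 4, 7)
        if c in fr_idx:
            th = th * theta_env
        x += th
        x += cfg.eeg_alpha_amp * _band_noise(rng, n, fs, 8, 12)
        x += cfg.eeg_beta_amp * _band_noise(rng, n, fs, 13, 24)
        x += cfg.eeg_betaext_amp * _band_noise(rng, n, fs, 25, 40)
        eeg[c] = x

    # blinks: Poisson event train, identical timing on all frontal channels
    n_blinks = rng.poisson(cfg.blink_rate_hz * timeline.total_duration)
    blink_times = np.sort(rng.uniform(0, timeline.total_duration, n_blinks))
    tmpl = _blink_template(fs, cfg.blink_width_s)
    gains = _blink_gains(channels)
    for t0 in blink_times:
        i0 = int(t0 * fs)
        seg = tmpl[: n - i0]
        amp = cfg.blink_amp * rng.uniform(0.8, 1.2)
        for c in np.nonzero(gains)[0]:
            eeg[c, i0 : i0 + len(seg)] += (amp * gains[c] * seg).astype(np.float32)

    events: dict = {"blink_times": blink_times, "corrupt_channels": []}

    # optional corrupted channels: a long flat run and heavy-tailed spikes
    if cfg.n_corrupt_channels:
        bad = rng.choice(n_ch, size=cfg.n_corrupt_channels, replace=False)
        for c in bad:
            i0 = int(0.2 * n)
            eeg[c, i0 : i0 + int(0.15 * n)] = eeg[c, i0]
            spikes = rng.choice(n, size=max(n // 2000, 10), replace=False)
            eeg[c, spikes] += rng.standard_t(1, size=len(spikes)).astype(np.float32) * 200
        events["corrupt_channels"] = sorted(int(c) for c in bad)

    return eeg, events


def synth_rr_series(
    timeline: SessionTimeline,
    ad_labels: dict[str, str],
    effects: ClassEffects,
    cfg: GenConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """True R-peak times (s) and the RR series (ms) that produced them."""
    dur = timeline.total_duration
    drift_phase = rng.uniform(0, 2 * np.pi)

    def mult(table: dict[str, float], t: float) -> float:
        for b in timeline.ad_blocks:
            if b.onset <= t < b.end:
                return table[effects.effective_class(ad_labels[b.ad_id])]
        return 1.0

    times = [0.0]
    rrs = []
    t = 0.0
    while True:
        rr = (
            cfg.base_rr_ms * mult(effects.rr_mean_mult, t)
            + cfg.rr_lf_amp_ms * np.sin(2 * np.pi * 0.1 * t)
            + cfg.rr_hf_amp_ms * np.sin(2 * np.pi * 0.25 * t)
            + cfg.rr_drift_amp_ms
            * mult(effects.rr_drift_mult, t)
            * np.sin(2 * np.pi * cfg.rr_drift_freq_hz * t + drift_phase)
            + cfg.rr_noise_ms * rng.standard_normal()
        )
        rr = max(rr, 300.0)
        t += rr / 1000.0
        if t >= dur:
            break
        times.append(t)
        rrs.append(rr)
    return np.asarray(times), np.asarray(rrs)


def _pqrst_template(fs: float, r_amp: float) -> tuple[np.ndarray, int]:
    """Gaussian-bump PQRST complex; returns (template, index of R apex)."""
    t = np.arange(-0.30, 0.45, 1.0 / fs)

    def bump(amp, mu, sigma):
        return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    w = (
        bump(0.12 * r_amp, -0.19, 0.025)   # P
        + bump(-0.14 * r_amp, -0.028, 0.010)  # Q
        + bump(r_amp, 0.0, 0.011)          # R
        + bump(-0.22 * r_amp, 0.030, 0.012)   # S
        + bump(0.28 * r_amp, 0.22, 0.045)  # T
    )
    return w, int(np.argmin(np.abs(t)))


def synth_ecg(
    timeline: SessionTimeline,
    r_times: np.ndarray,
    cfg: GenConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    fs = ECG_FS
    n = int(round(timeline.total_duration * fs))
    ecg = np.zeros(n)
    tmpl, r_off = _pqrst_template(fs, cfg.r_amp_mv)
    for tr in r_times:
        i0 = int(round(tr * fs)) - r_off
        j0, j1 = max(i0, 0), min(i0 + len(tmpl), n)
        ecg[j0:j1] += tmpl[j0 - i0 : j1 - i0]
    if cfg.ecg_noise_mv:
        ecg += cfg.ecg_noise_mv * rng.standard_normal(n)
    tt = np.arange(n) / fs
    if cfg.ecg_mains_mv:
        ecg += cfg.ecg_mains_mv * np.sin(2 * np.pi * 50.0 * tt)
    if cfg.ecg_wander_mv:
        ecg += cfg.ecg_wander_mv * np.sin(2 * np.pi * 0.2 * tt + rng.uniform(0, 2 * np.pi))
    return ecg


def _scr_kernel(fs: float, rise_s: float, decay_s: float, length_s: float = 15.0) -> np.ndarray:
    t = np.arange(0, length_s, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def synth_gsr(
    timeline: SessionTimeline,
    ad_labels: dict[str, str],
    effects: ClassEffects,
    cfg: GenConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    fs = AUX_FS
    dur = timeline.total_duration
    n = int(round(dur * fs))
    tt = np.arange(n) / fs
    gsr = (
        cfg.gsr_tonic_us
        + cfg.gsr_tonic_sin_us * np.sin(2 * np.pi * tt / cfg.gsr_tonic_period_s)
        + 0.05 * tt / dur
    )

    # piecewise-homogeneous Poisson event process
    onsets: list[float] = []
    for b in timeline.blocks:
        if b.kind == "ad":
            rate = effects.gsr_rate_per_min[effects.effective_class(ad_labels[b.ad_id])]
        else:
            rate = cfg.gsr_base_rate_per_min
        lam = rate / 60.0 * b.duration
        k = rng.poisson(lam)
        onsets.extend(np.sort(rng.uniform(b.onset, b.end, k)))
    onsets_arr = np.sort(np.asarray(onsets))

    kern = _scr_kernel(fs, cfg.scr_rise_s, cfg.scr_decay_s)
    t_peak_off = float(np.argmax(kern)) / fs
    for t0 in onsets_arr:
        i0 = int(round(t0 * fs))
        amp = cfg.scr_amp_us * rng.lognormal(0.0, 0.3)
        seg = kern[: n - i0]
        gsr[i0 : i0 + len(seg)] += amp * seg
    if cfg.gsr_noise_us:
        gsr += cfg.gsr_noise_us * rng.standard_normal(n)
    events = {"scr_onsets": onsets_arr, "scr_peak_times": onsets_arr + t_peak_off}
    return gsr, events


def synth_rsp(
    timeline: SessionTimeline, cfg: GenConfig, rng: np.random.Generator
) -> np.ndarray:
    fs = AUX_FS
    n = int(round(timeline.total_duration * fs))
    tt = np.arange(n) / fs
    f_inst = cfg.rsp_rate_hz + cfg.rsp_fm_depth_hz * np.sin(
        2 * np.pi * cfg.rsp_fm_freq_hz * tt + rng.uniform(0, 2 * np.pi)
    )
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    rsp = np.sin(phase)
    if cfg.rsp_noise:
        rsp = rsp + cfg.rsp_noise * rng.standard_normal(n)
    return rsp


# ---------------------------------------------------------------------------
# subject / cohort assembly
# ---------------------------------------------------------------------------

def generate_subject(
    timeline: SessionTimeline,
    profile: SubjectProfile,
    ad_labels: dict[str, str],
    gen_config: GenConfig | None = None,
    modalities: Iterable[str] = ("eeg", "ecg", "gsr", "rsp"),
) -> SignalBundle:
    """Synthesise one subject's SignalBundle (deterministic in the profile seed)."""
    profile.check_against(timeline)
    cfg = gen_config or GenConfig()
    rng = np.random.default_rng(profile.rng_seed)
    want = set(modalities)
    bundle = SignalBundle(timeline=timeline)
    effects = profile.effects

    # sub-streams are seeded independently so that skipping a modality does
    # not perturb the others
    seeds = rng.integers(0, 2**31 - 1, size=4)
    if "eeg" in want and profile.has_eeg:
        eeg, ev = synth_eeg(timeline, ad_labels, effects, cfg, np.random.default_rng(seeds[0]))
        bundle.eeg = eeg
        bundle.events.update(ev)
    if ("ecg" in want and profile.has_ecg) or ("hrv" in want and profile.has_ecg):
        rng_ecg = np.random.default_rng(seeds[1])
        r_times, rr = synth_rr_series(timeline, ad_labels, effects, cfg, rng_ecg)
        bundle.ecg = synth_ecg(timeline, r_times, cfg, rng_ecg)
        bundle.events["r_times"] = r_times
        bundle.events["rr_ms"] = rr
    if "gsr" in want and profile.has_gsr:
        gsr, ev = synth_gsr(timeline, ad_labels, effects, cfg, np.random.default_rng(seeds[2]))
        bundle.gsr = gsr
        bundle.events.update(ev)
    if "rsp" in want and profile.has_rsp:
        bundle.rsp = synth_rsp(timeline, cfg, np.random.default_rng(seeds[3]))
    return bundle


def make_profile(
    subject_id: str,
    timeline: SessionTimeline,
    ad_labels: dict[str, str],
    effects: ClassEffects,
    cfg: GenConfig,
    seed: int,
) -> SubjectProfile:
    rng = np.random.default_rng(seed)
    remember: dict[str, bool] = {}
    like: dict[str, bool] = {}
    for ad in timeline.ad_ids:
        cls = effects.effective_class(ad_labels[ad])
        remember[ad] = bool(rng.random() < cfg.p_remember[cls])
        like[ad] = bool(rng.random() < cfg.p_like[cls])
    return SubjectProfile(
        subject_id=subject_id,
        remember=remember,
        like=like,
        effects=effects,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_subjects: int,
    class_effects: ClassEffects | None = None,
    seed: int = 0,
    session_config: SessionConfig | None = None,
    gen_config: GenConfig | None = None,
    drop: DropModel | None = DropModel(),
    modalities: Iterable[str] = ("eeg", "ecg", "gsr", "rsp"),
) -> Cohort:
    """Generate a cohort sharing one timeline, with per-subject sub-seeds.

    ``drop`` emulates recordings lost to corruption: the listed numbers of
    subjects lose EEG, ECG+RSP and GSR respectively (independently chosen,
    capped at ``n_subjects``).  Pass ``DropModel.none()`` (or ``None``) to
    keep every modality for every subject.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    effects = class_effects or ClassEffects.default()
    cfg = gen_config or GenConfig()
    drop = drop or DropModel.none()

    master = np.random.default_rng(seed)
    # every subject sees the same block layout but their own seeded ad order,
    # so presentation position cannot masquerade as an ad effect
    timelines = [
        generate_timeline(session_config, seed=int(master.integers(0, 2**31 - 1)))
        for _ in range(n_subjects)
    ]
    ads = (session_config or SessionConfig()).ads
    ad_labels = {a.ad_id: a.label for a in ads}

    profiles = [
        make_profile(f"s{i:03d}", timelines[i], ad_labels, effects, cfg,
                     seed=int(master.integers(0, 2**31 - 1)))
        for i in range(n_subjects)
    ]
    for n_drop, flags in (
        (drop.n_eeg, ("has_eeg",)),
        (drop.n_ecg_rsp, ("has_ecg", "has_rsp")),
        (drop.n_gsr, ("has_gsr",)),
    ):
        k = min(n_drop, n_subjects)
        if k:
            for i in master.choice(n_subjects, size=k, replace=False):
                for fl in flags:
                    setattr(profiles[i], fl, False)

    subjects = [
        (p, generate_subject(tl, p, ad_labels, cfg, modalities))
        for p, tl in zip(profiles, timelines)
    ]
    return Cohort(timeline=timelines[0], subjects=subjects, ad_labels=ad_labels, effects=effects)
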