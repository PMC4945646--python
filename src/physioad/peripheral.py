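"""GSR and respiration features from morphologically smoothed traces.

Skin-conductance features treat local maxima of the smoothed trace as
sudomotor (SCR) peaks; each maximum is paired with the immediately preceding
local minimum to measure the conductivity rise of that response.  Breathing
features anchor breaths at inhalation maxima and measure inter-breath
intervals max-to-max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExtremaSequence",
    "detect_extrema",
    "gsr_features",
    "rsp_features",
    "GSR_FEATURE_NAMES",
    "RSP_FEATURE_NAMES",
]

GSR_FEATURE_NAMES: list[str] = [
    "gsr_mean", "gsr_var", "gsr_std",
    "gsr_n_maxima", "gsr_n_minima", "gsr_mean_rise",
    "gsr_max", "gsr_min", "gsr_range", "gsr_peaks_per_time",
]

RSP_FEATURE_NAMES: list[str] = [
    "rsp_rate", "rsp_mean", "rsp_longest_ibi", "rsp_shortest_ibi",
    "rsp_max", "rsp_min",
]


@dataclass
class ExtremaSequence:
    """Strictly alternating local minima/maxima of a smoothed trace."""

    times: np.ndarray    # seconds
    values: np.ndarray
    kinds: np.ndarray    # +1 for maxima, -1 for minima

    def __post_init__(self) -> None:
        if len(self.kinds) > 1 and np.any(self.kinds[1:] == self.kinds[:-1]):
            raise ValueError("extrema must alternate")

    @property
    def maxima(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.kinds == 1
        return self.times[m], self.values[m]

    @property
    def minima(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.kinds == -1
        return self.times[m], self.values[m]

    def __len__(self) -> int:
        return len(self.times)


def detect_extrema(
    x: np.ndarray, fs: float = 32.0, min_prominence: float = 0.0
) -> ExtremaSequence:
    """Sign-change scan of the first difference.

    Plateaus are resolved to their midpoint; alternation is enforced by
    merging the lesser of two same-type neighbours (the lower of two maxima,
    the higher of two minima).  ``min_prominence`` prunes wiggles whose
    amplitude excursion is smaller than the given value: adjacent
    minimum/maximum pairs closer in value than this are removed, smallest
    first, so residual micro-ripple that survives smoothing is not counted
    as physiology.
    """
    x = np.asarray(x, float)
    empty = ExtremaSequence(np.array([]), np.array([]), np.array([], int))
    if len(x) < 3:
        return empty

    # run-length compress equal consecutive values so plateaus become points
    change = np.r_[True, np.diff(x) != 0]
    starts = np.flatnonzero(change)
    vals = x[starts]
    ends = np.r_[starts[1:], len(x)]
    mids = (starts + ends - 1) / 2.0  # plateau midpoint (samples)
    if len(vals) < 3:
        return empty

    d = np.sign(np.diff(vals))
    idx: list[int] = []
    kinds: list[int] = []
    for i in range(1, len(vals) - 1):
        if d[i - 1] > 0 and d[i] < 0:
            idx.append(i)
            kinds.append(1)
        elif d[i - 1] < 0 and d[i] > 0:
            idx.append(i)
            kinds.append(-1)
    if not idx:
        return empty

    times = [mids[i] / fs for i in idx]
    values = [vals[i] for i in idx]

    # enforce alternation (can only be violated after plateau merging edge cases)
    changed = True
    while changed and len(kinds) > 1:
        changed = False
        for i in range(len(kinds) - 1):
            if kinds[i] == kinds[i + 1]:
                if kinds[i] == 1:
                    drop = i if values[i] < values[i + 1] else i + 1
                else:
                    drop = i if values[i] > values[i + 1] else i + 1
                del times[drop], values[drop], kinds[drop]
                changed = True
                break

    # prune low-prominence wiggles (adjacent pairs of opposite type whose
    # value difference is below the floor), smallest excursion first
    if min_prominence > 0:
        while len(kinds) > 1:
            gaps = [abs(values[i + 1] - values[i]) for i in range(len(kinds) - 1)]
            i = int(np.argmin(gaps))
            if gaps[i] >= min_prominence:
                break
            del times[i + 1], values[i + 1], kinds[i + 1]
            del times[i], values[i], kinds[i]
        if len(kinds) == 1 and min_prominence > 0:
            # a lone extremum of a near-flat trace is not meaningful
            span = float(np.ptp(x))
            if span < min_prominence:
                return ExtremaSequence(np.array([]), np.array([]), np.array([], int))
    return ExtremaSequence(np.asarray(times), np.asarray(values), np.asarray(kinds, int))


#: minimum skin-conductance excursion counted as a sudomotor response (uS);
#: the conventional SCR amplitude criterion
SCR_MIN_AMPLITUDE_US = 0.05


def gsr_features(
    gsr_segment: np.ndarray, fs: float = 32.0,
    min_prominence: float = SCR_MIN_AMPLITUDE_US,
) -> dict[str, float]:
    """The ten skin-conductance statistics of one stimulus interval.

    Expects the morphologically smoothed trace.  ``gsr_mean_rise`` is the
    mean conductivity gain over consecutive minimum-to-maximum pairs; NaN
    when the segment carries no such pair.  Extrema shallower than
    ``min_prominence`` are not counted as sudomotor events.
    """
    x = np.asarray(gsr_segment, float)
    if len(x) == 0:
        raise ValueError("empty GSR segment")
    duration = len(x) / fs
    ext = detect_extrema(x, fs, min_prominence=min_prominence)
    tmax, vmax = ext.maxima
    tmin, vmin = ext.minima

    rises = []
    for t, v in zip(tmax, vmax):
        prior = tmin < t
        if prior.any():
            rises.append(v - vmin[prior][-1])
    return {
        "gsr_mean": float(x.mean()),
        "gsr_var": float(x.var()),
        "gsr_std": float(x.std()),
        "gsr_n_maxima": float(len(tmax)),
        "gsr_n_minima": float(len(tmin)),
        "gsr_mean_rise": float(np.mean(rises)) if rises else float("nan"),
        "gsr_max": float(x.max()),
        "gsr_min": float(x.min()),
        "gsr_range": float(x.max() - x.min()),
        "gsr_peaks_per_time": float(len(tmax) / duration),
    }


def rsp_features(rsp_segment: np.ndarray, fs: float = 32.0) -> dict[str, float]:
    """The six respiration statistics of one stimulus interval.

    Breaths are inhalation maxima of the smoothed trace (excursions of at
    least 10% of the segment's own range); the rate is breaths/minute and
    inter-breath intervals are measured max-to-max.
    """
    x = np.asarray(rsp_segment, float)
    if len(x) == 0:
        raise ValueError("empty RSP segment")
    duration = len(x) / fs
    # breaths must swing at least 10% of the trace's own range
    tmax, _ = detect_extrema(x, fs, min_prominence=0.1 * float(np.ptp(x))).maxima
    ibis = np.diff(tmax)
    return {
        "rsp_rate": float(len(tmax) * 60.0 / duration),
        "rsp_mean": float(x.mean()),
        "rsp_longest_ibi": float(ibis.max()) if len(ibis) else float("nan"),
        "rsp_shortest_ibi": float(ibis.min()) if len(ibis) else float("nan"),
        "rsp_max": float(x.max()),
        "rsp_min": float(x.min()),
    }
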