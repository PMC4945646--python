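"""Session timelines: documentary filler with embedded commercial blocks.

A recording session is a single continuous timeline in which three blocks of
three commercials each are inserted into a neutral documentary.  The stretch of
documentary immediately preceding each ad block doubles as the baseline window
for EEG normalisation, so every ad block must be preceded by at least two
minutes of documentary and the first block cannot start before minute seven.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

__all__ = [
    "StimulusBlock",
    "SessionTimeline",
    "SessionConfig",
    "AdSpec",
    "DEFAULT_ADS",
    "generate_timeline",
    "BASELINE_S",
    "FIRST_BLOCK_MIN_ONSET_S",
]

#: duration of the pre-block documentary baseline used for Zscore normalisation
BASELINE_S = 120.0
#: earliest allowed onset of the first ad block (7 minutes)
FIRST_BLOCK_MIN_ONSET_S = 420.0

ADS_PER_BLOCK = 3
N_AD_BLOCKS = 3


@dataclass(frozen=True)
class AdSpec:
    """One commercial: identifier, effectiveness class and panel score.

    ``label`` is one of ``positive``/``neutral``/``negative``/``unlabeled``.
    The unlabeled ad is the spot under evaluation: it is never used for
    training and is predicted by the final model.
    """

    ad_id: str
    label: str
    ace_score: Optional[int] = None


# Default stimulus set: nine commercials grouped by their panel effectiveness
# score — four positive, two neutral, two negative and one unlabeled spot
# under evaluation.
DEFAULT_ADS: tuple[AdSpec, ...] = (
    AdSpec("brotherhood", "positive", 665),
    AdSpec("security_camera", "positive", 641),
    AdSpec("goat_4_sale", "positive", 626),
    AdSpec("stuck", "positive", 611),
    AdSpec("bravery", "neutral", 394),
    AdSpec("concept", "neutral", 362),
    AdSpec("pub_loo_shocker", "negative", 210),
    AdSpec("carmel_limo", "negative", 167),
    AdSpec("the_date", "unlabeled", None),
)


@dataclass(frozen=True)
class StimulusBlock:
    """A contiguous segment of the session: documentary filler or one ad."""

    kind: str  # "documentary" | "ad"
    onset: float  # seconds from session start
    duration: float  # seconds
    ad_id: Optional[str] = None
    brand_windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("documentary", "ad"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("block duration must be positive")
        end = self.onset + self.duration
        for lo, hi in self.brand_windows:
            if not (self.onset <= lo < hi <= end):
                raise ValueError("brand window outside its ad block")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class SessionTimeline:
    """Ordered, gap-free tiling of a session by stimulus blocks."""

    total_duration: float
    blocks: list[StimulusBlock]
    ad_order_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        t = 0.0
        for b in self.blocks:
            if abs(b.onset - t) > 1e-9:
                raise ValueError("blocks must tile the session without gaps/overlap")
            t = b.end
        if abs(t - self.total_duration) > 1e-9:
            raise ValueError("blocks do not cover the full session")
        groups = self.ad_block_groups()
        if len(groups) != N_AD_BLOCKS:
            raise ValueError(f"expected {N_AD_BLOCKS} ad blocks, got {len(groups)}")
        for g in groups:
            if len(g) != ADS_PER_BLOCK:
                raise ValueError("each ad block must contain exactly 3 ads")
        if groups[0][0].onset < FIRST_BLOCK_MIN_ONSET_S:
            raise ValueError("first ad block must start >= 7 min into the session")
        for g in groups:
            pre = self._documentary_before(g[0].onset)
            if pre < BASELINE_S - 1e-9:
                raise ValueError("every ad block needs >= 2 min documentary baseline")

    def _documentary_before(self, onset: float) -> float:
        run = 0.0
        for b in self.blocks:
            if b.end <= onset + 1e-9:
                run = run + b.duration if b.kind == "documentary" else 0.0
            if abs(b.end - onset) < 1e-9:
                break
        return run

    # -- views -------------------------------------------------------------
    @property
    def ad_blocks(self) -> list[StimulusBlock]:
        return [b for b in self.blocks if b.kind == "ad"]

    def ad_block_groups(self) -> list[list[StimulusBlock]]:
        """Ads grouped into their contiguous blocks of three."""
        groups: list[list[StimulusBlock]] = []
        prev_end = None
        for b in self.blocks:
            if b.kind != "ad":
                continue
            if prev_end is not None and abs(b.onset - prev_end) < 1e-9:
                groups[-1].append(b)
            else:
                groups.append([b])
            prev_end = b.end
        return groups

    def block_for_ad(self, ad_id: str) -> StimulusBlock:
        for b in self.ad_blocks:
            if b.ad_id == ad_id:
                return b
        raise KeyError(ad_id)

    def baseline_interval(self, ad_id: str) -> tuple[float, float]:
        """The 2-min documentary window preceding the block containing *ad_id*."""
        for group in self.ad_block_groups():
            if any(b.ad_id == ad_id for b in group):
                start = group[0].onset
                return (start - BASELINE_S, start)
        raise KeyError(ad_id)

    @property
    def ad_ids(self) -> list[str]:
        return [b.ad_id for b in self.ad_blocks]

    # -- (de)serialisation -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "total_duration": self.total_duration,
                "ad_order_seed": self.ad_order_seed,
                "blocks": [asdict(b) for b in self.blocks],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionTimeline":
        d = json.loads(text)
        blocks = [
            StimulusBlock(
                kind=b["kind"],
                onset=b["onset"],
                duration=b["duration"],
                ad_id=b.get("ad_id"),
                brand_windows=tuple(tuple(w) for w in b.get("brand_windows", ())),
            )
            for b in d["blocks"]
        ]
        return cls(d["total_duration"], blocks, d.get("ad_order_seed", 0))


@dataclass
class SessionConfig:
    """Segment lengths of the session layout.

    ``documentary_s`` gives the documentary segments in order: the opening
    stretch before the first ad block, the fillers between blocks, and the
    closing tail (``n_blocks + 1`` entries).  All nine ads share one duration.
    """

    documentary_s: tuple[float, ...] = (420.0, 390.0, 390.0, 60.0)
    ad_duration_s: float = 60.0
    ads: tuple[AdSpec, ...] = DEFAULT_ADS
    brand_windows_rel: tuple[tuple[float, float], ...] = ((10.0, 15.0), (-5.0, 0.0))
    """Brand exposure windows relative to ad onset; negative values anchor to
    the ad end (a mid-spot product shot and the closing brand card)."""

    @classmethod
    def compact(cls) -> "SessionConfig":
        """Shortest layout satisfying the structural invariants (~20 min).

        Used for simulation studies where the full half-hour session adds
        nothing but documentary filler.
        """
        return cls(documentary_s=(420.0, 120.0, 120.0, 30.0))


def _resolve_brand_windows(
    cfg: SessionConfig, onset: float, duration: float
) -> tuple[tuple[float, float], ...]:
    out = []
    for lo, hi in cfg.brand_windows_rel:
        a = onset + (lo if lo >= 0 else duration + lo)
        b = onset + (hi if hi > 0 else duration + hi)
        a, b = max(a, onset), min(b, onset + duration)
        if a < b:
            out.append((a, b))
    return tuple(out)


def generate_timeline(config: SessionConfig | None = None, seed: int = 0) -> SessionTimeline:
    """Lay out a session; ad-to-slot assignment is a seeded permutation.

    The nine commercials are permuted across the nine slots so that
    presentation order cannot act as a confound.

    Raises ``ValueError`` if the configured segments cannot satisfy the
    baseline/onset invariants.
    """
    import numpy as np

    cfg = config or SessionConfig()
    if len(cfg.documentary_s) != N_AD_BLOCKS + 1:
        raise ValueError("need n_blocks + 1 documentary segments")
    n_ads = N_AD_BLOCKS * ADS_PER_BLOCK
    if len(cfg.ads) != n_ads:
        raise ValueError(f"need exactly {n_ads} ads")
    if len({a.ad_id for a in cfg.ads}) != n_ads:
        raise ValueError("ad ids must be distinct")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_ads)
    ads = [cfg.ads[i] for i in order]

    blocks: list[StimulusBlock] = []
    t = 0.0
    k = 0
    for i in range(N_AD_BLOCKS):
        doc = cfg.documentary_s[i]
        blocks.append(StimulusBlock("documentary", t, doc))
        t += doc
        for _ in range(ADS_PER_BLOCK):
            bw = _resolve_brand_windows(cfg, t, cfg.ad_duration_s)
            blocks.append(
                StimulusBlock("ad", t, cfg.ad_duration_s, ad_id=ads[k].ad_id, brand_windows=bw)
            )
            t += cfg.ad_duration_s
            k += 1
    blocks.append(StimulusBlock("documentary", t, cfg.documentary_s[-1]))
    t += cfg.documentary_s[-1]
    return SessionTimeline(total_duration=t, blocks=blocks, ad_order_seed=seed)
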