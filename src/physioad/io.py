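"""File interchange: per-signal CSVs with a JSON timeline sidecar, feature
tables as CSV, and ARFF (nominal class last) for Weka interoperability."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import FeatureTable
from .session import SessionTimeline
from .synthetic import SignalBundle

__all__ = [
    "write_bundle",
    "read_bundle",
    "write_feature_table",
    "read_feature_table",
    "dump_arff",
    "load_arff",
]


def write_bundle(directory: str | Path, bundle: SignalBundle, subject_id: str) -> None:
    """One CSV per signal (columns: time_s, channel...) + timeline JSON."""
    d = Path(directory) / subject_id
    d.mkdir(parents=True, exist_ok=True)
    (d / "timeline.json").write_text(bundle.timeline.to_json())
    if bundle.eeg is not None:
        t = np.arange(bundle.eeg.shape[1]) / bundle.fs_eeg
        df = pd.DataFrame(bundle.eeg.T, columns=list(bundle.channels))
        df.insert(0, "time_s", t)
        df.to_csv(d / "eeg.csv", index=False, float_format="%.4f")
    for name, trace, fs in (
        ("ecg", bundle.ecg, bundle.fs_ecg),
        ("gsr", bundle.gsr, bundle.fs_aux),
        ("rsp", bundle.rsp, bundle.fs_aux),
    ):
        if trace is None:
            continue
        t = np.arange(len(trace)) / fs
        pd.DataFrame({"time_s": t, name: trace}).to_csv(
            d / f"{name}.csv", index=False, float_format="%.6f"
        )


def read_bundle(directory: str | Path, subject_id: str) -> SignalBundle:
    d = Path(directory) / subject_id
    timeline = SessionTimeline.from_json((d / "timeline.json").read_text())
    bundle = SignalBundle(timeline=timeline)

    def fs_of(t: np.ndarray) -> int:
        return int(round(1.0 / np.median(np.diff(t))))

    if (d / "eeg.csv").exists():
        df = pd.read_csv(d / "eeg.csv")
        bundle.fs_eeg = fs_of(df["time_s"].to_numpy())
        bundle.channels = tuple(c for c in df.columns if c != "time_s")
        bundle.eeg = df[list(bundle.channels)].to_numpy().T.astype(np.float32)
    for name in ("ecg", "gsr", "rsp"):
        p = d / f"{name}.csv"
        if p.exists():
            df = pd.read_csv(p)
            fs = fs_of(df["time_s"].to_numpy())
            if name == "ecg":
                bundle.fs_ecg = fs
            else:
                bundle.fs_aux = fs
            setattr(bundle, name, df[name].to_numpy())
    return bundle


def write_feature_table(path: str | Path, table: FeatureTable) -> None:
    df = table.X.copy()
    df["label"] = table.y
    df.to_csv(path)


def read_feature_table(path: str | Path, variant: str = "") -> FeatureTable:
    df = pd.read_csv(path, index_col=[0, 1])
    y = df.pop("label")
    return FeatureTable(df, y, variant)


# ---------------------------------------------------------------------------
# ARFF
# ---------------------------------------------------------------------------

def _safe(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_+./-]", "_", str(name))


def dump_arff(path: str | Path, table: FeatureTable, relation: str | None = None) -> None:
    """Write the table as ARFF with the nominal class attribute last."""
    classes = sorted(table.y.unique())
    lines = [f"@relation {_safe(relation or table.variant or 'features')}", ""]
    for col in table.X.columns:
        lines.append(f"@attribute {_safe(col)} numeric")
    lines.append("@attribute class {" + ",".join(_safe(c) for c in classes) + "}")
    lines.append("")
    lines.append("@data")
    for (_, row), label in zip(table.X.iterrows(), table.y):
        cells = ["?" if not np.isfinite(v) else repr(float(v)) for v in row]
        lines.append(",".join(cells + [_safe(label)]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_arff(path: str | Path, variant: str = "") -> FeatureTable:
    """Read back an ARFF file written by :func:`dump_arff`."""
    attrs: list[str] = []
    data: list[list[float]] = []
    labels: list[str] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@attribute"):
            name = line.split(None, 2)[1]
            attrs.append(name)
        elif low.startswith("@data"):
            in_data = True
        elif in_data:
            cells = line.split(",")
            labels.append(cells[-1])
            data.append([float("nan") if c == "?" else float(c) for c in cells[:-1]])
    X = pd.DataFrame(data, columns=attrs[:-1])
    X.index = pd.MultiIndex.from_tuples(
        [(f"row{i}", "") for i in range(len(X))], names=["subject", "ad"]
    )
    y = pd.Series(labels, index=X.index, name="label")
    return FeatureTable(X, y, variant)
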