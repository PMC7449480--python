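"""Delimited-text readers and writers.

All on-disk artifacts are plain TSV (or JSON for split plans): epochs as
one sample per row with a commented header, cohort manifests, feature
tables, annotation files and rankings.  The formats are deliberately
trivial so recordings from other acquisition chains can be converted
with a one-liner.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .cohort import EpochedSignal
from .evaluation import SplitPlan
from .feature_selection import FeatureRanking

__all__ = [
    "write_epoch",
    "read_epoch",
    "write_manifest",
    "read_manifest",
    "write_feature_table",
    "read_feature_table",
    "read_annotations",
    "write_split_plan",
    "read_split_plan",
    "write_ranking",
]

PathLike = Union[str, Path]


def write_epoch(path: PathLike, epoch: EpochedSignal) -> None:
    """One sample per row; labels in '#key=value' header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#sampling_rate_hz={epoch.sampling_rate}\n")
        fh.write(f"#patient_id={epoch.patient_id}\n")
        fh.write(f"#event={epoch.event_label}\n")
        fh.write(f"#state={epoch.state}\n")
        fh.write(f"#channel={epoch.channel_label}\n")
        fh.write("amplitude_uv\n")
        np.savetxt(fh, epoch.samples, fmt="%.6f")


def read_epoch(path: PathLike) -> EpochedSignal:
    meta = {}
    path = Path(path)
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        samples = np.loadtxt(fh, skiprows=1)
    return EpochedSignal(
        samples=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        patient_id=meta["patient_id"],
        event_label=meta["event"],
        state=meta["state"],
        channel_label=meta.get("channel", ""),
    )


def write_manifest(path: PathLike, rows: Sequence[dict]) -> None:
    """Cohort manifest: patient_id, event, state, file."""
    pd.DataFrame(rows, columns=["patient_id", "event", "state", "file"]).to_csv(
        path, sep="\t", index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_feature_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotations(path: PathLike) -> pd.DataFrame:
    """Annotation table: patient_id, event, last_response_time_s,
    first_no_response_time_s."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "event", "last_response_time_s",
                "first_no_response_time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns {sorted(missing)}")
    return df


def write_split_plan(path: PathLike, plan: SplitPlan) -> None:
    Path(path).write_text(json.dumps(
        {"working": plan.working, "held_back": plan.held_back}, indent=2))


def read_split_plan(path: PathLike) -> SplitPlan:
    data = json.loads(Path(path).read_text())
    return SplitPlan(working=list(data["working"]),
                     held_back=list(data["held_back"]))


def write_ranking(path: PathLike, ranking: FeatureRanking) -> None:
    ranking.table.to_csv(path, sep="\t", index=False)
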