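"""Readers and writers for cohort data and numeric intermediates.

On-disk layout: the subject manifest is a CSV, each subject's ROI time
series a TSV whose header row carries the ROI labels, and numeric
intermediates live in a compressed NumPy array container with named entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "FormatError",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "save_arrays",
    "load_arrays",
    "save_json",
    "load_json",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "illness_duration",
    "mean_fd",
    "max_fd",
]


class FormatError(ValueError):
    """Malformed on-disk input (ragged rows, non-numeric cells, bad labels)."""


@dataclass
class RoiTimeSeries:
    """One subject's T x m ROI time-series matrix with acquisition metadata."""

    subject_id: str
    data: np.ndarray  # T x m, BOLD-like arbitrary units
    tr: float  # seconds
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"{self.subject_id}: time series must be 2-D")
        t, m = self.data.shape
        if t < 2 or m < 2:
            raise FormatError(f"{self.subject_id}: need T >= 2 and m >= 2, got {t}x{m}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise FormatError(
                f"{self.subject_id}: non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if self.tr <= 0:
            raise FormatError(f"{self.subject_id}: TR must be positive, got {self.tr}")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i + 1:03d}" for i in range(m)]
        if len(self.roi_labels) != m:
            raise FormatError(
                f"{self.subject_id}: {len(self.roi_labels)} labels for {m} columns"
            )
        if len(set(self.roi_labels)) != m:
            seen: set[str] = set()
            dup = next(l for l in self.roi_labels if l in seen or seen.add(l))
            raise FormatError(f"{self.subject_id}: duplicate ROI label {dup!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def read_timeseries(path: str | Path, tr: float, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a TSV time series (header row = ROI labels) into a validated object.

    Errors name the offending row/column so malformed exports are locatable.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        if len(labels) != len(set(labels)):
            raise FormatError(f"{path.name}: duplicate ROI label in header")
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(labels):
                raise FormatError(
                    f"{path.name}: row {lineno} has {len(cells)} cells, expected {len(labels)}"
                )
            parsed = []
            for col, cell in enumerate(cells):
                try:
                    value = float(cell)
                except ValueError:
                    value = np.nan
                if not np.isfinite(value):
                    raise FormatError(
                        f"{path.name}: non-numeric cell at row {lineno}, "
                        f"column {col} ({labels[col]!r}): {cell!r}"
                    )
                parsed.append(value)
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path.name}: no data rows")
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeSeries(subject_id=sid, data=np.asarray(rows, dtype=float), tr=tr, roi_labels=labels)


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(ts.roi_labels) + "\n")
        for row in ts.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def save_arrays(path: str | Path, **arrays: np.ndarray) -> None:
    """Save named numeric intermediates to one compressed container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)


def load_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path, allow_pickle=False) as data:
        return {k: data[k] for k in data.files}


def save_json(obj: object, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def load_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)
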