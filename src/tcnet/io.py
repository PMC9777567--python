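"""File I/O and the ROI time-series extraction pipeline.

Covers: reading/writing time-series TSV/CSV, atlas lookup tables, NIfTI
label volumes; per-region voxel averaging of a 4D image; normalisation and
subsampling; subject averaging; and run-metadata sidecars.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .data import TimeSeriesMatrix, ValidationError, zscore_columns

__all__ = [
    "AtlasLookup",
    "read_timeseries",
    "write_timeseries",
    "extract_roi_timeseries",
    "normalize_and_subsample",
    "group_average",
    "write_metadata_sidecar",
]


@dataclass
class AtlasLookup:
    """Region id -> (name, group/lobe) mapping; id 0 (background) excluded."""

    table: pd.DataFrame  # columns: id, name, group

    def __post_init__(self) -> None:
        required = {"id", "name", "group"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"lookup needs columns {sorted(required)}")
        self.table = self.table.copy()
        self.table["id"] = self.table["id"].astype(int)
        if (self.table["id"] <= 0).any():
            raise ValidationError("region ids must be positive (0 = background)")
        if self.table["id"].duplicated().any():
            raise ValidationError("duplicate region ids")
        self.table = self.table.sort_values("id").reset_index(drop=True)

    @property
    def ids(self) -> list[int]:
        return self.table["id"].tolist()

    def name_of(self, region_id: int) -> str:
        return str(self.table.set_index("id").loc[region_id, "name"])

    def group_of(self, region_id: int) -> str:
        return str(self.table.set_index("id").loc[region_id, "group"])

    @classmethod
    def read_tsv(cls, path) -> "AtlasLookup":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_timeseries(path, sep: str | None = None) -> TimeSeriesMatrix:
    return TimeSeriesMatrix.read_tsv(path, sep=sep)


def write_timeseries(ts: TimeSeriesMatrix, path, sep: str = "\t") -> None:
    ts.write_tsv(path, sep=sep)


def _as_array(img) -> np.ndarray:
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata())
    return np.asarray(img, dtype=float)


def extract_roi_timeseries(image4d, labels3d, lookup: AtlasLookup) -> TimeSeriesMatrix:
    """Average the 4D signal over each labeled region.

    Per region: uniform (voxel-count weighted) mean over all voxels carrying
    that label, at every time point.  Columns are ordered by ascending
    region id and named from the lookup; regions listed in the lookup but
    absent from the label volume are skipped with a warning.
    """
    data = _as_array(image4d)
    labels = np.asarray(_as_array(labels3d)).astype(int)
    if data.ndim != 4:
        raise ValidationError("image must be 4-D (x, y, z, t)")
    if labels.shape != data.shape[:3]:
        raise ValidationError(
            f"label shape {labels.shape} != image spatial shape {data.shape[:3]}"
        )
    flat = data.reshape(-1, data.shape[3])
    lab = labels.reshape(-1)
    cols, names = [], []
    for rid in lookup.ids:
        mask = lab == rid
        if not mask.any():
            warnings.warn(f"region {rid} ({lookup.name_of(rid)}) absent from label volume; omitted")
            continue
        cols.append(flat[mask].mean(axis=0))
        names.append(lookup.name_of(rid))
    if not cols:
        raise ValidationError("no lookup region present in the label volume")
    return TimeSeriesMatrix(np.column_stack(cols), names)


def normalize_and_subsample(ts: TimeSeriesMatrix, subsample_factor: int = 1) -> TimeSeriesMatrix:
    """Z-score each column, then keep every ``subsample_factor``-th row."""
    if int(subsample_factor) != subsample_factor or subsample_factor < 1:
        raise ValidationError("subsample_factor must be an integer >= 1")
    bad = ts.constant_columns()
    if bad:
        raise ValidationError(f"constant column(s): {bad}")
    vals = zscore_columns(ts.values)[:: int(subsample_factor)]
    step = None
    if ts.sampling_step is not None:
        step = ts.sampling_step * subsample_factor
    return TimeSeriesMatrix(vals, list(ts.names), step)


def group_average(series: list[TimeSeriesMatrix]) -> TimeSeriesMatrix:
    """Element-wise mean across subjects (identical shapes and names)."""
    if not series:
        raise ValidationError("no subjects given")
    ref = series[0]
    for s in series[1:]:
        if s.values.shape != ref.values.shape:
            raise ValidationError("subject shapes differ")
        if s.names != ref.names:
            raise ValidationError("subject column names differ")
    mean = np.mean([s.values for s in series], axis=0)
    return TimeSeriesMatrix(mean, list(ref.names), ref.sampling_step)


def write_metadata_sidecar(path, *, seed=None, config: dict | None = None,
                           extra: dict | None = None) -> None:
    """JSON sidecar recording seed, config and package version for re-runs."""
    from . import __version__

    doc = {
        "tcnet_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config or {},
    }
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, default=str)
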