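"""Core data container: a samples-by-variables time-series matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class TimeSeriesMatrix:
    """Continuous multichannel time series.

    Rows are time points, columns are named variables (channels, brain
    regions, ...).  This is the universal input of the package: estimators,
    CorEx and connectivity methods all consume it.

    Parameters
    ----------
    values : (n_samples, n_vars) float array
        No missing entries allowed.
    names : sequence of str
        Unique column identifiers, one per variable.
    sampling_step : float, optional
        Sampling interval in seconds (e.g. the fMRI repetition time).
    """

    values: np.ndarray
    names: list[str] = field(default_factory=list)
    sampling_step: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array (time x variables)")
        if not self.names:
            self.names = [f"V{i}" for i in range(self.values.shape[1])]
        self.names = [str(n) for n in self.names]
        if len(self.names) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.names)} names for {self.values.shape[1]} columns"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("variable names must be unique")
        if self.values.shape[0] < 2:
            raise ValidationError("need at least 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        if self.sampling_step is not None and self.sampling_step <= 0:
            raise ValidationError("sampling_step must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def select(self, names: Sequence[str]) -> "TimeSeriesMatrix":
        idx = [self.names.index(n) for n in names]
        return TimeSeriesMatrix(self.values[:, idx], list(names), self.sampling_step)

    def constant_columns(self) -> list[str]:
        ptp = self.values.max(axis=0) - self.values.min(axis=0)
        return [n for n, p in zip(self.names, ptp) if p == 0.0]

    # ------------------------------------------------------------------ I/O
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, sampling_step: float | None = None
    ) -> "TimeSeriesMatrix":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], sampling_step)

    def write_tsv(self, path, sep: str = "\t") -> None:
        """Write as delimited text: header row of names, one row per time point.

        Floats are written with 17 significant digits so a read-back is
        value-identical.
        """
        self.to_dataframe().to_csv(path, sep=sep, index=False, float_format="%.17g")

    @classmethod
    def read_tsv(
        cls, path, sep: str | None = None, sampling_step: float | None = None
    ) -> "TimeSeriesMatrix":
        """Read a TSV/CSV with a header row of variable names."""
        if sep is None:
            sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        return cls.from_dataframe(df, sampling_step)


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def zscore_columns(values: np.ndarray, allow_constant: bool = False) -> np.ndarray:
    """Z-score each column; constant columns error unless explicitly allowed
    (then they are mapped to zeros)."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    bad = sd < 1e-15
    if bad.any() and not allow_constant:
        raise ValidationError(f"constant column(s) at indices {np.where(bad)[0].tolist()}")
    sd = np.where(bad, 1.0, sd)
    out = (values - mu) / sd
    if bad.any():
        out[:, bad] = 0.0
    return out
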