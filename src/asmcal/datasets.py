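"""Observed time-series container shared by the simulator, calibrator and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Tidy table of observations: (observable, time_d, value, sigma).

    ``sigma`` is the per-record measurement scale used for residual
    weighting; records without one get the per-observable default of
    5% of the observed range when :meth:`sigmas` is asked to fill.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    COLUMNS = ("observable", "time_d", "value", "sigma")

    def __post_init__(self):
        df = self.frame.copy()
        if "sigma" not in df.columns:
            df["sigma"] = np.nan
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        df = df[list(self.COLUMNS)]
        df["time_d"] = df["time_d"].astype(float)
        df["value"] = df["value"].astype(float)
        df["sigma"] = df["sigma"].astype(float)
        if (df["time_d"] < 0).any():
            raise ValueError("negative time in dataset")
        if not np.isfinite(df["value"]).all():
            raise ValueError("non-numeric value in dataset")
        df = df.sort_values(["observable", "time_d"], kind="mergesort")
        self.frame = df.reset_index(drop=True)

    @property
    def observables(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["observable"]))

    def __len__(self) -> int:
        return len(self.frame)

    def times(self, observable: str) -> np.ndarray:
        sel = self.frame[self.frame["observable"] == observable]
        return sel["time_d"].to_numpy()

    def values(self, observable: str) -> np.ndarray:
        sel = self.frame[self.frame["observable"] == observable]
        return sel["value"].to_numpy()

    def sigmas(self, observable: str, fill: bool = True) -> np.ndarray:
        """Per-record sigma; NaNs filled with 5% of the observable's range."""
        sel = self.frame[self.frame["observable"] == observable]
        s = sel["sigma"].to_numpy().copy()
        if fill and np.isnan(s).any():
            v = sel["value"].to_numpy()
            span = float(v.max() - v.min()) if len(v) else 0.0
            s[np.isnan(s)] = max(0.05 * span, 1e-6)
        return s

    @property
    def span(self) -> tuple[float, float]:
        t = self.frame["time_d"]
        return float(t.min()), float(t.max())

    def subset_times(self, t_min: float, t_max: float) -> "Dataset":
        df = self.frame
        keep = (df["time_d"] >= t_min) & (df["time_d"] <= t_max)
        return Dataset(df[keep].reset_index(drop=True), dict(self.meta))
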