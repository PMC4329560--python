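"""File dialects: datasets, scenario files, run configuration, report dumps.

All tabular I/O is comma-delimited UTF-8 text with '#' comment lines, so
runs stay diff-able.  Times are in days throughout (sub-cycle SBR times as
fractional days).  Configuration files are YAML; unknown keys are rejected
(strict mode) so typos surface immediately.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .calibrate import GAConfig
from .datasets import Dataset
from .model import OBSERVABLE_NAMES
from .protocol import NOAPConfig
from .scenarios import CSTRConfig, Forcing, Phase, SBRSchedule
from .sensitivity import SensitivityConfig

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_forcing",
    "load_scenario",
    "RunConfig",
    "load_config",
    "config_hash",
    "write_report",
]


# -- datasets -----------------------------------------------------------------

def read_dataset(path: str | Path, known_observables=OBSERVABLE_NAMES) -> Dataset:
    """Read (observable_name, time_d, value[, sigma]) delimited text."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    if "observable_name" in df.columns:
        df = df.rename(columns={"observable_name": "observable"})
    required = {"observable", "time_d", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns observable_name,time_d,value"
                         f"[,sigma]; found {list(df.columns)}")
    unknown = set(df["observable"]) - set(known_observables)
    if unknown:
        raise ValueError(f"{path}: unknown observable name(s) {sorted(unknown)}")
    for col in ("time_d", "value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), col].iloc[0]
            raise ValueError(f"{path}: non-numeric {col} entry {bad!r}")
        df[col] = vals
    if (df["time_d"] < 0).any():
        raise ValueError(f"{path}: negative time")
    return Dataset(df, meta={"path": str(path)})


def write_dataset(dataset: Dataset, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    df = dataset.frame.rename(columns={"observable": "observable_name"})
    if df["sigma"].isna().all():
        df = df.drop(columns=["sigma"])
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# -- forcing / scenario files -------------------------------------------------

def read_forcing(path: str | Path) -> Forcing:
    """2-column delimited text (time_d, value) with '#' comments."""
    df = pd.read_csv(path, comment="#", header=None, names=["time_d", "value"],
                     skip_blank_lines=True)
    # tolerate a header row
    df = df[pd.to_numeric(df["time_d"], errors="coerce").notna()]
    return Forcing(df["time_d"].astype(float).to_numpy(),
                   df["value"].astype(float).to_numpy())


def _strict_keys(d: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown key(s) {sorted(unknown)}")


def load_scenario(source: str | Path | Mapping, base_dir: Path | None = None):
    """Build an SBRSchedule or CSTRConfig from a YAML file or mapping.

    SBR dialect::

        kind: sbr
        volume0: 7.0
        phases:
          - {kind: feed, duration_d: 0.002083, volume: 7.0,
             composition: {S_S: 250.0, ...}}
          - {kind: aerobic, duration_d: 0.1667, do: 2.0}   # or do_file: path
          ...

    CSTR dialect::

        kind: cstr
        volume: 4.0
        flow: 8.0
        srt: 12.0
        influent: {S_S: 180.0, ...}
        do: 0.5           # or do_file: path
    """
    if isinstance(source, (str, Path)):
        base_dir = Path(source).parent
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
        base_dir = base_dir or Path(".")
    kind = data.get("kind")
    if kind == "sbr":
        _strict_keys(data, {"kind", "volume0", "phases"}, "scenario")
        phases = []
        for i, ph in enumerate(data["phases"]):
            _strict_keys(ph, {"kind", "duration_d", "do", "do_file", "volume",
                              "composition", "react"}, f"phase {i}")
            do = ph.get("do")
            if "do_file" in ph:
                do = read_forcing(base_dir / ph["do_file"])
            phases.append(Phase(kind=ph["kind"], duration=float(ph["duration_d"]),
                                do=do, volume=float(ph.get("volume", 0.0)),
                                composition=ph.get("composition"),
                                react=bool(ph.get("react", True))))
        return SBRSchedule(phases=tuple(phases), volume0=float(data["volume0"]))
    if kind == "cstr":
        _strict_keys(data, {"kind", "volume", "flow", "srt", "influent",
                            "do", "do_file", "clarifier_volume"}, "scenario")
        do = data.get("do", 0.5)
        if "do_file" in data:
            do = read_forcing(base_dir / data["do_file"])
        return CSTRConfig(volume=float(data["volume"]), flow=float(data["flow"]),
                          srt=float(data["srt"]), influent=data.get("influent"),
                          do=do,
                          clarifier_volume=float(data.get("clarifier_volume", 0.0)))
    raise ValueError(f"scenario kind must be 'sbr' or 'cstr', got {kind!r}")


# -- run configuration --------------------------------------------------------

@dataclass
class RunConfig:
    """Fully validated run configuration with defaults filled."""

    dataset: str
    scenario: str | None = None
    model_file: str | None = None
    out_dir: str = "results"
    seed: int = 0
    verbosity: int = 1
    noap: NOAPConfig = field(default_factory=NOAPConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    gsa: SensitivityConfig = field(default_factory=SensitivityConfig)

    def normalized(self) -> dict:
        d = {
            "dataset": self.dataset,
            "scenario": self.scenario,
            "model_file": self.model_file,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "verbosity": self.verbosity,
            "noap": _dataclass_dict(self.noap),
            "ga": _dataclass_dict(self.ga),
            "gsa": _dataclass_dict(self.gsa),
        }
        return d


def _dataclass_dict(obj) -> dict:
    out = {}
    for k, v in asdict(obj).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def _build(cls, data: Mapping, where: str):
    import dataclasses

    fields = {f.name for f in dataclasses.fields(cls)}
    _strict_keys(data, fields, where)
    kwargs = dict(data)
    # nested configs inside NOAPConfig
    if cls is NOAPConfig:
        if "sens" in kwargs:
            kwargs["sens"] = _build(SensitivityConfig, kwargs["sens"], f"{where}.sens")
        for key in ("ga_trial", "ga_final"):
            if key in kwargs:
                kwargs[key] = _build(GAConfig, kwargs[key], f"{where}.{key}")
    if cls is SensitivityConfig and isinstance(kwargs.get("weights"), list):
        kwargs["weights"] = tuple(kwargs["weights"])
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (strict: unknown keys fail)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    _strict_keys(data, {"dataset", "scenario", "model_file", "out_dir", "seed",
                        "verbosity", "noap", "ga", "gsa"}, str(path))
    if "dataset" not in data:
        raise ValueError(f"{path}: missing required key 'dataset'")
    for key, cls in (("noap", NOAPConfig), ("ga", GAConfig),
                     ("gsa", SensitivityConfig)):
        if key in data:
            data[key] = _build(cls, data[key], f"{path}:{key}")
    cfg = RunConfig(**data)
    if not isinstance(cfg.seed, (int, np.integer)):
        raise ValueError(f"{path}: seed must be an integer")
    base = path.parent
    ds_path = base / cfg.dataset
    if not ds_path.exists() and not Path(cfg.dataset).exists():
        raise FileNotFoundError(f"{path}: dataset file {cfg.dataset!r} not found")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(cfg.normalized(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report: Mapping, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=default)
        fh.write("\n")
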