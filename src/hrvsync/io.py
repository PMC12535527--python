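"""File formats and run configuration.

RR logs use a minimal open CSV dialect — header ``time_s,rr_ms,flag``, one row
per beat, times in seconds from session start (the three devices are assumed
pre-synchronized; a per-subject offset can be applied at read time).  Floats
are written with ``%.3f`` so write(read(f)) round-trips up to formatting.

Run configuration is a YAML file mirroring the stage configs; unknown keys
are rejected and the fully-defaulted effective config is saved next to every
run's outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import CleaningConfig, RRSeries
from .spectral import CWTConfig, FrequencyBands

logger = logging.getLogger("hrvsync")

RR_HEADER = ["time_s", "rr_ms", "flag"]

#: filename pattern carrying identity: <subject>_<session>_<role>.csv
FNAME_RE = re.compile(r"(?P<subject>[^_]+)_(?P<session>[^_]+)_(?P<role>participant|therapist|horse)\.csv$")


def write_rr_csv(series: RRSeries, path: str | Path) -> Path:
    """Write a series in the RR-CSV dialect (%.3f floats)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": [f"{v:.3f}" for v in series.beat_time],
            "rr_ms": [f"{v:.3f}" for v in series.rr],
            "flag": series.flag,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_rr_csv(
    path: str | Path,
    role: str | None = None,
    subject_id: str | None = None,
    session_id: str | None = None,
    time_offset_s: float = 0.0,
    time_tolerance_s: float = 0.5,
) -> tuple[RRSeries, list[str]]:
    """Read an RR-CSV file into a typed series.

    Identity fields default to the ``<subject>_<session>_<role>.csv`` filename
    pattern.  Malformed rows are skipped and collected into the returned
    report; an empty file or times decreasing by more than
    ``time_tolerance_s`` are errors (small non-monotonicities are duplicate
    artifacts and are left for the cleaning stage).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    if list(raw.columns)[:2] != RR_HEADER[:2]:
        raise ValueError(f"{path}: header must start with {RR_HEADER[:2]}")
    if raw.empty:
        raise ValueError(f"{path}: empty RR log")

    report: list[str] = []
    times, rrs, flags = [], [], []
    for i, row in raw.iterrows():
        try:
            t = float(row["time_s"])
            rr = float(row["rr_ms"])
            if not np.isfinite(t) or not np.isfinite(rr) or rr <= 0:
                raise ValueError("non-finite or non-positive value")
        except (TypeError, ValueError) as exc:
            report.append(f"row {i + 2}: {exc} ({row.to_dict()})")
            continue
        times.append(t)
        rrs.append(rr)
        flags.append(row.get("flag", "ok") if isinstance(row.get("flag"), str) else "ok")
    if not times:
        raise ValueError(f"{path}: no parseable rows")
    t_arr = np.asarray(times) + time_offset_s
    if np.any(np.diff(t_arr) < -time_tolerance_s):
        raise ValueError(f"{path}: non-monotone timestamps beyond tolerance")

    m = FNAME_RE.search(path.name)
    return (
        RRSeries(
            beat_time=t_arr,
            rr=np.asarray(rrs),
            role=role or (m.group("role") if m else "participant"),
            subject_id=subject_id or (m.group("subject") if m else path.stem),
            session_id=session_id or (m.group("session") if m else ""),
            flag=np.asarray(flags, dtype=object),
        ),
        report,
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Effective configuration of a pipeline run."""

    cleaning: CleaningConfig = dataclasses.field(default_factory=CleaningConfig)
    cwt: CWTConfig = dataclasses.field(default_factory=CWTConfig)
    bands: FrequencyBands = dataclasses.field(default_factory=FrequencyBands)
    fs: float = 4.0
    z_stratum: str = "dyad"
    use_coi: bool = True
    sig_method: str = "analytic"
    alpha: float = 0.05
    seed: int = 0
    n_control: int = 4
    n_patient: int = 2
    outdir: str = "hrvsync_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        kwargs = {}
        for fld, typ in (("cleaning", CleaningConfig), ("cwt", CWTConfig), ("bands", FrequencyBands)):
            if fld in d:
                sub = d.pop(fld)
                unknown = set(sub) - {f.name for f in dataclasses.fields(typ)}
                if unknown:
                    raise ValueError(f"unknown keys in {fld}: {sorted(unknown)}")
                kwargs[fld] = typ(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Persist the fully-defaulted effective config."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
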