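"""Reading waveforms and physiology tables; writing tidy results and manifests.

Plain-text CSV is the canonical interchange format: waveforms as two-column
(time_s, mv) or single-column millivolt streams with an explicit sampling
rate, physiology panels as one row per (subject, timepoint) with a
column-name mapping isolating any source spreadsheet's layout.  XLSX panels
are supported read-only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectral import AMSASeries, SpectralConfig, WaveformRecord

log = logging.getLogger("vfwave")

__all__ = [
    "read_waveform",
    "write_waveform",
    "read_physio_table",
    "write_amsa_frames",
    "write_amsa_minutes",
    "minute_table_from_series",
    "RunConfig",
    "write_manifest",
]

_REL_TOL_SPACING = 1e-3  # tolerated relative jitter in the time column


def read_waveform(
    path: str | Path,
    fs: float | None = None,
    subject_id: str | None = None,
    t0: float = 0.0,
) -> WaveformRecord:
    """Read a waveform CSV into a :class:`WaveformRecord` (mV units).

    Two layouts are accepted: two columns (time in seconds, voltage in mV;
    header optional, fs inferred from the median spacing) or one column of
    voltages with ``fs`` given explicitly.  Rows with non-finite voltage are
    dropped with a logged count; a non-monotone time column is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, comment="#")
    # tolerate a header row of labels
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    df = df.apply(pd.to_numeric, errors="coerce")

    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        # validate the time base before dropping bad-voltage rows, so an
        # occasional rejected sample does not read as a sampling gap
        dt = np.diff(t[np.isfinite(t)])
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValueError(f"{path.name}: time column not strictly increasing at row {bad}")
        spacing = float(np.median(dt))
        if np.any(np.abs(dt - spacing) > _REL_TOL_SPACING * spacing):
            raise ValueError(f"{path.name}: non-uniform sampling (median dt {spacing:g} s)")
        keep = np.isfinite(v) & np.isfinite(t)
        dropped = int((~keep).sum())
        if dropped:
            log.warning("%s: dropped %d rows with non-finite values", path.name, dropped)
        t, v = t[keep], v[keep]
        inferred = 1.0 / spacing
        if fs is not None and abs(inferred - fs) > _REL_TOL_SPACING * fs:
            raise ValueError(
                f"{path.name}: declared fs {fs} Hz conflicts with inferred {inferred:.3f} Hz"
            )
        fs = inferred
        t0 = float(t[0])
    else:
        if fs is None:
            raise ValueError(f"{path.name}: single-column waveform requires an explicit fs")
        v = df.iloc[:, 0].to_numpy(dtype=float)
        keep = np.isfinite(v)
        dropped = int((~keep).sum())
        if dropped:
            log.warning("%s: dropped %d rows with non-finite values", path.name, dropped)
        v = v[keep]

    if v.size == 0:
        raise ValueError(f"{path.name}: no finite samples")
    return WaveformRecord(
        subject_id=subject_id or path.stem, samples=v, fs=float(fs), t0=t0
    )


def write_waveform(record: WaveformRecord, path: str | Path) -> None:
    """Write a record as two-column CSV (time_s, mv)."""
    t = record.t0 + np.arange(record.samples.size) / record.fs
    pd.DataFrame({"time_s": t, "mv": record.samples}).to_csv(path, index=False)


def read_physio_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-(subject, timepoint) physiology panel from CSV or XLSX.

    ``column_map`` maps canonical names (subject_id, timepoint, map_mmHg,
    rap_mmHg, lad_flow, cao2_mldl, cvo2_mldl, lac_a_mM, lac_v_mM,
    paco2_mmHg, pvco2_mmHg) to the file's column headers.  A mapped column
    missing from the file is an error naming it; unmapped extra columns are
    ignored with a log note.
    """
    path = Path(path)
    reader = pd.read_excel if path.suffix.lower() in {".xlsx", ".xls"} else pd.read_csv
    df = reader(path)
    if df.empty:
        raise ValueError(f"{path.name}: empty table")
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise KeyError(f"{path.name}: mapped column(s) not found: {', '.join(missing)}")
        extra = set(df.columns) - set(column_map.values())
        if extra:
            log.info("%s: ignoring unmapped columns: %s", path.name, sorted(extra))
        df = df[[src for src in column_map.values()]]
        df.columns = list(column_map.keys())
    return df


def write_amsa_frames(series: AMSASeries, path: str | Path) -> None:
    """Tidy per-frame CSV: (subject_id, center_time_s, amsa_mvhz, valid)."""
    pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "center_time_s": series.frame_times,
            "amsa_mvhz": series.frame_amsa,
            "valid": series.frame_valid,
        }
    ).to_csv(path, index=False)


def write_amsa_minutes(series_list, path: str | Path) -> None:
    """Tidy per-minute CSV over one or many subjects: (subject_id, minute, amsa_mvhz)."""
    if isinstance(series_list, AMSASeries):
        series_list = [series_list]
    frames = [
        pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "minute": s.minute_index,
                "amsa_mvhz": s.minute_amsa,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def minute_table_from_series(series_list) -> pd.DataFrame:
    """Wide subjects x minutes table of minute-mean AMSA (columns = minute ints)."""
    rows = {
        s.subject_id: pd.Series(s.minute_amsa, index=s.minute_index)
        for s in series_list
    }
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    table.columns.name = "minute"
    return table


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; YAML round-trippable."""

    seed: int = 0
    spectral: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    stats: dict = field(
        default_factory=lambda: {"alpha_tiers": [0.05, 0.001], "families": ["BL", "VF10"]}
    )
    io: dict = field(default_factory=dict)

    def spectral_config(self) -> SpectralConfig:
        return SpectralConfig(**self.spectral)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(path: str | Path, config: RunConfig, inputs=(), **extra) -> None:
    """JSON run manifest: resolved config, package version, seed, input digests."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
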