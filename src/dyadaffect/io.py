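"""On-disk layout for recordings and cohorts.

One directory per dyad containing ``manifest.json`` (dyad id, sampling
rate, segment boundaries as 0-based half-open sample indices, scenario
order and labels) plus eight CSV files ``p{1,2}_{ecg,eda,resp,temp}.csv``
with columns ``t_seconds,value``. A cohort directory holds the dyad
directories plus ``selfreport.csv`` and ``traits.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .labels import SIGNALS
from .recording import PARTICIPANTS, DyadRecording, Segment
from .preprocess import EventSeries
from .simulate import Cohort, EffectConfig, default_effect_config

__all__ = ["write_recording", "read_recording", "write_cohort", "read_cohort_tables",
           "write_events", "read_events"]


def write_recording(recording: DyadRecording, out_dir: str | Path) -> Path:
    out = Path(out_dir) / recording.dyad_id
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dyad_id": recording.dyad_id,
        "fs": recording.fs,
        "segments": [
            {"name": s.name, "start_sample": s.start_sample,
             "end_sample": s.end_sample, "label": s.label}
            for s in recording.segments
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    n = recording.n_samples
    t = np.arange(n) / recording.fs
    for p in PARTICIPANTS:
        for sig in SIGNALS:
            pd.DataFrame({"t_seconds": t, "value": recording.signals[p][sig]}).to_csv(
                out / f"{p}_{sig}.csv", index=False
            )
    return out


def read_recording(dyad_dir: str | Path) -> DyadRecording:
    dyad_dir = Path(dyad_dir)
    mpath = dyad_dir / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"no manifest.json in {dyad_dir}")
    try:
        manifest = json.loads(mpath.read_text())
        segments = [
            Segment(s["name"], int(s["start_sample"]), int(s["end_sample"]),
                    s.get("label"))
            for s in manifest["segments"]
        ]
        signals = {
            p: {
                sig: pd.read_csv(dyad_dir / f"{p}_{sig}.csv")["value"].to_numpy(float)
                for sig in SIGNALS
            }
            for p in PARTICIPANTS
        }
        return DyadRecording(
            dyad_id=manifest["dyad_id"], fs=float(manifest["fs"]),
            signals=signals, segments=segments,
        )
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed recording in {dyad_dir}: {exc}") from exc


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort.recordings:
        for rec in cohort.recordings:
            write_recording(rec, out)
    cohort.selfreport.to_csv(out / "selfreport.csv", index=False)
    cohort.traits.to_csv(out / "traits.csv", index=False)
    return out


def read_cohort_tables(cohort_dir: str | Path) -> tuple[list[DyadRecording], Cohort]:
    """Load every dyad directory plus the questionnaire tables."""
    cohort_dir = Path(cohort_dir)
    recs = [
        read_recording(d)
        for d in sorted(cohort_dir.iterdir())
        if d.is_dir() and (d / "manifest.json").exists()
    ]
    cohort = Cohort(
        recordings=recs,
        traits=pd.read_csv(cohort_dir / "traits.csv"),
        selfreport=pd.read_csv(cohort_dir / "selfreport.csv"),
        effect=default_effect_config(),
        seed=-1,
    )
    return recs, cohort


def write_events(events: EventSeries, path: str | Path) -> None:
    pd.DataFrame({
        "t_seconds": events.times,
        "amplitude": events.amplitudes,
        "interpolated": events.interpolated.astype(int),
    }).to_csv(path, index=False)


def read_events(path: str | Path, kind: str) -> EventSeries:
    df = pd.read_csv(path)
    return EventSeries(kind, df["t_seconds"].to_numpy(float),
                       df["amplitude"].to_numpy(float),
                       df["interpolated"].to_numpy() != 0)
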