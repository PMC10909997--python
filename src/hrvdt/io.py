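"""Readers and writers for the pipeline's plain-text interchange formats.

Conventions: comma-separated UTF-8 with a header row and '.' decimals; times
in seconds, intervals in ms, powers in ms^2 — units are embedded in column
names.  ECG can additionally be written as a WFDB-style plain-text header
(record name, fs, gain, channel) next to the CSV signal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import ECGRecord, RRSeries
from .synth import ResponseEvent, ResponseLog, TLX_DIMENSIONS
from .taskload import TLXResponse


# ---------------------------------------------------------------- ECG

def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": record.times, "voltage_uV": record.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_ecg_csv(path: str | Path, fs: float | None = None) -> ECGRecord:
    df = pd.read_csv(path)
    t, v = df["time_s"].to_numpy(), df["voltage_uV"].to_numpy()
    if fs is None:
        dt = np.diff(t)
        # tolerate the rounding of a 6-decimal time column
        if dt.size == 0 or np.ptp(dt) > 1e-4:
            raise ValueError("cannot infer fs from an uneven time column; pass fs")
        fs = (len(t) - 1) / float(t[-1] - t[0])
    return ECGRecord(samples=v, fs=float(round(fs, 6)))


def write_ecg_record(record: ECGRecord, path_stem: str | Path,
                     gain_uV_per_unit: float = 1.0) -> None:
    """WFDB-style text header + CSV signal (``<stem>.hea`` / ``<stem>.csv``)."""
    stem = Path(path_stem)
    name = stem.name
    n = len(record.samples)
    header = (f"{name} 1 {record.fs:g} {n}\n"
              f"{name}.csv csv {gain_uV_per_unit:g}(uV/unit) 0 0 {record.channel_label}\n")
    stem.with_suffix(".hea").write_text(header, encoding="utf-8")
    write_ecg_csv(record, stem.with_suffix(".csv"))
    if record.annotations is not None:
        pd.DataFrame({"beat_time_s": record.annotations}).to_csv(
            stem.with_suffix(".ann.csv"), index=False, float_format="%.6f")


# ---------------------------------------------------------------- RR

def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    pd.DataFrame({"rr_ms": rr.intervals, "flag": rr.flags}).to_csv(
        path, index=False, float_format="%.6f")


def read_rr_csv(path: str | Path, start_time_s: float = 0.0) -> RRSeries:
    """Rebuild an RR series from an interval CSV.

    Beat times are re-synthesized by cumulative summation from
    ``start_time_s`` (interval CSVs do not carry absolute beat times), so a
    written-then-read series preserves intervals and flags exactly and beat
    times up to that global offset.
    """
    df = pd.read_csv(path)
    iv = df["rr_ms"].to_numpy(dtype=float)
    flags = (df["flag"].to_numpy(dtype=object) if "flag" in df.columns
             else None)
    beats = start_time_s + np.concatenate(([0.0], np.cumsum(iv))) / 1000.0
    if flags is not None and np.any(flags != "normal"):
        return RRSeries(beat_times=beats, intervals=iv, flags=flags)
    return RRSeries(beat_times=beats, intervals=iv)


# ---------------------------------------------------------------- behavior

def write_response_log_csv(log: ResponseLog, path: str | Path) -> None:
    rows = [{"onset_s": e.onset, "is_target": int(e.is_target),
             "responded": int(e.responded),
             "rt_ms": e.rt_ms if e.rt_ms is not None else ""}
            for e in log.events]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_response_log_csv(path: str | Path,
                          response_window_s: float = 2.0) -> ResponseLog:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        rt = row["rt_ms"]
        rt = None if pd.isna(rt) or rt == "" else float(rt)
        events.append(ResponseEvent(onset=float(row["onset_s"]),
                                    is_target=bool(row["is_target"]),
                                    responded=bool(row["responded"]), rt_ms=rt))
    return ResponseLog(events=tuple(events), response_window_s=response_window_s)


# ---------------------------------------------------------------- TLX

def write_tlx_csv(response: TLXResponse, path: str | Path) -> None:
    rows = [{"record": "rating", "dimension": d, "value": response.ratings[d],
             "pair_a": "", "pair_b": ""} for d in TLX_DIMENSIONS]
    rows += [{"record": "choice", "dimension": chosen, "value": "",
              "pair_a": a, "pair_b": b} for (a, b), chosen in response.pair_choices]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tlx_csv(path: str | Path) -> TLXResponse:
    df = pd.read_csv(path)
    ratings = {str(r["dimension"]): int(r["value"])
               for _, r in df[df["record"] == "rating"].iterrows()}
    choices = tuple(((str(r["pair_a"]), str(r["pair_b"])), str(r["dimension"]))
                    for _, r in df[df["record"] == "choice"].iterrows())
    return TLXResponse(ratings=ratings, pair_choices=choices)


# ---------------------------------------------------------------- manifest

def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))
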