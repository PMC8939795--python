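"""Shared I/O: HDF5 time series and stimulation records, CSV/JSON tables,
provenance sidecars."""

from __future__ import annotations

import dataclasses
import json
import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .controller import ControllerConfig, StimulationRecord
from .simulate import TimeSeriesSet


def save_timeseries(path, ts: TimeSeriesSet, record: StimulationRecord | None = None):
    """Write a TimeSeriesSet (and optional StimulationRecord group) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("labels", data=np.array(ts.labels, dtype="S"))
        f.create_dataset("fs", data=ts.fs)
        f.attrs["meta"] = json.dumps(ts.meta)
        if record is not None:
            g = f.create_group("stimulation")
            g.create_dataset("stim_onsets", data=record.stim_onsets)
            g.create_dataset("waveform", data=record.waveform)
            g.create_dataset("phase_estimates", data=record.phase_estimates)
            g.create_dataset("update_times", data=record.update_times)
            g.create_dataset("gate_log", data=record.gate_log)
            g.attrs["fs"] = record.fs
            if record.config is not None:
                g.attrs["config"] = json.dumps(dataclasses.asdict(record.config))


def load_timeseries(path):
    """Read a TimeSeriesSet (and StimulationRecord, if present) from HDF5."""
    with h5py.File(path, "r") as f:
        ts = TimeSeriesSet(
            data=f["data"][()],
            labels=[s.decode() for s in f["labels"][()]],
            fs=float(f["fs"][()]),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )
        rec = None
        if "stimulation" in f:
            g = f["stimulation"]
            cfg = None
            if "config" in g.attrs:
                d = json.loads(g.attrs["config"])
                d["band"] = tuple(d["band"])
                cfg = ControllerConfig(**d)
            rec = StimulationRecord(
                stim_onsets=g["stim_onsets"][()],
                waveform=g["waveform"][()],
                fs=float(g.attrs["fs"]),
                phase_estimates=g["phase_estimates"][()],
                update_times=g["update_times"][()],
                gate_log=g["gate_log"][()],
                config=cfg,
            )
    return (ts, rec) if rec is not None else ts


def export_csv(path, ts: TimeSeriesSet) -> None:
    df = pd.DataFrame(ts.data.T, columns=ts.labels)
    df.insert(0, "time", ts.times)
    df.to_csv(path, index=False)


def burstset_frame(bursts) -> pd.DataFrame:
    return pd.DataFrame(
        [{"onset": a, "offset": b, "duration": b - a} for a, b in bursts.intervals]
    ).assign(band_low=bursts.band[0], band_high=bursts.band[1],
             threshold=bursts.threshold_value)


def plv_frame(plv) -> pd.DataFrame:
    rows = []
    n = len(plv.labels)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({"a": plv.labels[i], "b": plv.labels[j],
                         "plv": plv.values[i, j],
                         "band_low": plv.band[0], "band_high": plv.band[1]})
    return pd.DataFrame(rows)


def write_provenance(path, seed: int, config: dict | None = None) -> None:
    """JSON sidecar recording how an output file was produced."""
    payload = {
        "package": "cbgtloop",
        "version": __version__,
        "seed": seed,
        "config": config or {},
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
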