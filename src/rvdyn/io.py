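"""Delimited-text sample matrices with JSON sidecar metadata.

A patient dataset on disk is a directory with one ``meta.json`` sidecar
and one CSV sample matrix per recorded epoch (steady pacing, sinus beats,
each S1S2 train, each paced-ECG repeat).  A sample matrix has a
``time_ms`` first column and one column per channel, with a header row of
channel ids; channels within an epoch share the time base.  The sidecar
carries the sampling rate, channel descriptions (kind, region, position),
the stimulus annotations of the realised S1S2 schedule, and the patient
labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import (ElectrodeMap, PatientRecord, ProtocolEvent, SignalTrace,
                   StimulusProtocol, build_electrode_map)

_FLOAT_FMT = "%.6f"


def electrode_map_to_json(emap: ElectrodeMap) -> list[dict]:
    return [{"electrode_id": e.electrode_id, "column": e.column,
             "row": e.row, "position_mm": list(e.position_mm),
             "region": e.region, "segment": e.segment}
            for e in emap.electrodes]


def electrode_map_from_json(items: list[dict]) -> ElectrodeMap:
    return build_electrode_map(items)


def write_traces_csv(traces: dict[str, SignalTrace], path: Path) -> None:
    """Write channels sharing a time base as one sample matrix."""
    ids = sorted(traces)
    first = traces[ids[0]]
    for t in traces.values():
        if t.samples.size != first.samples.size or t.t0 != first.t0 \
                or t.fs != first.fs:
            raise ValueError("channels in one epoch must share the "
                             "time base")
    data = {"time_ms": first.times_ms}
    data.update({cid: traces[cid].samples for cid in ids})
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traces_csv(path: Path, fs: float) -> dict[str, SignalTrace]:
    df = pd.read_csv(path)
    t0 = float(df.time_ms.iloc[0])
    return {c: SignalTrace(c, fs, t0, df[c].to_numpy())
            for c in df.columns if c != "time_ms"}


def _stimuli_json(record: PatientRecord) -> list[dict]:
    out = []
    for ev in record.protocol.events:
        out.append({"train": ev.train, "type": "S2", "t_ms": 0.0,
                    "coupling_ms": ev.coupling_ms,
                    "captured": bool(ev.captured)})
        out.append({"train": ev.train, "type": "S1",
                    "t_ms": -ev.coupling_ms, "coupling_ms": None})
    return out


def write_record(record: PatientRecord, outdir: Path | str) -> Path:
    """Write a patient record as CSV epochs plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    epochs: list[dict] = []

    def dump(traces: dict[str, SignalTrace], name: str, kind: str,
             extra: dict | None = None) -> None:
        if not traces:
            return
        fname = f"{name}.csv"
        write_traces_csv(traces, outdir / fname)
        fs = next(iter(traces.values())).fs
        epochs.append({"name": name, "file": fname, "kind": kind,
                       "fs_hz": fs, **(extra or {})})

    by_rep: dict[int, dict] = {}
    for (rep, eid), tr in record.steady_traces.items():
        by_rep.setdefault(rep, {})[eid] = tr
    for rep, traces in sorted(by_rep.items()):
        dump(traces, f"steady_{rep}", "egm")
    by_rep = {}
    for (rep, eid), tr in record.sinus_traces.items():
        by_rep.setdefault(rep, {})[eid] = tr
    for rep, traces in sorted(by_rep.items()):
        dump(traces, f"sinus_{rep}", "egm")
    by_train: dict[int, dict] = {}
    for (train, eid), tr in record.train_traces.items():
        by_train.setdefault(train, {})[eid] = tr
    for train, traces in sorted(by_train.items()):
        dump(traces, f"train_{train:03d}", "egm",
             {"train": train,
              "coupling_ms": record.train_couplings[train]})
    by_state_rep: dict[tuple, dict] = {}
    for (lead, state, rep), tr in record.ecg_traces.items():
        by_state_rep.setdefault((state, rep), {})[lead] = tr
    for (state, rep), traces in sorted(by_state_rep.items()):
        dump(traces, f"ecg_{state}_{rep}", "ecg", {"state": state,
                                                   "repeat": rep})

    meta = {
        "labels": {"patient_id": record.patient_id, "group": record.group},
        "channels": electrode_map_to_json(record.electrode_map),
        "stimuli": _stimuli_json(record),
        "protocol": {"verp_ms": record.protocol.verp_ms,
                     "pre_verp_ci_ms": record.protocol.pre_verp_ci_ms,
                     "s1_cycle_ms": record.protocol.s1_cycle_ms,
                     "s1_per_train": record.protocol.s1_per_train},
        "epochs": epochs,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1,
                                                 sort_keys=True))
    return outdir


def read_record(indir: Path | str) -> PatientRecord:
    """Read a patient record written by :func:`write_record`."""
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    events = [ProtocolEvent(s["train"], s["coupling_ms"],
                            bool(s["captured"]))
              for s in meta["stimuli"] if s["type"] == "S2"]
    protocol = StimulusProtocol(
        events=events, verp_ms=meta["protocol"]["verp_ms"],
        pre_verp_ci_ms=meta["protocol"]["pre_verp_ci_ms"],
        s1_cycle_ms=meta["protocol"]["s1_cycle_ms"],
        s1_per_train=meta["protocol"]["s1_per_train"])
    record = PatientRecord(
        patient_id=meta["labels"]["patient_id"],
        group=meta["labels"]["group"],
        electrode_map=electrode_map_from_json(meta["channels"]),
        protocol=protocol)
    for ep in meta["epochs"]:
        traces = read_traces_csv(indir / ep["file"], ep["fs_hz"])
        name = ep["name"]
        if name.startswith("steady_"):
            rep = int(name.split("_")[1])
            for eid, tr in traces.items():
                record.steady_traces[(rep, eid)] = tr
        elif name.startswith("sinus_"):
            rep = int(name.split("_")[1])
            for eid, tr in traces.items():
                record.sinus_traces[(rep, eid)] = tr
        elif name.startswith("train_"):
            train = ep["train"]
            record.train_couplings[train] = ep["coupling_ms"]
            for eid, tr in traces.items():
                record.train_traces[(train, eid)] = tr
        elif name.startswith("ecg_"):
            for lead, tr in traces.items():
                record.ecg_traces[(lead, ep["state"], ep["repeat"])] = tr
    return record
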