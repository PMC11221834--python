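"""Session directory format.

One directory per session:

* ``lfp_header.txt`` — plain-text header (fs, n_samples, n_tetrodes, units)
* ``lfp_tet<k>.f32`` — flat binary float32 LFP per tetrode, µV
* ``spikes.csv`` — columnar marked spikes (tetrode, time_s, mark1..mark4)
* ``trials.jsonl`` / ``ground_truth.jsonl`` / ``state_intervals.jsonl`` —
  line-delimited records
* ``config.json`` — generator and task configuration
* ``position.csv`` — linearized trajectory (optional)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import MarkedSpikeTrain, RippleSeries, SwrEvent
from .synth import GroundTruthEvent, SessionConfig, SizeDistribution
from .task import SyntheticSession, TaskConfig, Trial


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, set)):
        return [_jsonable(v) for v in x]
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _jsonable(dataclasses.asdict(x))
    if isinstance(x, float) and np.isnan(x):
        return None
    return x


def _trial_record(trial: Trial) -> dict:
    d = dataclasses.asdict(trial)
    d["trigger_event"] = (
        None
        if trial.trigger_event is None
        else {
            "t_start": trial.trigger_event.t_start,
            "t_end": trial.trigger_event.t_end,
            "t_peak": trial.trigger_event.t_peak,
            "size": trial.trigger_event.size,
            "source": trial.trigger_event.source,
        }
    )
    return _jsonable(d)


def _trial_from_record(d: dict) -> Trial:
    trig = d.pop("trigger_event", None)
    pre_speed = d.pop("pre_speed", None)
    post_speed = d.pop("post_speed", None)
    d = {k: (np.nan if v is None else v) for k, v in d.items()}
    trial = Trial(**d)
    if trig is not None:
        trial.trigger_event = SwrEvent(**trig)
    trial.pre_speed = None if pre_speed is None else np.asarray(pre_speed)
    trial.post_speed = None if post_speed is None else np.asarray(post_speed)
    return trial


def write_session(session: SyntheticSession, path: str | Path) -> Path:
    """Serialize a session to a directory (creates it)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lfp = session.lfp
    (path / "lfp_header.txt").write_text(
        f"fs {lfp.fs}\nn_samples {lfp.n_samples}\n"
        f"n_tetrodes {lfp.n_tetrodes}\nunits uV\nt0 {lfp.t0}\n"
    )
    for k in range(lfp.n_tetrodes):
        lfp.data[k].astype(np.float32).tofile(path / f"lfp_tet{k}.f32")
    rows = []
    for train in session.spikes or []:
        for i in range(train.n_spikes):
            rows.append(
                [train.tetrode, train.times[i], *train.marks[i].tolist()]
            )
    pd.DataFrame(
        rows, columns=["tetrode", "time_s", "mark1", "mark2", "mark3", "mark4"]
    ).to_csv(path / "spikes.csv", index=False)
    with open(path / "trials.jsonl", "w") as fh:
        for trial in session.trials:
            fh.write(json.dumps(_trial_record(trial), sort_keys=True) + "\n")
    with open(path / "ground_truth.jsonl", "w") as fh:
        for ev in session.ground_truth:
            fh.write(json.dumps(_jsonable(dataclasses.asdict(ev)), sort_keys=True) + "\n")
    with open(path / "state_intervals.jsonl", "w") as fh:
        for t0, t1, state in session.state_intervals:
            fh.write(json.dumps({"t_start": t0, "t_end": t1, "state": state}) + "\n")
    cfg = _jsonable(dataclasses.asdict(session.config))
    (path / "config.json").write_text(
        json.dumps(
            {
                "session": cfg,
                "task": _jsonable(dataclasses.asdict(session.task_config)),
                "day": session.day,
            },
            indent=2,
            sort_keys=True,
        )
    )
    if session.position is not None:
        pd.DataFrame(
            {
                "time_s": session.position["times"],
                "linear_cm": session.position["linear"],
            }
        ).to_csv(path / "position.csv", index=False)
    return path


def read_session(path: str | Path) -> SyntheticSession:
    """Load a serialized session directory."""
    path = Path(path)
    header = dict(
        line.split(maxsplit=1)
        for line in (path / "lfp_header.txt").read_text().splitlines()
    )
    fs = float(header["fs"])
    n_tet = int(header["n_tetrodes"])
    data = np.stack(
        [
            np.fromfile(path / f"lfp_tet{k}.f32", dtype=np.float32).astype(np.float64)
            for k in range(n_tet)
        ]
    )
    lfp = RippleSeries(data, fs, float(header.get("t0", 0.0)))
    spikes = None
    spikes_df = pd.read_csv(path / "spikes.csv")
    if len(spikes_df):
        spikes = []
        for tet in range(n_tet):
            sub = spikes_df[spikes_df["tetrode"] == tet]
            spikes.append(
                MarkedSpikeTrain(
                    tet,
                    sub["time_s"].to_numpy(),
                    sub[["mark1", "mark2", "mark3", "mark4"]].to_numpy(),
                )
            )
    trials = [
        _trial_from_record(json.loads(line))
        for line in (path / "trials.jsonl").read_text().splitlines()
    ]
    gt = []
    for line in (path / "ground_truth.jsonl").read_text().splitlines():
        d = json.loads(line)
        gt.append(GroundTruthEvent(**d))
    intervals = [
        (r["t_start"], r["t_end"], r["state"])
        for r in map(json.loads, (path / "state_intervals.jsonl").read_text().splitlines())
    ]
    meta = json.loads((path / "config.json").read_text())
    scfg = meta["session"]
    scfg["swr_size_distribution"] = SizeDistribution(**scfg["swr_size_distribution"])
    scfg["ripple_freq_range"] = tuple(scfg["ripple_freq_range"])
    scfg["swr_duration_range"] = tuple(scfg["swr_duration_range"])
    task = meta["task"]
    for key in ("repeats_per_goal", "timeout_range", "bootstrap_delay_range",
                "control_delay_range"):
        task[key] = tuple(task[key])
    position = None
    if (path / "position.csv").exists():
        pos = pd.read_csv(path / "position.csv")
        position = {
            "times": pos["time_s"].to_numpy(),
            "linear": pos["linear_cm"].to_numpy(),
        }
    return SyntheticSession(
        lfp=lfp,
        trials=trials,
        ground_truth=gt,
        state_intervals=intervals,
        config=SessionConfig(**scfg),
        task_config=TaskConfig(**task),
        spikes=spikes,
        position=position,
        day=meta.get("day", 1),
    )


def events_to_frame(events: list[SwrEvent]) -> pd.DataFrame:
    """Columnar event table (t_start, t_end, t_peak, size, length, source)."""
    return pd.DataFrame(
        [
            {
                "t_start": e.t_start,
                "t_end": e.t_end,
                "t_peak": e.t_peak,
                "size": e.size,
                "length": e.length,
                "source": e.source,
            }
            for e in events
        ]
    )


def frame_to_events(df: pd.DataFrame) -> list[SwrEvent]:
    return [
        SwrEvent(
            t_start=row.t_start,
            t_end=row.t_end,
            t_peak=row.t_peak,
            size=row.size,
            source=getattr(row, "source", "offline"),
        )
        for row in df.itertuples()
    ]
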