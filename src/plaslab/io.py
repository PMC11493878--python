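"""Plain-text interchange formats.

Events and stimulation markers travel as tab-separated tables, hypnograms
as one-stage-per-line text (30-s epochs), cohort tables as CSV, configs as
YAML, and recordings as npz + JSON sidecar (channel metadata, rate, night,
generator seed). EDF import is available through mne when an EDF file is
supplied.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from plaslab.detector import StimulationMarker
from plaslab.synth import Recording, SynthConfig

MARKER_COLUMNS = ["onset_s", "condition", "night", "delay_ms"]
EVENT_COLUMNS = ["onset_s", "kind", "amplitude"]


def write_markers(markers, path):
    df = pd.DataFrame([{"onset_s": m.time_s, "condition": m.condition,
                        "night": m.night, "delay_ms": m.delay_ms}
                       for m in markers], columns=MARKER_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_markers(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [StimulationMarker(time_s=float(r.onset_s), condition=str(r.condition),
                              night=str(r.night), delay_ms=float(r.delay_ms))
            for r in df.itertuples()]


def write_events(events: pd.DataFrame, path):
    out = events.rename(columns={"time": "onset_s"})[
        [c for c in EVENT_COLUMNS if c in events.columns or c == "onset_s"]]
    out.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"onset_s": "time"})


def write_hypnogram(hypnogram, path):
    Path(path).write_text("\n".join(str(s) for s in hypnogram) + "\n")


def read_hypnogram(path) -> np.ndarray:
    return np.array(Path(path).read_text().split())


def write_config(config: SynthConfig, path):
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def read_config(path) -> SynthConfig:
    return SynthConfig(**yaml.safe_load(Path(path).read_text()))


def save_recording(rec: Recording, path, seed=None):
    """npz container + .json sidecar with axis metadata and the seed."""
    path = Path(path)
    np.savez_compressed(path, data=rec.data, positions=rec.channel_positions)
    meta = {"rate": rec.rate, "night": rec.night,
            "channel_names": list(rec.channel_names),
            "hypnogram": [str(s) for s in rec.hypnogram],
            "events": rec.events.to_dict(orient="list"),
            "seed": seed}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_recording(path) -> Recording:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return Recording(data=arrays["data"], rate=float(meta["rate"]),
                     channel_names=list(meta["channel_names"]),
                     channel_positions=arrays["positions"],
                     hypnogram=np.array(meta["hypnogram"]),
                     events=pd.DataFrame(meta["events"]),
                     night=meta["night"])


def read_edf(path, hypnogram_path=None, night="BL") -> Recording:
    """Load a (real or exported) EDF recording through mne; positions fall
    back to a spiral layout when the montage carries none."""
    import mne

    from plaslab import layout as _layout

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts → µV
    names = list(raw.ch_names)
    montage = raw.get_montage()
    if montage is not None:
        pos_map = montage.get_positions()["ch_pos"]
        pos = np.array([pos_map[ch] for ch in names])
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    else:
        _, pos = _layout.spiral_layout(len(names))
    hypno = (read_hypnogram(hypnogram_path) if hypnogram_path is not None
             else np.array(["W"] * int(data.shape[1] / raw.info["sfreq"] // 30)))
    return Recording(data=data.astype(np.float32), rate=float(raw.info["sfreq"]),
                     channel_names=names, channel_positions=pos,
                     hypnogram=hypno,
                     events=pd.DataFrame(columns=["kind", "time", "amplitude"]),
                     night=night)
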