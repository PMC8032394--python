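"""Readers and writers for the pipeline's on-disk formats.

Event streams, trial tables and region-count tables travel as tidy TSV/CSV;
epoch schedules and generator truth as YAML; multi-channel glomerulus images
as multi-page TIFF with a JSON sidecar naming the channels and carrying the
ROI masks (packed as extra pages).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import Epoch, EpochSchedule, EventStream, SpikeTrain
from .imaging import GlomerulusImage

__all__ = [
    "write_event_stream", "read_event_stream",
    "write_schedule", "read_schedule",
    "write_table", "read_table",
    "write_glomerulus_image", "read_glomerulus_image",
    "write_spike_train", "read_spike_train",
    "write_json",
]


def write_event_stream(stream: EventStream, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(stream.intervals, columns=["onset_s", "offset_s"])
    df.insert(0, "session_id", stream.session_id)
    df.insert(0, "subject_id", stream.subject_id)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_event_stream(path: str | Path) -> EventStream:
    df = pd.read_csv(path, sep="\t")
    subject = str(df["subject_id"].iloc[0]) if len(df) else "subject"
    session = str(df["session_id"].iloc[0]) if len(df) else "session"
    return EventStream(intervals=df[["onset_s", "offset_s"]].to_numpy(float),
                       subject_id=subject, session_id=session)


def write_schedule(schedule: EpochSchedule, path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"kind": e.kind, "start_s": e.start_s, "end_s": e.end_s,
         "odor_id": e.odor_id, "concentration": e.concentration}
        for e in schedule
    ]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_schedule(path: str | Path) -> EpochSchedule:
    payload = yaml.safe_load(Path(path).read_text())
    return EpochSchedule(tuple(Epoch(**e) for e in payload))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def write_glomerulus_image(image: GlomerulusImage, path: str | Path) -> Path:
    """Multi-page TIFF: one page per channel, then one uint8 page per ROI;
    a JSON sidecar (``<path>.json``) names the pages and the pixel size."""
    path = Path(path)
    names = list(image.channels)
    pages = [np.asarray(image.channels[n], dtype=np.float32) for n in names]
    pages += [roi.astype(np.uint8) for roi in image.rois]
    tifffile.imwrite(path, np.stack(pages))
    sidecar = {"channels": names, "n_rois": len(image.rois),
               "pixel_size_um": image.pixel_size_um}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    if image.truth is not None:
        truth = {k: v for k, v in image.truth.items() if not hasattr(v, "__dataclass_fields__")}
        Path(str(path) + ".truth.yaml").write_text(yaml.safe_dump(truth))
    return path


def read_glomerulus_image(path: str | Path) -> GlomerulusImage:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    stack = tifffile.imread(path)
    names = sidecar["channels"]
    channels = {n: np.asarray(stack[i], dtype=float) for i, n in enumerate(names)}
    rois = [stack[len(names) + i].astype(bool) for i in range(sidecar["n_rois"])]
    return GlomerulusImage(channels=channels, rois=rois,
                           pixel_size_um=float(sidecar["pixel_size_um"]))


def write_spike_train(train: SpikeTrain, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"spike_time_s": train.times_s})
    df.attrs["duration_s"] = train.duration_s
    with open(path, "w") as fh:
        fh.write(f"# duration_s={train.duration_s}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_spike_train(path: str | Path) -> SpikeTrain:
    with open(path) as fh:
        header = fh.readline().strip()
        duration = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    return SpikeTrain(times_s=df["spike_time_s"].to_numpy(float), duration_s=duration)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=1, default=default))
    return path
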