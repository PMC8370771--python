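"""Reading and writing the pipeline's on-disk formats.

Events travel as per-event multi-page TIFFs (one page per channel, channel
names recorded in page tags) plus a manifest CSV; feature tables, cluster
summaries and test results are CSV; spillover matrices are CSV; run
provenance is a small JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageEvent


def write_events(events, directory, manifest_path=None,
                 ground_truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Write one multi-page TIFF per event plus a manifest CSV.

    Each TIFF page is one channel; the channel name is stored in the page
    description tag.  The manifest records event_id, sample_id, file and any
    ground-truth columns supplied.  Returns the manifest DataFrame.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for ev in events:
        fname = f"{ev.event_id}.tif"
        chans = list(ev.channels)
        with tifffile.TiffWriter(directory / fname) as tw:
            for c in chans:
                tw.write(ev.channels[c].astype(np.float32), description=c)
        rows.append({"event_id": ev.event_id, "sample_id": ev.sample_id,
                     "file": fname, "channels": ";".join(chans)})
    manifest = pd.DataFrame(rows)
    if ground_truth is not None:
        manifest = manifest.merge(ground_truth, on=["event_id", "sample_id"], how="left")
    if manifest_path is None:
        manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest


def read_events(manifest_path, directory=None) -> list[ImageEvent]:
    """Load events written by :func:`write_events`."""
    manifest_path = Path(manifest_path)
    directory = Path(directory) if directory else manifest_path.parent
    events = []
    manifest = pd.read_csv(manifest_path)
    for _, row in manifest.iterrows():
        with tifffile.TiffFile(directory / row["file"]) as tf:
            chans = {}
            for page in tf.pages:
                name = (page.description or f"ch{len(chans)}").strip()
                chans[name] = page.asarray().astype(float)
        events.append(ImageEvent(str(row["event_id"]), str(row["sample_id"]), chans))
    return events


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(path, stage: str, config: dict, seed: int,
                       inputs: list[str | Path], started: float) -> dict:
    """Record the provenance of one pipeline stage run."""
    from . import __version__
    manifest = {
        "stage": stage,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).is_file()},
        "version": __version__,
        "numpy_version": np.__version__,
        "wall_time_s": round(time.time() - started, 3),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
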