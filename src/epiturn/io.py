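"""Readers and writers for the formats the pipeline touches.

Counts travel as MatrixMarket MTX plus ``genes.tsv``/``cells.tsv``
(optional ``spliced.mtx``/``unspliced.mtx`` layers by naming convention);
image stacks as per-frame TIFF with a ``stack.yaml`` sidecar (channel
names, voxel size, frame times); events, tracks and trend tables as CSV.
Coordinates in CSVs are micrometres (0-based pixel origin, top-left) and
times are hours from experiment start.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import io as scio
from scipy import sparse

from epiturn.imgtrack import ImageStack
from epiturn.synth.expression import ExpressionBundle
from epiturn.synth.tissue import CellTrack, EventRecord

LAYER_FILES = {"spliced": "spliced.mtx", "unspliced": "unspliced.mtx"}


# ---------------------------------------------------------------------------
# counts bundles (MTX + TSV)


def write_counts(bundle: ExpressionBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    # genes x cells on disk, the common MTX convention
    scio.mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(bundle.counts.T))
    for name, fn in LAYER_FILES.items():
        if name in bundle.layers:
            scio.mmwrite(str(out / fn), sparse.csr_matrix(bundle.layers[name].T))
    bundle.genes.to_csv(out / "genes.tsv", sep="\t")
    bundle.cells.to_csv(out / "cells.tsv", sep="\t")


def read_counts(indir: str | Path) -> ExpressionBundle:
    ind = Path(indir)
    for fn in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (ind / fn).exists():
            raise FileNotFoundError(f"missing {fn} in {ind}")
    counts = np.asarray(scio.mmread(str(ind / "matrix.mtx")).todense()).T
    genes = pd.read_csv(ind / "genes.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(ind / "cells.tsv", sep="\t", index_col=0)
    if counts.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    layers = {}
    for name, fn in LAYER_FILES.items():
        if (ind / fn).exists():
            layer = np.asarray(scio.mmread(str(ind / fn)).todense()).T
            if layer.shape != counts.shape:
                raise ValueError(f"layer {name!r} shape mismatch")
            layers[name] = layer.astype(np.int64)
    return ExpressionBundle(
        counts=counts.astype(np.int64), genes=genes, cells=cells, layers=layers
    )


# ---------------------------------------------------------------------------
# events and tracks CSV

EVENT_COLUMNS = ["event_id", "type", "time_h", "x_um", "y_um", "cell_id", "daughters", "cause"]


def write_events(events: list[EventRecord], path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "type": e.type,
                "time_h": e.time,
                "x_um": e.position[0],
                "y_um": e.position[1],
                "cell_id": e.cell_id,
                "daughters": ";".join(map(str, e.daughter_ids)),
                "cause": "" if e.cause_event_id is None else e.cause_event_id,
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_events(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(
        path,
        dtype={"daughters": "string", "cause": "string"},
        float_precision="round_trip",
    )
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns {sorted(missing)}")
    events = []
    for _, row in df.iterrows():
        daughters = tuple(
            int(d) for d in str(row["daughters"]).split(";")
            if pd.notna(row["daughters"]) and d != "" and d != "<NA>"
        )
        cause = row["cause"]
        cause_id = None if pd.isna(cause) or cause == "" else int(cause)
        events.append(
            EventRecord(
                event_id=int(row["event_id"]),
                type=str(row["type"]),
                time=float(row["time_h"]),
                position=(float(row["x_um"]), float(row["y_um"])),
                cell_id=int(row["cell_id"]),
                daughter_ids=daughters,
                cause_event_id=cause_id,
            )
        )
    return events


def write_tracks(tracks: list[CellTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for frame, (x, y) in sorted(tr.positions.items()):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "parent_id": "" if tr.parent_id is None else tr.parent_id,
                    "birth_time_h": tr.birth_time,
                    "end_time_h": "" if tr.end_time is None else tr.end_time,
                    "end_fate": tr.end_fate,
                    "reporter_on_time_h": ""
                    if tr.reporter_on_time is None
                    else tr.reporter_on_time,
                    "frame": frame,
                    "x_um": x,
                    "y_um": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# image stacks (TIFF + YAML sidecar)


def write_stacks(stacks: list[ImageStack], outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "channels": list(stacks[0].channels),
        "voxel_size_um": list(stacks[0].voxel_size),
        "frame_times_h": [float(s.frame_time) for s in stacks],
        "files": [f"frame{i:04d}.tif" for i in range(len(stacks))],
    }
    for i, s in enumerate(stacks):
        tifffile.imwrite(
            out / meta["files"][i],
            np.asarray(s.data, dtype=np.float32),
            photometric="minisblack",
        )
    with open(out / "stack.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_stacks(indir: str | Path) -> list[ImageStack]:
    ind = Path(indir)
    sidecar = ind / "stack.yaml"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing stack.yaml in {ind}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    times = meta["frame_times_h"]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("frame times must be strictly increasing")
    stacks = []
    for fn, t in zip(meta["files"], times):
        data = tifffile.imread(ind / fn)
        if data.ndim != 4 or data.shape[0] != len(meta["channels"]):
            raise ValueError(f"{fn}: expected (channel, z, y, x) with "
                             f"{len(meta['channels'])} channels")
        stacks.append(
            ImageStack(
                data=data,
                voxel_size=tuple(meta["voxel_size_um"]),
                channels=list(meta["channels"]),
                frame_time=float(t),
            )
        )
    return stacks


# ---------------------------------------------------------------------------
# trend tables and run configuration

TREND_COLUMNS = ["Y", "X", "G", "region_id"]


def write_trend(table: pd.DataFrame, path: str | Path) -> None:
    table[TREND_COLUMNS].to_csv(path, index=False)


def read_trend(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TREND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trend CSV missing columns {sorted(missing)}")
    if (df["Y"] < 0).any() or (df["X"] < 0).any():
        raise ValueError("Y and X must be non-negative")
    return df


KNOWN_CONFIG_KEYS = {
    "seed",
    "log_level",
    "paths",
    "tissue",
    "imaging",
    "expression",
    "trend",
    "imbalance",
    "trajectory",
    "regulon",
}


def load_config(path: Optional[str | Path]) -> dict:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
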