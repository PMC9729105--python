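"""Render tissue simulations into 3D multichannel stacks.

Geometry: z index 0 is the tissue surface and increases with depth. The
epidermis/dermis interface sits at depth ``h*(x, y)``; the ECM channel is
a slab at and below the interface, nuclei are Gaussian blobs centred a
fixed offset above it, and the membrane channel carries ridges along the
Voronoi boundaries between cell positions. A per-frame 2D drift is
applied to all content and recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import ndtr

from epiturn._rng import substream
from epiturn.imgtrack import ImageStack
from epiturn.synth.tissue import CellTrack

CHANNELS = ("nuclei", "reporter", "membrane", "ECM")


@dataclass
class ImagingConfig:
    """Rendering parameters. Lengths in micrometres."""

    shape: tuple[int, int, int] = (16, 96, 96)      # (nz, ny, nx) voxels
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x) um
    surface: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    base_depth: float = 8.0          # um, interface depth when surface is None
    nucleus_radius: float = 1.5      # um, Gaussian sigma of nuclear blobs
    nucleus_offset: float = 3.0      # um, nucleus centre above the interface
    ecm_thickness: float = 4.0       # um
    membrane_width: float = 1.0      # um
    drift_sd: float = 0.0            # um per frame random-walk step (0 = none)
    drifts: Optional[Sequence[tuple[float, float]]] = None  # explicit (dx, dy)
    reporter_high: float = 200.0
    reporter_low: float = 20.0
    nuclei_intensity: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class SynthImageTruth:
    """Per-frame ground truth of a rendered timelapse."""

    nuclei_centers: list[np.ndarray] = field(default_factory=list)  # (n, 3) x,y,z um
    cell_ids: list[np.ndarray] = field(default_factory=list)
    surface_height: list[np.ndarray] = field(default_factory=list)  # (ny, nx) um
    drifts: list[tuple[float, float]] = field(default_factory=list)  # (dx, dy) um
    reporter_class: list[dict[int, str]] = field(default_factory=list)


def _surface_grid(cfg: ImagingConfig, ny: int, nx: int) -> np.ndarray:
    ys = np.arange(ny) * cfg.voxel_size[1]
    xs = np.arange(nx) * cfg.voxel_size[2]
    xx, yy = np.meshgrid(xs, ys)
    if cfg.surface is None:
        return np.full((ny, nx), cfg.base_depth)
    return np.asarray(cfg.surface(xx, yy), dtype=float)


def synthesize_timelapse(
    tracks: list[CellTrack],
    cfg: ImagingConfig,
    frames: Optional[Sequence[int]] = None,
    frame_interval: float = 6.0,
) -> tuple[list[ImageStack], SynthImageTruth]:
    """Render one multichannel 3D stack per frame plus the ground truth."""
    if not tracks:
        raise ValueError("tracks must be non-empty")
    nz, ny, nx = cfg.shape
    vz, vy, vx = cfg.voxel_size
    if min(ny * vy, nx * vx) < 4 * cfg.nucleus_radius:
        raise ValueError("field too small for the configured nucleus size")

    if frames is None:
        frames = sorted({f for tr in tracks for f in tr.positions})
    rng = substream(cfg.seed, "imaging")

    if cfg.drifts is not None:
        drifts = [tuple(map(float, d)) for d in cfg.drifts]
    else:
        steps = rng.normal(0.0, cfg.drift_sd, size=(len(frames), 2))
        steps[0] = 0.0
        cum = np.cumsum(steps, axis=0)
        drifts = [(float(dx), float(dy)) for dx, dy in cum]
    if tuple(drifts[0]) != (0.0, 0.0):
        raise ValueError("drift of frame 0 must be (0, 0)")

    surf = _surface_grid(cfg, ny, nx)
    zs = (np.arange(nz) * vz)[:, None, None]

    stacks: list[ImageStack] = []
    truth = SynthImageTruth()
    for fi, frame in enumerate(frames):
        dx, dy = drifts[fi]
        centers, ids, rep_cls = [], [], {}
        for tr in tracks:
            if frame not in tr.positions:
                continue
            x, y = tr.positions[frame]
            x, y = x + dx, y + dy
            if not (0 <= x < nx * vx and 0 <= y < ny * vy):
                continue
            iy = min(int(round(y / vy)), ny - 1)
            ix = min(int(round(x / vx)), nx - 1)
            z = surf[iy, ix] - cfg.nucleus_offset
            centers.append((x, y, z))
            ids.append(tr.cell_id)
            t = frame * frame_interval
            on = tr.reporter_on_time is not None and tr.reporter_on_time <= t
            rep_cls[tr.cell_id] = "high" if on else "low"

        vol = np.zeros((len(CHANNELS), nz, ny, nx), dtype=np.float32)
        # ECM: smooth slab starting at the interface
        depth = zs - surf[None, :, :]
        # erf-shaped upper edge: the 50% crossing sits exactly at the interface
        edge = ndtr(depth / 0.5)
        vol[3] = (100.0 * edge * (depth < cfg.ecm_thickness)).astype(np.float32)
        # nuclei + reporter blobs
        sig = cfg.nucleus_radius
        half = int(np.ceil(3 * sig / min(vx, vy)))
        for (x, y, z), cid in zip(centers, ids):
            iy, ix = int(round(y / vy)), int(round(x / vx))
            y0, y1 = max(0, iy - half), min(ny, iy + half + 1)
            x0, x1 = max(0, ix - half), min(nx, ix + half + 1)
            gy = (np.arange(y0, y1) * vy - y)[None, :, None]
            gx = (np.arange(x0, x1) * vx - x)[None, None, :]
            gz = (np.arange(nz) * vz - z)[:, None, None]
            blob = np.exp(-0.5 * (gx**2 + gy**2 + gz**2) / sig**2)
            vol[0, :, y0:y1, x0:x1] += cfg.nuclei_intensity * blob
            amp = cfg.reporter_high if rep_cls[cid] == "high" else cfg.reporter_low
            vol[1, :, y0:y1, x0:x1] += amp * blob
        # membrane: ridges where the two nearest cells are nearly equidistant
        if len(centers) >= 2:
            pts = np.array([(c[0], c[1]) for c in centers])
            tree = cKDTree(pts)
            yy, xx = np.meshgrid(np.arange(ny) * vy, np.arange(nx) * vx, indexing="ij")
            d, _ = tree.query(np.c_[xx.ravel(), yy.ravel()], k=2)
            ridge = np.exp(
                -0.5 * ((d[:, 1] - d[:, 0]) / cfg.membrane_width) ** 2
            ).reshape(ny, nx)
            zprof = np.exp(-0.5 * ((zs - (surf - cfg.nucleus_offset)) / (2 * sig)) ** 2)
            vol[2] = 80.0 * zprof * ridge[None, :, :]
        if cfg.noise_sd > 0:
            vol += rng.normal(0.0, cfg.noise_sd, size=vol.shape).astype(np.float32)
            np.clip(vol, 0.0, None, out=vol)

        stacks.append(
            ImageStack(
                data=vol,
                voxel_size=cfg.voxel_size,
                channels=list(CHANNELS),
                frame_time=frame * frame_interval,
            )
        )
        truth.nuclei_centers.append(np.array(centers).reshape(-1, 3))
        truth.cell_ids.append(np.array(ids, dtype=int))
        truth.surface_height.append(surf.copy())
        truth.drifts.append((dx, dy))
        truth.reporter_class.append(rep_cls)
    return stacks, truth
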