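"""Basal-layer extraction and cell-level quantification from 3D stacks.

The processing chain mirrors intravital basal-layer analysis: estimate the
epidermis/dermis interface height per xy column from the ECM (or nuclear)
channel, level the stack so the interface is flat, average a few z-slices
into a 2D basal-plane image, detect cell positions as local extrema,
correct inter-frame drift by nearest-neighbour square-distance
minimization, and quantify the nuclear reporter around each position.

Conventions: z index 0 is the tissue surface and increases with depth;
positions are micrometres from the image origin (0-based pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu


@dataclass
class ImageStack:
    """A multichannel 3D frame, indexed (channel, z, y, x)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x) um
    channels: list[str] = field(default_factory=list)
    frame_time: float = 0.0  # h

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (channel, z, y, x)")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one channel")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channels.index(channel)
            except ValueError:
                raise KeyError(f"channel {channel!r} not in {self.channels}") from None
        if not 0 <= channel < self.data.shape[0]:
            raise KeyError(f"channel index {channel} out of range")
        return channel


@dataclass
class HeightMap:
    """Interface height h(x, y) in (fractional) z-index units."""

    h: np.ndarray  # (ny, nx)


@dataclass
class PlaneImage:
    """2D per-channel intensities from a basal-plane projection."""

    data: np.ndarray  # (channel, y, x)
    pixel_size: tuple[float, float] = (1.0, 1.0)  # (y, x) um
    channels: list[str] = field(default_factory=list)

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channels.index(channel)
            except ValueError:
                raise KeyError(f"channel {channel!r} not in {self.channels}") from None
        return channel


@dataclass
class CellPositions:
    """Detected 2D cell positions, micrometres from the image origin."""

    xy: np.ndarray  # (n, 2) as (x, y)
    mode: str = "maxima"


@dataclass
class ReporterLevel:
    cell_id: int
    raw: float
    normalized: Optional[float] = None
    is_high: Optional[bool] = None


def compute_height_map(
    stack: ImageStack,
    channel: int | str,
    blur_sigma_um: float = 6.0,
    threshold: str = "half-max",
) -> HeightMap:
    """Estimate interface height per xy column from a structural channel.

    The channel is Gaussian-blurred in xy (sigma ``blur_sigma_um``) and
    thresholded; the height is the smallest z at which the mask is true,
    refined to the sub-voxel threshold crossing. Columns with no masked
    voxel are filled from their nearest valid neighbour.

    ``threshold='half-max'`` (default) uses the midpoint of the 1st and
    99th intensity percentiles — robust when most voxels are empty, where
    Otsu can collapse onto the background mode; ``'otsu'`` is available
    for less skewed data.
    """
    ci = stack.channel_index(channel)
    vol = np.asarray(stack.data[ci], dtype=float)
    if not np.any(vol > 0):
        raise ValueError("no interface signal: channel is empty")
    _, vy, vx = stack.voxel_size
    blurred = ndimage.gaussian_filter(vol, sigma=(0.0, blur_sigma_um / vy, blur_sigma_um / vx))
    if threshold == "half-max":
        thr = 0.5 * (np.percentile(blurred, 1) + np.percentile(blurred, 99))
    elif threshold == "otsu":
        thr = threshold_otsu(blurred)
    else:
        raise ValueError("threshold must be 'half-max' or 'otsu'")
    mask = blurred > thr

    nz, ny, nx = vol.shape
    any_col = mask.any(axis=0)
    # sub-voxel: linear interpolation of the threshold crossing
    iz = np.argmax(mask, axis=0)
    above = np.clip(iz - 1, 0, nz - 1)
    lo = blurred[above, np.arange(ny)[:, None], np.arange(nx)[None, :]]
    hi = blurred[iz, np.arange(ny)[:, None], np.arange(nx)[None, :]]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (thr - lo) / (hi - lo)
    frac = np.where((iz > 0) & np.isfinite(frac), np.clip(frac, 0.0, 1.0), 1.0)
    h = np.where(any_col, above + frac, np.nan)

    if np.isnan(h).all():
        raise ValueError("no interface signal: mask empty everywhere")
    if np.isnan(h).any():
        miss = np.isnan(h)
        _, (iy, ix) = ndimage.distance_transform_edt(miss, return_indices=True)
        h = h[iy, ix]
    return HeightMap(h=h)


def flatten_stack(stack: ImageStack, hmap: HeightMap, target_z: float = 0.0) -> ImageStack:
    """Shift each xy column in z so the interface lies at ``target_z``.

    Output voxel (z, y, x) samples the input at z + h(x, y) - target_z
    with linear interpolation; out-of-range samples are zero.
    """
    nc, nz, ny, nx = stack.data.shape
    if hmap.h.shape != (ny, nx):
        raise ValueError(f"height map shape {hmap.h.shape} != stack xy {(ny, nx)}")
    src = np.arange(nz)[:, None, None] + (hmap.h - target_z)[None, :, :]
    z0 = np.floor(src).astype(int)
    frac = src - z0
    z1 = z0 + 1
    valid0 = (z0 >= 0) & (z0 < nz)
    valid1 = (z1 >= 0) & (z1 < nz)
    z0c = np.clip(z0, 0, nz - 1)
    z1c = np.clip(z1, 0, nz - 1)
    iy = np.arange(ny)[None, :, None]
    ix = np.arange(nx)[None, None, :]
    out = np.empty_like(stack.data, dtype=float)
    for c in range(nc):
        ch = stack.data[c]
        a = np.where(valid0, ch[z0c, iy, ix], 0.0)
        b = np.where(valid1, ch[z1c, iy, ix], 0.0)
        out[c] = (1.0 - frac) * a + frac * b
    return ImageStack(
        data=out,
        voxel_size=stack.voxel_size,
        channels=list(stack.channels),
        frame_time=stack.frame_time,
    )


def project_basal(stack: ImageStack, z_start: int, n_slices: int = 3) -> PlaneImage:
    """Mean-project ``n_slices`` consecutive z-positions into a 2D image."""
    nz = stack.data.shape[1]
    if z_start < 0 or z_start + n_slices > nz:
        raise ValueError(f"z range [{z_start}, {z_start + n_slices}) outside 0..{nz}")
    plane = stack.data[:, z_start : z_start + n_slices].mean(axis=1)
    return PlaneImage(
        data=plane,
        pixel_size=(stack.voxel_size[1], stack.voxel_size[2]),
        channels=list(stack.channels),
    )


def detect_cells(
    plane: PlaneImage,
    channel: int | str = 0,
    mode: str = "maxima",
    min_separation_um: float = 4.0,
    smooth_sigma_um: float = 1.0,
) -> CellPositions:
    """Detect cell positions as local extrema of a (lightly smoothed) channel.

    ``mode='minima'`` finds dark centres (membrane channel), ``'maxima'``
    bright ones (nuclear channel). Extrema closer than
    ``min_separation_um`` are pruned, keeping the stronger one.
    """
    if mode not in ("minima", "maxima"):
        raise ValueError("mode must be 'minima' or 'maxima'")
    ci = plane.channel_index(channel)
    img = np.asarray(plane.data[ci], dtype=float)
    if img.size == 0:
        raise ValueError("empty plane")
    py, px = plane.pixel_size
    img = ndimage.gaussian_filter(img, sigma=(smooth_sigma_um / py, smooth_sigma_um / px))
    if mode == "minima":
        img = -img
    if np.ptp(img) == 0:
        return CellPositions(xy=np.empty((0, 2)), mode=mode)
    min_dist = max(1, int(round(min_separation_um / min(py, px))))
    coords = peak_local_max(
        img,
        min_distance=min_dist,
        threshold_abs=img.min() + 1e-6 * np.ptp(img),
        exclude_border=False,
    )
    # sub-pixel refinement: intensity centroid in a 5x5 window above the
    # local background, so positions are not quantized to whole pixels
    ny, nx = img.shape
    refined = coords.astype(float)
    for i, (iy, ix) in enumerate(coords):
        y0, y1 = max(0, iy - 2), min(ny, iy + 3)
        x0, x1 = max(0, ix - 2), min(nx, ix + 3)
        win = img[y0:y1, x0:x1] - img[y0:y1, x0:x1].min()
        tot = win.sum()
        if tot > 0:
            gy, gx = np.mgrid[y0:y1, x0:x1]
            refined[i] = [(win * gy).sum() / tot, (win * gx).sum() / tot]
    xy = np.c_[refined[:, 1] * px, refined[:, 0] * py]
    return CellPositions(xy=xy, mode=mode)


def _registration_cost(
    ref: np.ndarray, tree: cKDTree, shift: np.ndarray, trim: float
) -> float:
    d, _ = tree.query(ref + shift)
    d2 = np.sort(d**2)
    keep = max(1, int(np.ceil((1.0 - trim) * len(d2))))
    return float(np.mean(d2[:keep]))


def register_frames(
    ref: CellPositions,
    mov: CellPositions,
    search_radius_um: float = 10.0,
    coarse_step_um: float = 1.0,
    fine_step_um: float = 0.05,
    trim_fraction: float = 0.15,
) -> tuple[float, float]:
    """Drift between frames as the translation minimizing nearest-pair cost.

    Returns the shift s = (dx, dy) minimizing the mean over i of
    min_j ||p_i + s - q_j||^2, where p are ``ref`` and q are ``mov``
    positions: the coarse argmin on a 1 um grid is refined on a fine
    local grid; ties prefer smaller ||s||. The largest ``trim_fraction``
    of squared distances is dropped from the mean so cells that appear,
    vanish or drift out of the field do not bias the estimate.
    """
    p = np.asarray(ref.xy, dtype=float)
    q = np.asarray(mov.xy, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("both position sets must be non-empty")
    tree = cKDTree(q)

    def best_on_grid(grid: np.ndarray) -> np.ndarray:
        costs = np.array(
            [_registration_cost(p, tree, s, trim_fraction) for s in grid]
        )
        order = np.lexsort((np.einsum("ij,ij->i", grid, grid), costs))
        return grid[order[0]]

    ax = np.arange(-search_radius_um, search_radius_um + 1e-9, coarse_step_um)
    coarse = np.array([(sx, sy) for sx in ax for sy in ax])
    s = best_on_grid(coarse)
    for step in (0.25, fine_step_um):
        ax = np.arange(-coarse_step_um, coarse_step_um + 1e-9, step)
        s = best_on_grid(s + np.array([(sx, sy) for sx in ax for sy in ax]))
    s = np.where(np.abs(s) < 1e-9, 0.0, s)  # snap float-accumulation dust
    return float(s[0]), float(s[1])


def quantify_reporter(
    plane: PlaneImage,
    positions: CellPositions,
    channel: int | str = 0,
    radius_um: float = 3.0,
    method: str = "disc_mean",
    labels: Optional[np.ndarray] = None,
    cell_ids: Optional[Sequence[int]] = None,
) -> list[ReporterLevel]:
    """Per-cell reporter level around each detected position.

    ``disc_mean`` averages pixels with centre distance <= ``radius_um``
    (restricted to in-bounds pixels at the border); ``segment_sum`` sums
    intensity over the segment of ``labels`` containing the position.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if method not in ("disc_mean", "segment_sum"):
        raise ValueError("method must be 'disc_mean' or 'segment_sum'")
    if method == "segment_sum" and labels is None:
        raise ValueError("segment_sum requires a label mask")
    ci = plane.channel_index(channel)
    img = np.asarray(plane.data[ci], dtype=float)
    ny, nx = img.shape
    py, px = plane.pixel_size
    if cell_ids is None:
        cell_ids = list(range(len(positions.xy)))

    out: list[ReporterLevel] = []
    for cid, (x, y) in zip(cell_ids, positions.xy):
        if not (0 <= x <= (nx - 1) * px and 0 <= y <= (ny - 1) * py):
            raise ValueError(f"position ({x}, {y}) outside the plane")
        if method == "disc_mean":
            ix, iy = x / px, y / py
            r_px = radius_um / min(px, py)
            x0, x1 = max(0, int(np.floor(ix - r_px))), min(nx - 1, int(np.ceil(ix + r_px)))
            y0, y1 = max(0, int(np.floor(iy - r_px))), min(ny - 1, int(np.ceil(iy + r_px)))
            gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
            dist2 = ((gx * px - x)) ** 2 + ((gy * py - y)) ** 2
            sel = dist2 <= radius_um**2
            raw = float(img[y0 : y1 + 1, x0 : x1 + 1][sel].mean()) if sel.any() else float("nan")
        else:
            lab = labels[int(round(y / py)), int(round(x / px))]
            raw = float(img[labels == lab].sum()) if lab != 0 else 0.0
        out.append(ReporterLevel(cell_id=int(cid), raw=raw))
    return out


def normalize_by_dividing(
    levels: list[ReporterLevel], dividing_ids: Sequence[int]
) -> list[ReporterLevel]:
    """Express each raw level as a fold of the mean over dividing cells."""
    ids = set(dividing_ids)
    if not ids:
        raise ValueError("dividing_ids must be non-empty")
    div_raw = [lv.raw for lv in levels if lv.cell_id in ids]
    if not div_raw:
        raise ValueError("no dividing cells present in levels")
    m = float(np.mean(div_raw))
    if m == 0:
        raise ValueError("dividing-cell mean is zero")
    return [
        ReporterLevel(cell_id=lv.cell_id, raw=lv.raw, normalized=lv.raw / m, is_high=lv.is_high)
        for lv in levels
    ]


def classify_high(levels: list[ReporterLevel], threshold: float) -> list[ReporterLevel]:
    """Flag cells whose normalized level strictly exceeds ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = []
    for lv in levels:
        if lv.normalized is None:
            raise ValueError("levels must be normalized before classification")
        out.append(
            ReporterLevel(
                cell_id=lv.cell_id,
                raw=lv.raw,
                normalized=lv.normalized,
                is_high=bool(lv.normalized > threshold),
            )
        )
    return out
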