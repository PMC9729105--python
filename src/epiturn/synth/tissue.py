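"""Stochastic basal-layer event dynamics.

Cells live on a 2D field (the basal plane). Each cell delaminates at a
constant background rate and, optionally, divides at a constant background
rate. A delamination may additionally *trigger* one division among the
neighbours within ``trigger_radius``, after a random delay — the coupling
that produces a net neighbour fate imbalance of -1 before divisions.

Cells are quasi-static: positions receive only a small per-frame jitter.
Daughters are placed at +/- half a cell radius along a random in-plane
axis. Reporter onset is drawn to precede each delamination by a
configurable lead time (days-scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from epiturn._rng import substream

HOURS_PER_DAY = 24.0


@dataclass
class TissueSimConfig:
    """Parameters of the basal-layer event simulation.

    Rates are per cell per day; times are hours; lengths are micrometres.
    """

    field_size: tuple[float, float] = (200.0, 200.0)
    init_density: float = 1.0          # cells per 100 um^2
    frame_interval: float = 6.0        # h
    n_frames: int = 40
    delam_rate: float = 0.3            # delaminations / cell / day
    division_rate: float = 0.0         # spontaneous divisions / cell / day
    coupling_prob: float = 0.0         # P(delamination triggers a division)
    trigger_radius: float = 10.0       # um
    trigger_delay: tuple[float, float] = (12.0, 48.0)   # h, uniform
    reporter_lead: tuple[float, float] = (84.0, 12.0)   # h, (mean, sd) normal
    jitter_sd: float = 0.3             # um per frame, per axis
    cell_radius: float = 4.0           # um, sets daughter placement
    min_spacing: float = 0.0           # um, exclusion distance at seeding
    seed_delam_times: tuple[float, ...] = ()  # forced delaminations (h)
    homeostatic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delam_rate", "division_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ValueError(f"coupling_prob must be in [0, 1], got {self.coupling_prob}")
        if self.trigger_radius <= 0:
            raise ValueError("trigger_radius must be > 0")
        if self.trigger_delay[0] < 0 or self.trigger_delay[1] < self.trigger_delay[0]:
            raise ValueError("trigger_delay must be a non-negative (lo, hi) interval")
        if self.frame_interval <= 0 or self.n_frames < 1:
            raise ValueError("frame_interval must be > 0 and n_frames >= 1")
        if self.homeostatic and self.coupling_prob != 1.0:
            raise ValueError(
                "homeostatic mode requires coupling_prob = 1 so every loss "
                "is compensated by a triggered division"
            )

    @property
    def n_init_cells(self) -> int:
        area = self.field_size[0] * self.field_size[1]
        return int(round(self.init_density * area / 100.0))


@dataclass
class CellTrack:
    cell_id: int
    parent_id: Optional[int]
    birth_time: float
    end_time: Optional[float] = None
    end_fate: str = "censored"          # divide | delaminate | censored
    positions: dict[int, tuple[float, float]] = field(default_factory=dict)
    reporter_on_time: Optional[float] = None


@dataclass
class EventRecord:
    event_id: int
    type: str                           # division | delamination
    time: float                         # h
    position: tuple[float, float]       # um
    cell_id: int
    daughter_ids: tuple[int, ...] = ()
    cause_event_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.type == "division" and len(self.daughter_ids) != 2:
            raise ValueError("division events require exactly 2 daughter_ids")
        if self.type == "delamination" and self.daughter_ids:
            raise ValueError("delamination events carry no daughter_ids")


def simulate_basal_dynamics(
    config: TissueSimConfig,
) -> tuple[list[CellTrack], list[EventRecord]]:
    """Simulate basal-layer cell fates; return tracks and the event log.

    Per frame, in order: pending triggered divisions that have come due
    fire first (choosing a live neighbour within ``trigger_radius`` of the
    causal delamination), then spontaneous delaminations and divisions are
    drawn per cell. Triggered divisions record their causal delamination
    in ``cause_event_id``.
    """
    rng = substream(config.seed, "tissue")
    n0 = config.n_init_cells
    if n0 == 0:
        raise ValueError("zero initial cells; increase field_size or init_density")

    fx, fy = config.field_size
    dt = config.frame_interval
    p_delam = config.delam_rate * dt / HOURS_PER_DAY
    p_div = config.division_rate * dt / HOURS_PER_DAY

    tracks: dict[int, CellTrack] = {}
    alive: set[int] = set()
    pos: dict[int, np.ndarray] = {}
    events: list[EventRecord] = []
    # (fire_time, cause_event_id, cause_xy)
    pending: list[tuple[float, Optional[int], np.ndarray]] = []
    next_cell = 0
    next_event = 0

    def spawn(parent: Optional[int], birth: float, xy: np.ndarray) -> int:
        nonlocal next_cell
        cid = next_cell
        next_cell += 1
        xy = np.clip(xy, [0.0, 0.0], [fx, fy])
        tracks[cid] = CellTrack(cell_id=cid, parent_id=parent, birth_time=birth)
        alive.add(cid)
        pos[cid] = np.asarray(xy, dtype=float)
        return cid

    def divide(cid: int, time: float, cause: Optional[int]) -> None:
        nonlocal next_event
        xy = pos[cid]
        theta = rng.uniform(0.0, 2.0 * math.pi)
        off = 0.5 * config.cell_radius * np.array([math.cos(theta), math.sin(theta)])
        d1 = spawn(cid, time, xy + off)
        d2 = spawn(cid, time, xy - off)
        tr = tracks[cid]
        tr.end_time, tr.end_fate = time, "divide"
        alive.discard(cid)
        del pos[cid]
        events.append(
            EventRecord(next_event, "division", time, (float(xy[0]), float(xy[1])),
                        cid, (d1, d2), cause)
        )
        next_event += 1

    def delaminate(cid: int, time: float) -> int:
        nonlocal next_event
        xy = pos[cid]
        tr = tracks[cid]
        tr.end_time, tr.end_fate = time, "delaminate"
        lead = max(0.0, rng.normal(*config.reporter_lead))
        tr.reporter_on_time = time - lead
        alive.discard(cid)
        del pos[cid]
        eid = next_event
        events.append(
            EventRecord(eid, "delamination", time, (float(xy[0]), float(xy[1])), cid)
        )
        next_event += 1
        return eid

    # initial seeding: uniform, with optional dart-throwing exclusion
    seeded: list[np.ndarray] = []
    attempts = 0
    while len(seeded) < n0 and attempts < 200 * n0:
        xy = rng.uniform([0.0, 0.0], [fx, fy])
        attempts += 1
        if config.min_spacing > 0 and any(
            np.hypot(*(xy - q)) < config.min_spacing for q in seeded
        ):
            continue
        seeded.append(xy)
    if len(seeded) < n0:
        raise ValueError("min_spacing too large for the requested density")
    for xy in seeded:
        spawn(None, 0.0, xy)

    # homeostatic runs start with the triggered-division queue at its
    # stationary level, else the population dips by the in-flight count
    # (~ n0 * delam_rate * mean_delay) during the initial transient
    if config.homeostatic and config.coupling_prob > 0:
        lo, hi = config.trigger_delay
        n_virtual = rng.poisson(n0 * config.delam_rate / HOURS_PER_DAY * hi)
        for _ in range(n_virtual):
            created = rng.uniform(-hi, 0.0)
            fire = created + rng.uniform(lo, hi)
            if fire > 0 and rng.random() < config.coupling_prob:
                xy = rng.uniform([0.0, 0.0], [fx, fy], size=2)
                pending.append((fire, None, xy))

    for frame in range(config.n_frames):
        t = frame * dt
        # record positions, then jitter for the next frame
        for cid in alive:
            p = pos[cid]
            tracks[cid].positions[frame] = (float(p[0]), float(p[1]))

        # fire due triggered divisions (in scheduling order)
        due = [p for p in pending if p[0] <= t]
        pending = [p for p in pending if p[0] > t]
        for fire_time, cause_eid, cause_xy in due:
            if not alive:
                break
            cand = [cid for cid in alive
                    if np.hypot(*(pos[cid] - cause_xy)) <= config.trigger_radius]
            if cand:
                divide(cand[rng.integers(len(cand))], fire_time, cause_eid)
            elif config.homeostatic:
                # closure: divide the nearest cell instead, but record no
                # cause (the causal audit only covers in-radius triggers)
                ids = sorted(alive)
                d = [np.hypot(*(pos[cid] - cause_xy)) for cid in ids]
                divide(ids[int(np.argmin(d))], fire_time, None)

        # forced delaminations scheduled into this frame interval
        for sd_time in config.seed_delam_times:
            if t <= sd_time < t + dt and alive:
                ids = sorted(alive)
                cid = ids[rng.integers(len(ids))]
                eid = delaminate(cid, sd_time)
                if rng.random() < config.coupling_prob:
                    delay = rng.uniform(*config.trigger_delay)
                    pending.append(
                        (sd_time + delay, eid, np.array(events[eid].position))
                    )

        # spontaneous events this frame
        ids = sorted(alive)
        u = rng.random(len(ids))
        for cid, ui in zip(ids, u):
            if ui < p_delam:
                etime = t + rng.uniform(0.0, dt)
                eid = delaminate(cid, etime)
                if rng.random() < config.coupling_prob:
                    delay = rng.uniform(*config.trigger_delay)
                    pending.append((etime + delay, eid, np.array(events[eid].position)))
            elif ui < p_delam + p_div:
                divide(cid, t + rng.uniform(0.0, dt), None)

        # jitter surviving cells
        if alive and config.jitter_sd > 0:
            ids = sorted(alive)
            jit = rng.normal(0.0, config.jitter_sd, size=(len(ids), 2))
            for cid, j in zip(ids, jit):
                pos[cid] = np.clip(pos[cid] + j, [0.0, 0.0], [fx, fy])

    # censor survivors at the last frame time
    t_end = (config.n_frames - 1) * dt
    for cid in alive:
        tracks[cid].end_time = t_end

    events.sort(key=lambda e: (e.time, e.event_id))
    return list(tracks.values()), events


def daughter_fate_fractions(
    tracks: list[CellTrack], horizon_h: float = 120.0
) -> tuple[float, int]:
    """Fraction of daughters whose resolved next fate is delamination.

    Only daughters (cells with a parent) whose fate resolved within
    ``horizon_h`` hours of birth count. Returns (fraction, n_resolved).
    """
    n_delam = n_resolved = 0
    for tr in tracks:
        if tr.parent_id is None or tr.end_fate == "censored":
            continue
        if tr.end_time is None or tr.end_time - tr.birth_time > horizon_h:
            continue
        n_resolved += 1
        if tr.end_fate == "delaminate":
            n_delam += 1
    if n_resolved == 0:
        return float("nan"), 0
    return n_delam / n_resolved, n_resolved
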