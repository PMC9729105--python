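"""Genotype-dependent proportion-vs-day tables for trend statistics."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from epiturn._rng import substream

# fixed recovery curve: rises then settles back, cubic in the day
_CONTROL_COEF = (0.30, 0.12, -0.018, 0.0007)


def control_curve(day: np.ndarray) -> np.ndarray:
    a0, a1, a2, a3 = _CONTROL_COEF
    day = np.asarray(day, dtype=float)
    return a0 + a1 * day + a2 * day**2 + a3 * day**3


def simulate_trend_data(
    effect_size: float,
    n_regions: int,
    days: Sequence[float],
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate (Y proportion, X day, G genotype, region) observations.

    Controls follow a fixed cubic recovery curve; the mutant curve is
    offset by ``effect_size``; iid Gaussian noise of ``noise_sd`` is
    added. Returns a tidy frame with columns Y, X, G, region_id.
    """
    days = list(days)
    if not days:
        raise ValueError("days must be non-empty")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = substream(seed, "trend")
    rows = []
    for g, offset in (("control", 0.0), ("mutant", effect_size)):
        for region in range(n_regions):
            base = control_curve(np.array(days)) + offset
            y = base + rng.normal(0.0, noise_sd, size=len(days))
            for d, yi in zip(days, y):
                rows.append(
                    {"Y": max(float(yi), 0.0), "X": float(d), "G": g,
                     "region_id": f"{g}_r{region}"}
                )
    return pd.DataFrame(rows)
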