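"""Negative-binomial count matrices along a latent differentiation axis.

Each cell carries a latent position ``s`` in [0, 1]. Gene programs are
smooth sigmoidal profiles of ``s``: ``diff-up`` genes switch on at a
per-gene onset, ``basal-down`` genes switch off, ``neutral`` genes are
flat and ``cycle`` genes are elevated only in cycling cells. Unspliced
abundance follows the program at ``s``; spliced abundance lags by
``splicing_lag`` (the nascent transcript leads the mature one). Counts
are negative binomial around depth-scaled expected proportions. A
"sorted" subpopulation flags cells below a latent threshold, with a small
contamination fraction from above it. Planted TF modules couple target
genes linearly to their TF's profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from epiturn._rng import substream


@dataclass
class GeneProgram:
    """One gene's profile: class, onset position on s and slope."""

    name: str
    kind: str = "neutral"      # basal-down | diff-up | neutral | cycle
    onset: float = 0.5         # position on s in [0, 1]
    slope: float = 10.0        # sigmoid steepness
    base_level: float = 1.0    # relative expression scale

    def __post_init__(self) -> None:
        if self.kind not in ("basal-down", "diff-up", "neutral", "cycle"):
            raise ValueError(f"unknown gene class {self.kind!r}")
        if not 0.0 <= self.onset <= 1.0:
            raise ValueError("onset must lie in [0, 1]")


@dataclass
class ExprSimConfig:
    n_cells: dict[str, int] = field(default_factory=lambda: {"ds1": 300})
    depth_mean: dict[str, float] = field(default_factory=lambda: {"ds1": 3000.0})
    depth_log_sd: float = 0.2
    programs: list[GeneProgram] = field(default_factory=lambda: default_programs())
    nb_dispersion: float = 0.1     # var = mu + dispersion * mu^2
    splicing_lag: float = 0.0      # Delta s between transcription and spliced
    unspliced_fraction: float = 0.25
    sorted_threshold: float = 0.5  # s0: sorted cells have s < s0 ...
    contamination: float = 0.05    # ... except this fraction drawn from above
    cycling_fraction: float = 0.0
    cycle_boost: float = 4.0
    tf_modules: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must be in [0, 1]")
        if not 0.0 <= self.sorted_threshold <= 1.0:
            raise ValueError("sorted_threshold must be in [0, 1]")
        if set(self.n_cells) != set(self.depth_mean):
            raise ValueError("n_cells and depth_mean must share dataset keys")


@dataclass
class ExpressionBundle:
    """Cells x genes counts plus metadata and optional layers/normalization."""

    counts: np.ndarray                    # (cells, genes) int
    genes: pd.DataFrame                   # indexed by gene name
    cells: pd.DataFrame                   # indexed by cell id
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    norm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n, g = self.counts.shape
        if len(self.cells) != n or len(self.genes) != g:
            raise ValueError("metadata shapes do not match the count matrix")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, name: str) -> int:
        try:
            return int(self.genes.index.get_loc(name))
        except KeyError:
            raise KeyError(f"gene {name!r} not found") from None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def program_profile(prog: GeneProgram, s: np.ndarray) -> np.ndarray:
    """Relative expected expression of one gene at latent positions s."""
    if prog.kind == "diff-up":
        return prog.base_level * _sigmoid(prog.slope * (s - prog.onset))
    if prog.kind == "basal-down":
        return prog.base_level * _sigmoid(-prog.slope * (s - prog.onset))
    # neutral and cycle share a flat s-profile; cycle is boosted per cell
    return np.full_like(s, prog.base_level, dtype=float)


def default_programs(
    n_diff_up: int = 20,
    n_basal_down: int = 20,
    n_neutral: int = 40,
    n_cycle: int = 10,
    slope: float = 12.0,
    rng: Optional[np.random.Generator] = None,
) -> list[GeneProgram]:
    """A staggered-onset program table; onsets spread over the axis."""
    rng = rng or np.random.default_rng(0)
    progs: list[GeneProgram] = []
    for i, onset in enumerate(np.linspace(0.25, 0.9, n_diff_up)):
        progs.append(GeneProgram(f"DIFF{i:03d}", "diff-up", float(onset), slope, 2.0))
    for i, onset in enumerate(np.linspace(0.3, 0.95, n_basal_down)):
        progs.append(GeneProgram(f"BASAL{i:03d}", "basal-down", float(onset), slope, 2.0))
    for i in range(n_neutral):
        progs.append(GeneProgram(f"NEUT{i:03d}", "neutral", 0.5, slope,
                                 float(rng.uniform(0.5, 2.0))))
    for i in range(n_cycle):
        progs.append(GeneProgram(f"CYC{i:03d}", "cycle", 0.5, slope, 1.0))
    return progs


def simulate_expression(config: ExprSimConfig) -> ExpressionBundle:
    """Draw an expression bundle with latent ground truth in the metadata.

    Cell metadata records ``latent_s``, ``dataset``, ``sorted`` (basal
    sort flag), ``cycling`` and ``depth``. Gene metadata records the
    program class, onset, TF flag and planted module membership.
    """
    progs = config.programs
    if not progs:
        raise ValueError("degenerate program table: no genes")
    names = [p.name for p in progs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names in program table")
    rng = substream(config.seed, "expression")

    cell_rows = []
    for ds, n in config.n_cells.items():
        for _ in range(n):
            cell_rows.append(ds)
    n_cells = len(cell_rows)
    if n_cells == 0:
        raise ValueError("no cells requested")
    s = rng.uniform(0.0, 1.0, size=n_cells)
    dataset = np.array(cell_rows)
    depth = np.array([
        rng.lognormal(np.log(config.depth_mean[ds]), config.depth_log_sd)
        for ds in dataset
    ])

    cycling = rng.random(n_cells) < config.cycling_fraction

    # sorted flag: below-threshold cells, plus contamination from above
    below = s < config.sorted_threshold
    sorted_flag = below.copy()
    above_idx = np.flatnonzero(~below)
    n_cont = int(round(config.contamination * below.sum()))
    if n_cont > 0 and len(above_idx) > 0:
        pick = rng.choice(above_idx, size=min(n_cont, len(above_idx)), replace=False)
        sorted_flag[pick] = True

    n_genes = len(progs)
    mu_u = np.empty((n_cells, n_genes))   # unspliced: program at s
    mu_s = np.empty((n_cells, n_genes))   # spliced: program at s - lag
    s_lag = np.clip(s - config.splicing_lag, 0.0, 1.0)
    for j, p in enumerate(progs):
        mu_u[:, j] = program_profile(p, s)
        mu_s[:, j] = program_profile(p, s_lag)
        if p.kind == "cycle":
            mu_u[cycling, j] *= config.cycle_boost
            mu_s[cycling, j] *= config.cycle_boost

    # planted TF -> target coupling, applied on both layers
    tf_flag = np.zeros(n_genes, dtype=bool)
    module_of = np.array([""] * n_genes, dtype=object)
    name_to_idx = {n: i for i, n in enumerate(names)}
    for tf, targets in config.tf_modules.items():
        if tf not in name_to_idx:
            raise ValueError(f"TF {tf!r} not in program table")
        ti = name_to_idx[tf]
        tf_flag[ti] = True
        for mu in (mu_u, mu_s):
            tf_prof = mu[:, ti] / max(mu[:, ti].mean(), 1e-12)
            for target, effect in targets.items():
                if target == tf:
                    continue
                tj = name_to_idx[target]
                module_of[tj] = tf
                mu[:, tj] = mu[:, tj] * (1.0 + effect * (tf_prof - 1.0)).clip(min=0.05)

    def draw_counts(mu: np.ndarray, total_share: float) -> np.ndarray:
        prop = mu / mu.sum(axis=1, keepdims=True)
        lam = prop * (depth * total_share)[:, None]
        if config.nb_dispersion <= 0:
            return rng.poisson(lam)
        r = 1.0 / config.nb_dispersion
        # Gamma-Poisson mixture == NB with var = mu + dispersion mu^2
        shape = rng.gamma(r, lam / r)
        return rng.poisson(shape)

    unspliced = draw_counts(mu_u, config.unspliced_fraction)
    spliced = draw_counts(mu_s, 1.0 - config.unspliced_fraction)
    counts = spliced + unspliced

    genes = pd.DataFrame(
        {
            "class": [p.kind for p in progs],
            "onset": [p.onset for p in progs],
            "is_tf": tf_flag,
            "module": module_of,
            "is_spike": False,
        },
        index=pd.Index(names, name="gene"),
    )
    cells = pd.DataFrame(
        {
            "dataset": dataset,
            "latent_s": s,
            "sorted": sorted_flag,
            "cycling": cycling,
            "depth": depth,
            "trace": False,
        },
        index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell"),
    )
    return ExpressionBundle(
        counts=counts.astype(np.int64),
        genes=genes,
        cells=cells,
        layers={"spliced": spliced.astype(np.int64), "unspliced": unspliced.astype(np.int64)},
    )
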