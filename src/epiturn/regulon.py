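"""TF-module (regulon) construction and per-cell target-gene scoring.

The downstream chain: (1) find genes positively correlated with the
differentiation anchor over the early-differentiation bins (2-4);
(2) expand every TF with at least one edge into that set to its full
target list; (3) score each cell for each module with a matched-control
gene-set score, after excluding genes differentially expressed in bin 1.

Network inference itself is a desk-scale surrogate (per-target ridge
importances); an externally computed adjacency list is accepted verbatim
and is the fidelity path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from statsmodels.stats.multitest import multipletests

from epiturn.trajectory import score_gene_set

logger = logging.getLogger(__name__)


@dataclass
class RegulonModule:
    tf: str
    targets: tuple[str, ...]


def infer_adjacency(
    norm: np.ndarray,
    gene_names: Sequence[str],
    tf_list: Sequence[str],
    n_top: int = 10,
) -> pd.DataFrame:
    """Surrogate network inference: per-target regression importances.

    Each non-TF gene is regressed on the standardized TF expression
    matrix (ridge); the importance of a (tf, target) edge is the absolute
    coefficient. The top ``n_top`` edges per target are kept. Returns a
    frame with columns (tf, target, importance).
    """
    tf_list = list(tf_list)
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    names = list(gene_names)
    idx = {g: i for i, g in enumerate(names)}
    missing = [tf for tf in tf_list if tf not in idx]
    if missing:
        raise KeyError(f"TFs not in gene list: {missing}")
    norm = np.asarray(norm, dtype=float)

    def zscore(m: np.ndarray) -> np.ndarray:
        sd = m.std(axis=0)
        sd[sd == 0] = 1.0
        return (m - m.mean(axis=0)) / sd

    x = zscore(norm[:, [idx[tf] for tf in tf_list]])
    rows = []
    for target in names:
        if target in tf_list:
            continue
        y = norm[:, idx[target]]
        if y.std() == 0:
            continue
        y = (y - y.mean()) / y.std()
        coef = Ridge(alpha=1.0, fit_intercept=False).fit(x, y).coef_
        imp = np.abs(coef)
        for j in np.argsort(-imp, kind="stable")[: min(n_top, len(tf_list))]:
            rows.append({"tf": tf_list[j], "target": target, "importance": float(imp[j])})
    adj = pd.DataFrame(rows, columns=["tf", "target", "importance"])
    if len(adj) and ((adj["tf"] == adj["target"]).any() or not np.isfinite(adj["importance"]).all()):
        raise ValueError("invalid adjacency: self-edges or non-finite importances")
    return adj


def diff_correlated_genes(
    norm: np.ndarray,
    gene_names: Sequence[str],
    bins: np.ndarray,
    anchor: str,
    r_min: float = 0.3,
    early_bins: Sequence[int] = (2, 3, 4),
) -> list[str]:
    """Genes with Pearson r > ``r_min`` against the anchor in early bins.

    The correlation is signed: only positively correlated genes pass.
    """
    names = list(gene_names)
    if anchor not in names:
        raise KeyError(f"anchor gene {anchor!r} missing")
    bins = np.asarray(bins)
    sel = np.isin(bins, list(early_bins))
    if sel.sum() < 3:
        raise ValueError(f"bins {list(early_bins)} contain too few cells ({sel.sum()})")
    sub = np.asarray(norm, dtype=float)[sel]
    a = sub[:, names.index(anchor)]
    if a.std() == 0:
        raise ValueError("anchor has zero variance in the early bins")
    ac = a - a.mean()
    denom_a = np.sqrt((ac**2).sum())
    g = sub - sub.mean(axis=0)
    denom_g = np.sqrt((g**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (g.T @ ac) / (denom_g * denom_a)
    r = np.where(np.isfinite(r), r, 0.0)
    return [names[i] for i in np.flatnonzero(r > r_min)]


def expand_modules(
    adjacency: pd.DataFrame, diff_genes: Sequence[str]
) -> list[RegulonModule]:
    """Every TF touching the diff set becomes a module of ALL its targets."""
    if adjacency.empty:
        raise ValueError("adjacency is empty")
    diff = set(diff_genes)
    modules = []
    for tf, grp in adjacency.groupby("tf", sort=True):
        targets = tuple(sorted(set(grp["target"])))
        if diff & set(targets):
            modules.append(RegulonModule(tf=str(tf), targets=targets))
    return modules


def de_genes_bin1(
    norm: np.ndarray,
    gene_names: Sequence[str],
    bins: np.ndarray,
    alpha: float = 0.05,
    lfc_min: float = 0.5,
) -> list[str]:
    """Genes up in bin 1 vs the rest: BH-adjusted rank-sum p < alpha and
    natural-log fold change (mean bin1 - mean rest of the log-normalized
    values) > lfc_min."""
    bins = np.asarray(bins)
    in1 = bins == 1
    if in1.sum() < 2 or (~in1).sum() < 2:
        raise ValueError("bin 1 and its complement must each have >= 2 cells")
    norm = np.asarray(norm, dtype=float)
    names = list(gene_names)
    lfc = norm[in1].mean(axis=0) - norm[~in1].mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pvals = stats.mannwhitneyu(
            norm[in1], norm[~in1], alternative="two-sided", axis=0
        ).pvalue
    # constant genes carry no evidence
    const = (norm.std(axis=0) == 0)
    pvals = np.where(const, 1.0, pvals)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [names[j] for j in np.flatnonzero((adj < alpha) & (lfc > lfc_min))]


def score_regulons(
    norm: np.ndarray,
    gene_names: Sequence[str],
    modules: Sequence[RegulonModule],
    excluded: Sequence[str] = (),
    ctrl_size: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells x TF table of module scores, excluded genes removed first.

    Modules emptied by the exclusion are skipped with a warning.
    """
    if not modules:
        raise ValueError("modules must be non-empty")
    names = list(gene_names)
    idx = {g: i for i, g in enumerate(names)}
    excl = set(excluded)
    out: dict[str, np.ndarray] = {}
    for mod in modules:
        kept = [t for t in mod.targets if t not in excl]
        if not kept:
            logger.warning("module %s emptied by exclusion; skipped", mod.tf)
            continue
        missing = [t for t in kept if t not in idx]
        if missing:
            raise KeyError(f"module {mod.tf} targets absent genes: {missing}")
        out[mod.tf] = score_gene_set(
            norm, [idx[t] for t in kept], n_bins=n_bins, ctrl_size=ctrl_size, seed=seed
        )
    if not out:
        raise ValueError("all modules were emptied by the exclusion list")
    return pd.DataFrame(out)
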