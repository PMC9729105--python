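"""Single-cell differentiation-trajectory pipeline.

Operations act on dense cells x genes matrices (counts or log-normalized
values) and compose into the standard chain: size-factor log
normalization, covariate regression, highly-variable-gene selection,
Markov-diffusion imputation, count downsampling, diffusion pseudotime,
delamination-point assignment on the ordered cells, equal-count binning
(six basal + four suprabasal), positivity calls, per-gene trend fitting
against the bin-1 baseline, gene-set and cell-cycle scoring, and
spliced/unspliced co-expression summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from epiturn._rng import substream
from epiturn.synth.expression import ExpressionBundle

CLUSTER_LABELS = ("B", "DI", "DII", "KI", "KII")


# ---------------------------------------------------------------------------
# normalization and covariate regression


def normalize_log(counts: np.ndarray) -> np.ndarray:
    """Size-factor normalize and log-transform: ln(x / sf + 1).

    The size factor of a cell is its library size divided by the median
    library size, so the median cell keeps its scale.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    if np.any(lib <= 0):
        bad = int(np.flatnonzero(lib <= 0)[0])
        raise ValueError(f"zero library size for cell {bad}")
    sf = lib / np.median(lib)
    return np.log1p(counts / sf[:, None])


def regress_covariates(norm: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Remove linear covariate effects per gene, keeping the intercept.

    Fits each gene on [1, centred covariates] by least squares
    (pseudoinverse, so rank-deficient designs are tolerated) and returns
    residual + fitted intercept; with centred covariates the intercept is
    the gene mean, so a fully explained gene flattens to its mean.
    """
    norm = np.asarray(norm, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != norm.shape[0]:
        raise ValueError(
            f"covariate rows ({cov.shape[0]}) != cells ({norm.shape[0]})"
        )
    cov = cov - cov.mean(axis=0)
    design = np.column_stack([np.ones(len(norm)), cov])
    beta = np.linalg.pinv(design) @ norm
    resid = norm - design @ beta
    return resid + beta[0][None, :]


def select_hvg(
    norm: np.ndarray,
    n: int = 4000,
    datasets: Optional[Sequence] = None,
    n_mean_bins: int = 20,
) -> np.ndarray:
    """Indices of highly variable genes shared across datasets.

    Within each dataset, genes are ranked by normalized dispersion —
    variance/mean on the linear scale (the log-normalized input is
    expm1-ed back), z-scored within equal-size mean bins — and the top
    ``n`` kept; the result is the intersection over datasets, in gene
    order.
    """
    norm = np.asarray(norm, dtype=float)
    n_genes = norm.shape[1]
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if datasets is None:
        groups = [np.arange(norm.shape[0])]
    else:
        datasets = np.asarray(datasets)
        groups = [np.flatnonzero(datasets == d) for d in pd.unique(datasets)]

    linear = np.expm1(norm)
    keep: Optional[set[int]] = None
    for rows in groups:
        sub = linear[rows]
        mean = sub.mean(axis=0)
        var = sub.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mean > 0, var / mean, 0.0)
        order = np.argsort(mean, kind="stable")
        bins = np.empty(n_genes, dtype=int)
        bins[order] = np.minimum(
            np.arange(n_genes) * n_mean_bins // max(n_genes, 1), n_mean_bins - 1
        )
        zdisp = np.empty(n_genes)
        for b in np.unique(bins):
            sel = bins == b
            mu, sd = disp[sel].mean(), disp[sel].std()
            zdisp[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
        # constant genes always rank last (tolerate expm1 rounding dust)
        zdisp[var <= 1e-10 * np.maximum(mean, 1.0) ** 2] = -np.inf
        top = set(np.argsort(-zdisp, kind="stable")[: min(n, n_genes)].tolist())
        keep = top if keep is None else keep & top
    return np.array(sorted(keep), dtype=int)


# ---------------------------------------------------------------------------
# graphs, imputation, label transfer


def _markov_matrix(
    matrix: np.ndarray, k: int, n_pcs: Optional[int]
) -> sparse.csr_matrix:
    """Row-stochastic transition matrix from an adaptive-bandwidth kNN kernel."""
    x = np.asarray(matrix, dtype=float)
    if n_pcs is not None and 0 < n_pcs < min(x.shape):
        x = PCA(n_components=n_pcs, random_state=0).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    sigma = np.maximum(dist[:, -1], 1e-12)
    aff = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(len(x)), k + 1)
    w = sparse.csr_matrix(
        (aff.ravel(), (rows, idx.ravel())), shape=(len(x), len(x))
    )
    w = (w + w.T) * 0.5
    inv_rowsum = 1.0 / np.asarray(w.sum(axis=1)).ravel()
    return sparse.diags(inv_rowsum) @ w


def magic_impute(
    norm: np.ndarray, k: int = 10, t: int = 2, n_pcs: int = 20
) -> np.ndarray:
    """Diffusion-smooth expression: M^t applied to the normalized matrix.

    M is the row-normalized, symmetrized adaptive Gaussian kNN kernel
    (bandwidth = distance to the k-th neighbour) built in PC space.
    ``t = 0`` returns the input unchanged.
    """
    norm = np.asarray(norm, dtype=float)
    if k >= norm.shape[0]:
        raise ValueError(f"k = {k} must be < n_cells = {norm.shape[0]}")
    if t == 0:
        return norm.copy()
    m = _markov_matrix(norm, k, n_pcs)
    out = norm
    for _ in range(t):
        out = m @ out
    return np.asarray(out)


def knn_transfer(
    ref_matrix: np.ndarray,
    ref_labels: Sequence,
    query_matrix: np.ndarray,
    k: int = 20,
) -> np.ndarray:
    """Distance-weighted (1/d) k-nearest-neighbour label transfer.

    A zero-distance reference cell wins outright; exact vote ties fall to
    the label of the single nearest neighbour.
    """
    ref = np.asarray(ref_matrix, dtype=float)
    query = np.asarray(query_matrix, dtype=float)
    labels = np.asarray(ref_labels)
    if ref.shape[1] != query.shape[1]:
        raise ValueError("reference and query gene spaces differ")
    if k > ref.shape[0]:
        raise ValueError(f"k = {k} exceeds n_ref = {ref.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(query)
    out = np.empty(len(query), dtype=labels.dtype)
    for i in range(len(query)):
        d, nbr = dist[i], labels[idx[i]]
        if d[0] == 0.0:
            out[i] = nbr[0]
            continue
        votes: dict = {}
        for lab, w in zip(nbr, 1.0 / d):
            votes[lab] = votes.get(lab, 0.0) + w
        best = max(votes.values())
        winners = [lab for lab, v in votes.items() if v == best]
        out[i] = winners[0] if len(winners) == 1 else nbr[0]
    return out


def downsample_counts(
    counts: np.ndarray, target: int = 2000, seed: int = 0
) -> np.ndarray:
    """Downsample each cell to at most ``target`` total counts.

    Cells above the target draw ``target`` items without replacement from
    their count multiset (multivariate hypergeometric); cells at or below
    it are returned unchanged. Never creates counts where there were none.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    rng = substream(seed, "downsample")
    out = counts.copy()
    totals = counts.sum(axis=1)
    for i in np.flatnonzero(totals > target):
        out[i] = rng.multivariate_hypergeometric(
            counts[i], target, method="marginals"
        )
    return out


# ---------------------------------------------------------------------------
# pseudotime, boundary, bins


def diffusion_pseudotime(
    matrix: np.ndarray,
    root: Optional[int] = None,
    anchor: Optional[np.ndarray] = None,
    k: int = 15,
    n_comps: int = 10,
    n_pcs: Optional[int] = 20,
) -> np.ndarray:
    """Diffusion pseudotime in [0, 1] from a root cell.

    Builds the Markov transition operator on the kNN graph, takes its
    spectral decomposition, embeds cells in diffusion components scaled
    by lambda / (1 - lambda), and measures Euclidean (diffusion) distance
    from the root, min-max scaled. If ``root`` is omitted, the root is
    the cell with minimal ``anchor`` expression among the 5% of cells at
    the low-anchor end of the first diffusion component. If ``anchor`` is
    given and the result anticorrelates with it, orientation is flipped.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if root is None and anchor is None:
        raise ValueError("provide a root cell or an anchor expression vector")
    m = _markov_matrix(x, k, n_pcs)
    n_cc, comp = connected_components(m > 0, directed=False)
    if n_cc > 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"kNN graph is disconnected ({n_cc} components, sizes {sizes.tolist()})"
        )
    # the symmetric conjugate S = D^-1/2 W D^-1/2 of M = D^-1 W shares its
    # spectrum and gives orthogonal eigenvectors
    dense = m.toarray()
    d = _kernel_rowsums(x, k, n_pcs)
    s = np.sqrt(d)[:, None] * dense / np.sqrt(d)[None, :]
    s = 0.5 * (s + s.T)  # numerical symmetry
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of M; drop the stationary component
    psi = evecs / np.sqrt(d)[:, None]
    lam = np.clip(evals[1 : n_comps + 1], None, 1.0 - 1e-10)
    coords = psi[:, 1 : n_comps + 1] * (lam / (1.0 - lam))[None, :]

    if root is None:
        dc1 = coords[:, 0]
        n_cand = max(1, int(np.ceil(0.05 * n)))
        low = np.argsort(dc1, kind="stable")[:n_cand]
        high = np.argsort(-dc1, kind="stable")[:n_cand]
        anchor = np.asarray(anchor, dtype=float)
        cand = low if anchor[low].mean() <= anchor[high].mean() else high
        root = int(cand[np.argmin(anchor[cand])])

    dist = np.linalg.norm(coords - coords[root][None, :], axis=1)
    rng_ = dist.max() - dist.min()
    pt = (dist - dist.min()) / rng_ if rng_ > 0 else np.zeros(n)
    if anchor is not None:
        anchor = np.asarray(anchor, dtype=float)
        if np.std(anchor) > 0 and np.corrcoef(pt, anchor)[0, 1] < 0:
            pt = 1.0 - pt
    return pt


def _kernel_rowsums(x: np.ndarray, k: int, n_pcs: Optional[int]) -> np.ndarray:
    """Row sums of the symmetrized affinity kernel (pre-normalization)."""
    x = np.asarray(x, dtype=float)
    if n_pcs is not None and 0 < n_pcs < min(x.shape):
        x = PCA(n_components=n_pcs, random_state=0).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    sigma = np.maximum(dist[:, -1], 1e-12)
    aff = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(len(x)), k + 1)
    w = sparse.csr_matrix((aff.ravel(), (rows, idx.ravel())), shape=(len(x), len(x)))
    w = (w + w.T) * 0.5
    return np.asarray(w.sum(axis=1)).ravel()


def order_cells(pseudotime: np.ndarray) -> np.ndarray:
    """0-based rank of each cell along pseudotime (0 = most basal)."""
    order = np.empty(len(pseudotime), dtype=int)
    order[np.argsort(pseudotime, kind="stable")] = np.arange(len(pseudotime))
    return order


def assign_delamination_point(
    order: np.ndarray, sorted_flags: np.ndarray, q: float = 0.95
) -> int:
    """Boundary rank: position of the ceil(q * n_sorted)-th sorted cell.

    Cells whose order rank is at or before the boundary are basal-side.
    """
    order = np.asarray(order)
    flags = np.asarray(sorted_flags, dtype=bool)
    if len(order) != len(flags):
        raise ValueError("order and sorted_flags differ in length")
    ranks = np.sort(order[flags])
    if len(ranks) == 0:
        raise ValueError("no sorted cells")
    kth = int(np.ceil(q * len(ranks)))
    return int(ranks[max(kth - 1, 0)])


def bin_cells(
    order: np.ndarray, boundary: int, n_basal: int = 6, n_supra: int = 4
) -> np.ndarray:
    """Ten equal-count pseudotime bins: 1..n_basal basal, then suprabasal.

    Each side is split into equal-count bins by order; remainders go to
    the earliest bins of that side.
    """
    order = np.asarray(order)
    n = len(order)
    n_b = int(boundary) + 1
    n_s = n - n_b
    if n_b < n_basal or n_s < n_supra:
        raise ValueError(
            f"too few cells per side: {n_b} basal for {n_basal} bins, "
            f"{n_s} suprabasal for {n_supra} bins"
        )
    bins_by_rank = np.empty(n, dtype=int)
    start = 0
    for b, chunk in enumerate(np.array_split(np.arange(n_b), n_basal)):
        bins_by_rank[start : start + len(chunk)] = b + 1
        start += len(chunk)
    for b, chunk in enumerate(np.array_split(np.arange(n_s), n_supra)):
        bins_by_rank[start : start + len(chunk)] = n_basal + b + 1
        start += len(chunk)
    return bins_by_rank[order]


def classify_positive(
    values: np.ndarray, cutoff: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """Strictly-above-cutoff positivity; default cutoff is the mean."""
    values = np.asarray(values, dtype=float)
    if cutoff is None:
        cutoff = float(values.mean())
    return values > cutoff, float(cutoff)


# ---------------------------------------------------------------------------
# trends and scores


@dataclass
class TrendFit:
    fitted: np.ndarray       # per cell, in order-rank space
    delta: np.ndarray        # fitted minus bin-1 baseline
    baseline: float
    window: int


def fit_trend(
    values: np.ndarray,
    order: np.ndarray,
    bins: np.ndarray,
    window_frac: float = 0.05,
    min_window: int = 31,
) -> TrendFit:
    """Centred rolling-mean expression along the ordered cells.

    The window is max(min_window, window_frac * n) forced odd and
    truncated at the edges; the baseline is the mean over bin-1 cells and
    ``delta`` is fitted minus baseline. Arrays are in cell space (the
    ``fitted`` value of cell i corresponds to its order rank).
    """
    values = np.asarray(values, dtype=float)
    order = np.asarray(order)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 cells")
    win = max(min_window, int(round(window_frac * n)))
    if win % 2 == 0:
        win += 1
    ranked = values[np.argsort(order, kind="stable")]
    fitted_ranked = (
        pd.Series(ranked).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )
    fitted = fitted_ranked[order]
    baseline = float(values[np.asarray(bins) == 1].mean())
    return TrendFit(fitted=fitted, delta=fitted - baseline, baseline=baseline, window=win)


def score_gene_set(
    norm: np.ndarray,
    gene_idx: Sequence[int],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell expression score of a gene set against matched controls.

    Genes are grouped into ``n_bins`` equal-size bins of mean expression;
    for each bin occupied by set genes, ``ctrl_size`` control genes are
    sampled from that bin (excluding the set where possible). The score
    is mean(set) - mean(controls) per cell.
    """
    norm = np.asarray(norm, dtype=float)
    gene_idx = np.asarray(gene_idx, dtype=int)
    if gene_idx.size == 0:
        raise ValueError("gene set is empty")
    if gene_idx.min() < 0 or gene_idx.max() >= norm.shape[1]:
        raise KeyError("gene set contains absent gene indices")
    rng = substream(seed, "gene_set_score")
    n_genes = norm.shape[1]
    mean_expr = norm.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.arange(n_genes) * n_bins // n_genes

    in_set = np.zeros(n_genes, dtype=bool)
    in_set[gene_idx] = True
    ctrl: list[int] = []
    for b in np.unique(bins[gene_idx]):
        pool = np.flatnonzero((bins == b) & ~in_set)
        if pool.size == 0:
            pool = np.flatnonzero(bins == b)  # degenerate: fall back to the set
        take = min(ctrl_size, pool.size)
        ctrl.extend(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.unique(ctrl)
    return norm[:, gene_idx].mean(axis=1) - norm[:, ctrl_idx].mean(axis=1)


def assign_cycle_phase(
    s_score: np.ndarray, g2m_score: np.ndarray, cutoff: float = 0.05
) -> np.ndarray:
    """G1 unless a score strictly exceeds the cutoff; larger score wins (tie: S)."""
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    if not (np.isfinite(s).all() and np.isfinite(g).all()):
        raise ValueError("scores must be finite")
    phase = np.where(
        np.maximum(s, g) > cutoff, np.where(g > s, "G2M", "S"), "G1"
    )
    return phase.astype(object)


def splicing_coexpression(
    bundle: ExpressionBundle,
    bins: np.ndarray,
    gene_a: str,
    gene_b: str,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-bin spliced/unspliced summaries and co-expression flags.

    Summaries are means of log(count + 1) per bin for the unspliced
    ``gene_a`` and spliced ``gene_b`` (plus the converse layers). A cell
    co-expresses when all four of gene_a/gene_b spliced/unspliced counts
    are > 0.
    """
    for layer in ("spliced", "unspliced"):
        if layer not in bundle.layers:
            raise ValueError(f"missing layer {layer!r}")
    ia, ib = bundle.gene_index(gene_a), bundle.gene_index(gene_b)
    spl, uns = bundle.layers["spliced"], bundle.layers["unspliced"]
    logs = {
        f"{gene_a}_unspliced": np.log1p(uns[:, ia]),
        f"{gene_a}_spliced": np.log1p(spl[:, ia]),
        f"{gene_b}_unspliced": np.log1p(uns[:, ib]),
        f"{gene_b}_spliced": np.log1p(spl[:, ib]),
    }
    df = pd.DataFrame({"bin": np.asarray(bins), **logs})
    summary = df.groupby("bin").mean()
    summary["n_cells"] = df.groupby("bin").size()
    coexpr = (
        (spl[:, ia] > 0) & (uns[:, ia] > 0) & (spl[:, ib] > 0) & (uns[:, ib] > 0)
    )
    return summary, coexpr


# ---------------------------------------------------------------------------
# assembled pipeline


@dataclass
class PseudotimeFrame:
    """Per-cell trajectory results plus the delamination boundary."""

    table: pd.DataFrame       # pseudotime, order, bin, positive, phase, ...
    boundary: int
    positive_cutoff: float


def run_pipeline(
    bundle: ExpressionBundle,
    anchor: str,
    n_hvg: int = 4000,
    target_counts: int = 2000,
    k_graph: int = 30,
    n_comps: int = 10,
    n_pcs: Optional[int] = 20,
    cycle_genes: Optional[tuple[Sequence[str], Sequence[str]]] = None,
    seed: int = 0,
) -> PseudotimeFrame:
    """Counts -> pseudotime -> boundary -> bins -> positivity (+ phases).

    When ``cycle_genes`` (S-phase and G2M marker lists) are given, the
    two phase scores and the log library size are regressed out of the
    normalized matrix before graph construction, so the cell-cycle axis
    does not contaminate the differentiation trajectory; positivity calls
    and phase scores themselves stay on the unregressed matrix.
    """
    down = downsample_counts(bundle.counts, target=target_counts, seed=seed)
    norm = normalize_log(down)
    ai = bundle.gene_index(anchor)
    anchor_expr = norm[:, ai]

    s_score = g2m_score = None
    covs = [np.log(down.sum(axis=1))]
    if cycle_genes is not None:
        s_genes, g2m_genes = cycle_genes
        s_idx = [bundle.gene_index(g) for g in s_genes]
        g_idx = [bundle.gene_index(g) for g in g2m_genes]
        s_score = score_gene_set(norm, s_idx, seed=seed)
        g2m_score = score_gene_set(norm, g_idx, seed=seed + 1)
        covs += [s_score, g2m_score]
    resid = regress_covariates(norm, np.column_stack(covs))

    hvg = select_hvg(resid, n=n_hvg, datasets=bundle.cells["dataset"].to_numpy())
    pt = diffusion_pseudotime(
        resid[:, hvg], anchor=anchor_expr, k=k_graph, n_comps=n_comps, n_pcs=n_pcs
    )
    order = order_cells(pt)
    boundary = assign_delamination_point(
        order, bundle.cells["sorted"].to_numpy(), q=0.95
    )
    bins = bin_cells(order, boundary)
    positive, cutoff = classify_positive(anchor_expr)
    table = pd.DataFrame(
        {
            "pseudotime": pt,
            "order": order,
            "bin": bins,
            f"{anchor}_positive": positive,
        },
        index=bundle.cells.index,
    )
    if s_score is not None:
        table["s_score"] = s_score
        table["g2m_score"] = g2m_score
        table["phase"] = assign_cycle_phase(s_score, g2m_score)
    return PseudotimeFrame(table=table, boundary=boundary, positive_cutoff=cutoff)
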