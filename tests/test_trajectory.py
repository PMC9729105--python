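import numpy as np
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from epiturn import trajectory as tj
from epiturn.synth.expression import ExprSimConfig, GeneProgram, simulate_expression


class TestNormalizeLog:
    def test_identical_cells_identical_rows(self, rng):
        row = rng.integers(0, 20, size=30)
        counts = np.vstack([row, row, rng.integers(1, 20, size=30)])
        norm = tj.normalize_log(counts)
        np.testing.assert_allclose(norm[0], norm[1])

    def test_doubled_cell_normalizes_equal(self, rng):
        a = rng.integers(1, 30, size=25)
        counts = np.vstack([a, 2 * a, rng.integers(1, 30, size=25)])
        norm = tj.normalize_log(counts)
        np.testing.assert_allclose(norm[0], norm[1], rtol=1e-12)

    def test_zero_cell_rejected(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="zero library size"):
            tj.normalize_log(counts)


class TestRegressCovariates:
    def test_orthogonal_covariate_no_change(self):
        cov = np.tile([1.0, -1.0], 24)
        gene = np.tile([1.0, 1.0, 2.0, 2.0], 12)  # orthogonal by construction
        assert abs(np.dot(cov - cov.mean(), gene - gene.mean())) < 1e-9
        out = tj.regress_covariates(gene[:, None], cov)
        np.testing.assert_allclose(out[:, 0], gene, atol=1e-9)

    def test_fully_explained_gene_flattens_to_mean(self, rng):
        cov = rng.normal(size=40)
        gene = 2.0 * cov
        out = tj.regress_covariates(gene[:, None], cov)
        np.testing.assert_allclose(out[:, 0], gene.mean(), atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="covariate rows"):
            tj.regress_covariates(np.zeros((10, 3)), np.zeros(9))

    def test_rank_deficient_design_tolerated(self, rng):
        cov = rng.normal(size=20)
        design = np.c_[cov, cov]  # duplicated column
        out = tj.regress_covariates(rng.normal(size=(20, 2)), design)
        assert np.isfinite(out).all()


class TestSelectHVG:
    def test_all_genes_when_n_large(self, rng):
        norm = rng.random((30, 8))
        assert len(tj.select_hvg(norm, n=100)) == 8

    def test_constant_gene_ranked_last(self, rng):
        norm = rng.random((40, 5))
        norm[:, 2] = 3.0
        top = tj.select_hvg(norm, n=4)
        assert 2 not in top

    def test_planted_high_dispersion_selected(self, rng):
        n_cells, n_genes = 300, 200
        counts = rng.poisson(5.0, size=(n_cells, n_genes)).astype(float)
        hot = [3, 50, 120]
        for j in hot:  # 10x overdispersed: gamma-mixed Poisson, same mean
            lam = rng.gamma(0.5, 10.0, size=n_cells)
            counts[:, j] = rng.poisson(lam)
        norm = tj.normalize_log(counts + 1)
        top = tj.select_hvg(norm, n=20)
        assert set(hot) <= set(top.tolist())

    def test_intersection_across_datasets(self, rng):
        norm = rng.random((60, 20))
        datasets = np.r_[np.zeros(30), np.ones(30)]
        top = tj.select_hvg(norm, n=10, datasets=datasets)
        t0 = tj.select_hvg(norm[:30], n=10)
        t1 = tj.select_hvg(norm[30:], n=10)
        assert set(top.tolist()) == set(t0.tolist()) & set(t1.tolist())


class TestMagic:
    def test_t_zero_identity(self, rng):
        norm = rng.random((40, 6))
        np.testing.assert_array_equal(tj.magic_impute(norm, k=5, t=0), norm)

    def test_blob_variance_shrinks_means_kept(self, rng):
        a = rng.normal(0.0, 1.0, size=(60, 4))
        b = rng.normal(20.0, 1.0, size=(60, 4))
        norm = np.vstack([a, b])
        out = tj.magic_impute(norm, k=5, t=2, n_pcs=None)
        for rows in (slice(0, 60), slice(60, 120)):
            assert out[rows].var(axis=0).sum() < norm[rows].var(axis=0).sum()
            np.testing.assert_allclose(
                out[rows].mean(axis=0), norm[rows].mean(axis=0), atol=0.35
            )

    def test_doubly_stochastic_limit_is_global_mean(self):
        # regular simplex: all pairwise distances equal -> uniform kernel
        x = np.eye(5) * 3.0
        out = tj.magic_impute(x, k=4, t=400, n_pcs=None)
        np.testing.assert_allclose(out, x.mean(axis=0)[None, :].repeat(5, 0), atol=1e-6)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError, match="k ="):
            tj.magic_impute(rng.random((5, 3)), k=5)


class TestKnnTransfer:
    def test_query_equals_reference_cell(self, rng):
        ref = rng.random((30, 4))
        labels = np.array(["B"] * 15 + ["DI"] * 15)
        out = tj.knn_transfer(ref, labels, ref[[3, 20]], k=5)
        assert list(out) == [labels[3], labels[20]]

    def test_separated_blobs_100pct(self, rng):
        ref = np.vstack([rng.normal(0, 0.5, (40, 3)), rng.normal(10, 0.5, (40, 3))])
        labels = np.array(["B"] * 40 + ["DI"] * 40)
        query = np.vstack([rng.normal(0, 0.5, (25, 3)), rng.normal(10, 0.5, (25, 3))])
        truth = np.array(["B"] * 25 + ["DI"] * 25)
        out = tj.knn_transfer(ref, labels, query, k=20)
        assert (out == truth).all()

    def test_k_exceeds_reference(self, rng):
        with pytest.raises(ValueError, match="exceeds n_ref"):
            tj.knn_transfer(rng.random((5, 2)), ["a"] * 5, rng.random((2, 2)), k=9)

    def test_gene_space_mismatch(self, rng):
        with pytest.raises(ValueError, match="gene spaces"):
            tj.knn_transfer(rng.random((5, 3)), ["a"] * 5, rng.random((2, 4)), k=2)


class TestDownsample:
    def test_cell_at_target_unchanged(self, rng):
        row = rng.multinomial(2000, np.ones(50) / 50)
        counts = row[None, :]
        out = tj.downsample_counts(counts, target=2000, seed=0)
        np.testing.assert_array_equal(out, counts)

    def test_totals_capped(self, rng):
        counts = rng.integers(0, 300, size=(20, 40))
        out = tj.downsample_counts(counts, target=2000, seed=1)
        expect = np.minimum(counts.sum(axis=1), 2000)
        np.testing.assert_array_equal(out.sum(axis=1), expect)

    def test_never_creates_counts(self, rng):
        counts = rng.integers(0, 200, size=(15, 30))
        counts[:, 5] = 0
        out = tj.downsample_counts(counts, target=100, seed=2)
        assert (out <= counts).all()
        assert (out[:, 5] == 0).all()

    def test_hypergeometric_expectation(self):
        # over repeated draws the mean per-gene count matches its share
        cell = np.array([[5000, 3000, 2000]])
        target = 1000
        reps = np.vstack([
            tj.downsample_counts(cell, target=target, seed=s) for s in range(400)
        ])
        mean = reps.mean(axis=0)
        share = cell[0] / cell.sum()
        expect = share * target
        # binomial-style CI on the mean of 400 draws
        se = np.sqrt(share * (1 - share) * target / 400)
        assert np.all(np.abs(mean - expect) < 5 * se)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tj.downsample_counts(np.array([[-1, 2]]))


class TestDiffusionPseudotime:
    def test_root_is_zero(self, rng):
        x = np.linspace(0, 10, 40)[:, None]
        x = np.c_[x, rng.normal(0, 0.05, size=(40, 1))]
        pt = tj.diffusion_pseudotime(x, root=0, k=5, n_pcs=None)
        assert pt[0] == 0.0

    def test_chain_monotone(self):
        x = np.arange(30, dtype=float)[:, None]
        pt = tj.diffusion_pseudotime(x, root=0, k=3, n_pcs=None)
        assert np.all(np.diff(pt) > 0)

    def test_recovers_latent_axis(self):
        cfg = ExprSimConfig(
            n_cells={"d": 400}, depth_mean={"d": 3000.0},
            nb_dispersion=0.15, seed=21,
        )
        b = simulate_expression(cfg)
        norm = tj.normalize_log(b.counts)
        hvg = tj.select_hvg(norm, n=60)
        anchor = norm[:, b.gene_index("DIFF000")]
        pt = tj.diffusion_pseudotime(norm[:, hvg], anchor=anchor, k=30)
        s = b.cells["latent_s"].to_numpy()
        assert spearmanr(pt, s).statistic >= 0.9

    def test_needs_root_or_anchor(self, rng):
        with pytest.raises(ValueError, match="root"):
            tj.diffusion_pseudotime(rng.random((20, 3)))

    def test_disconnected_graph_reported(self):
        x = np.vstack([np.zeros((10, 2)), np.full((10, 2), 1e6)])
        x += np.random.default_rng(0).normal(0, 0.01, x.shape)
        with pytest.raises(ValueError, match="disconnected"):
            tj.diffusion_pseudotime(x, root=0, k=3, n_pcs=None)


class TestBoundaryAndBins:
    def test_boundary_simple_ranks(self):
        # 100 sorted cells at ranks 0..99 among 200 cells total
        order = np.arange(200)
        flags = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        b = tj.assign_delamination_point(order, flags, q=0.95)
        assert b == 94  # ceil(0.95 * 100) = 95th sorted cell, rank 94

    def test_boundary_matches_bruteforce(self, rng):
        order = rng.permutation(150)
        flags = rng.random(150) < 0.4
        b = tj.assign_delamination_point(order, flags, q=0.95)
        ranks = sorted(order[flags])
        assert b == ranks[int(np.ceil(0.95 * len(ranks))) - 1]

    def test_no_sorted_cells(self):
        with pytest.raises(ValueError, match="no sorted"):
            tj.assign_delamination_point(np.arange(5), np.zeros(5, bool))

    def test_sixty_basal_six_bins_of_ten(self):
        order = np.arange(100)
        bins = tj.bin_cells(order, boundary=59)
        sizes = np.bincount(bins)[1:]
        assert list(sizes) == [10] * 6 + [10] * 4

    def test_remainder_goes_to_earliest(self):
        order = np.arange(101)
        bins = tj.bin_cells(order, boundary=60)  # 61 basal cells
        sizes = np.bincount(bins)[1:7]
        assert list(sizes) == [11, 10, 10, 10, 10, 10]

    def test_bin_nondecreasing_in_order(self, rng):
        order = rng.permutation(87)
        bins = tj.bin_cells(order, boundary=52)
        ranked_bins = bins[np.argsort(order)]
        assert np.all(np.diff(ranked_bins) >= 0)
        assert set(ranked_bins) == set(range(1, 11))
        sizes = np.bincount(ranked_bins)[1:]
        assert sizes[:6].max() - sizes[:6].min() <= 1
        assert sizes[6:].max() - sizes[6:].min() <= 1

    def test_too_few_cells_per_side(self):
        with pytest.raises(ValueError, match="too few"):
            tj.bin_cells(np.arange(8), boundary=3)


class TestClassifyPositive:
    def test_mean_cutoff(self):
        flags, cutoff = tj.classify_positive(np.array([0.0, 2.0]))
        assert cutoff == 1.0
        assert list(flags) == [False, True]

    def test_all_zero(self):
        flags, _ = tj.classify_positive(np.zeros(10))
        assert not flags.any()

    def test_strict_boundary(self):
        flags, _ = tj.classify_positive(np.array([1.0, 1.0, 1.0]), cutoff=1.0)
        assert not flags.any()

    def test_planted_mixture_fraction(self, rng):
        lo = rng.normal(0.2, 0.05, size=600)
        hi = rng.normal(3.0, 0.3, size=400)
        values = np.r_[lo, hi]
        flags, _ = tj.classify_positive(values)
        assert abs(flags.mean() - 0.4) <= 0.03


class TestFitTrend:
    def test_constant_gene_zero_delta(self):
        n = 80
        order = np.arange(n)
        bins = tj.bin_cells(order, boundary=47)
        fit = tj.fit_trend(np.full(n, 2.5), order, bins)
        np.testing.assert_allclose(fit.delta, 0.0, atol=1e-12)

    def test_linear_ramp_interior_exact(self):
        n = 200
        order = np.arange(n)
        values = 0.05 * order + 1.0
        bins = tj.bin_cells(order, boundary=119)
        fit = tj.fit_trend(values, order, bins)
        half = fit.window // 2
        np.testing.assert_allclose(
            fit.fitted[half : n - half], values[half : n - half], atol=1e-6
        )

    def test_baseline_is_bin1_mean(self, rng):
        n = 120
        order = rng.permutation(n)
        values = rng.random(n)
        bins = tj.bin_cells(order, boundary=71)
        fit = tj.fit_trend(values, order, bins)
        assert fit.baseline == pytest.approx(values[bins == 1].mean())


class TestScoreGeneSet:
    def test_degenerate_control_pool_scores_zero(self, rng):
        norm = rng.random((30, 6))
        scores = tj.score_gene_set(norm, np.arange(6), n_bins=1, ctrl_size=6, seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_planted_up_genes_raise_scores(self, rng):
        norm = rng.normal(0, 1, size=(200, 60))
        hot_cells = np.arange(60)
        gene_set = np.arange(8)
        norm[np.ix_(hot_cells, gene_set)] += 2.0
        scores = tj.score_gene_set(norm, gene_set, seed=1)
        p = mannwhitneyu(
            scores[hot_cells], scores[60:], alternative="greater"
        ).pvalue
        assert p < 0.01

    def test_absent_gene_rejected(self, rng):
        with pytest.raises(KeyError, match="absent"):
            tj.score_gene_set(rng.random((10, 5)), [7])

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            tj.score_gene_set(rng.random((10, 5)), [])


class TestCyclePhase:
    def test_examples(self):
        assert tj.assign_cycle_phase([0.2], [0.01])[0] == "S"
        assert tj.assign_cycle_phase([0.04], [0.04])[0] == "G1"
        assert tj.assign_cycle_phase([0.06], [0.06])[0] == "S"  # tie -> S
        assert tj.assign_cycle_phase([0.01], [0.3])[0] == "G2M"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            tj.assign_cycle_phase([np.nan], [0.0])

    def test_planted_cycling_detected(self):
        cfg = ExprSimConfig(
            n_cells={"d": 500},
            depth_mean={"d": 4000.0},
            cycling_fraction=0.2,
            cycle_boost=8.0,
            seed=12,
        )
        b = simulate_expression(cfg)
        norm = tj.normalize_log(b.counts)
        cyc_idx = np.flatnonzero((b.genes["class"] == "cycle").to_numpy())
        half = len(cyc_idx) // 2
        s_score = tj.score_gene_set(norm, cyc_idx[:half], seed=1)
        g2m_score = tj.score_gene_set(norm, cyc_idx[half:], seed=2)
        phase = tj.assign_cycle_phase(s_score, g2m_score, cutoff=0.05)
        predicted = phase != "G1"
        truth = b.cells["cycling"].to_numpy()
        sensitivity = predicted[truth].mean()
        specificity = (~predicted[~truth]).mean()
        assert sensitivity >= 0.9 and specificity >= 0.9


class TestSplicingCoexpression:
    def toy_bundle(self):
        import pandas as pd

        from epiturn.synth.expression import ExpressionBundle

        spl = np.array([[0, 0], [2, 0], [3, 4], [0, 5]])
        uns = np.array([[0, 0], [1, 1], [2, 2], [0, 1]])
        counts = spl + uns
        genes = pd.DataFrame(index=pd.Index(["a", "b"], name="gene"))
        cells = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(4)], name="cell"))
        return ExpressionBundle(
            counts=counts, genes=genes, cells=cells,
            layers={"spliced": spl, "unspliced": uns},
        )

    def test_all_zero_cell_not_coexpressing(self):
        b = self.toy_bundle()
        _, flags = tj.splicing_coexpression(b, np.ones(4, dtype=int), "a", "b")
        assert not flags[0]

    def test_matches_bruteforce(self):
        b = self.toy_bundle()
        _, flags = tj.splicing_coexpression(b, np.ones(4, dtype=int), "a", "b")
        spl, uns = b.layers["spliced"], b.layers["unspliced"]
        expect = [
            spl[i, 0] > 0 and uns[i, 0] > 0 and spl[i, 1] > 0 and uns[i, 1] > 0
            for i in range(4)
        ]
        assert list(flags) == expect

    def test_missing_layers_rejected(self, trajectory_bundle):
        b = self.toy_bundle()
        b.layers.pop("unspliced")
        with pytest.raises(ValueError, match="unspliced"):
            tj.splicing_coexpression(b, np.ones(4, dtype=int), "a", "b")

    def test_lag_creates_midtrajectory_overlap(self, trajectory_bundle):
        b = trajectory_bundle  # simulated with splicing_lag = 0.1
        s = b.cells["latent_s"].to_numpy()
        order = tj.order_cells(s)
        flags = b.cells["sorted"].to_numpy()
        boundary = tj.assign_delamination_point(order, flags)
        bins = tj.bin_cells(order, boundary)
        summary, _ = tj.splicing_coexpression(b, bins, "BASAL000", "DIFF000")
        mid = np.isin(bins, [5, 6, 7])
        uns_basal = b.layers["unspliced"][:, b.gene_index("BASAL000")]
        spl_diff = b.layers["spliced"][:, b.gene_index("DIFF000")]
        both = (uns_basal > 0) & (spl_diff > 0) & mid
        assert both.sum() > 0
        assert set(summary.index) == set(range(1, 11))


class TestRunPipeline:
    def test_recovery_and_binning(self, trajectory_bundle):
        b = trajectory_bundle
        cyc = [g for g in b.genes.index if g.startswith("CYC")]
        ptf = tj.run_pipeline(
            b, anchor="DIFF000", n_hvg=60, seed=1,
            cycle_genes=(cyc[:5], cyc[5:]),
        )
        s = b.cells["latent_s"].to_numpy()
        rho = spearmanr(ptf.table["pseudotime"], s).statistic
        assert rho >= 0.9
        basal_true = s < 0.5
        frac = (ptf.table["bin"].to_numpy()[basal_true] <= 6).mean()
        assert frac >= 0.9
        sizes = np.bincount(ptf.table["bin"])[1:]
        assert len(sizes) == 10
        assert sizes[:6].max() - sizes[:6].min() <= 1
        assert sizes[6:].max() - sizes[6:].min() <= 1
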