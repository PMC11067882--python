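"""Normalization, PCA, differentiation index, potency tests, gene sets."""

import itertools

import numpy as np
import pandas as pd
import pytest

from itfscreen.diffindex import (
    AllZeroCell,
    ControlReference,
    DegenerateControls,
    PcSpace,
    SetTooSmall,
    ZeroVarianceRow,
    as_expression_frame,
    compute_differentiation_index,
    differentiation_index_pipeline,
    filter_gene_sets,
    fit_pca,
    geneset_indexes,
    normalize_counts,
    percentile_ranks,
    ribosomal_genes,
    test_potency,
    tf_similarity,
)
from itfscreen.simulate import ExprSimParams, PopulationSpec, simulate_expression_cohort


def make_pcspace(scores: pd.DataFrame) -> PcSpace:
    """PcSpace wrapper around hand-written PC coordinates."""
    k = scores.shape[1]
    return PcSpace(
        scores=scores,
        loadings=pd.DataFrame(np.eye(k), columns=scores.columns),
        mean=pd.Series(np.zeros(k)),
        n_pcs=k,
    )


class TestNormalize:
    def test_direct_arithmetic(self):
        counts = pd.DataFrame([[1, 3]], index=["c"], columns=["g1", "g2"])
        out = normalize_counts(counts)
        np.testing.assert_allclose(out.to_numpy()[0],
                                   np.log1p([2500.0, 7500.0]))
        assert out.attrs["normalization"] == "log1p_cp10k"

    def test_all_zero_cell_left_as_zero_with_warning(self):
        counts = pd.DataFrame([[0, 0], [2, 2]], columns=["g1", "g2"])
        with pytest.warns(AllZeroCell):
            out = normalize_counts(counts)
        assert (out.iloc[0] == 0).all()

    def test_per_cell_scale_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(0, 20, size=(5, 8)))
        doubled = counts.copy()
        doubled.iloc[2] *= 2
        pd.testing.assert_frame_equal(normalize_counts(counts),
                                      normalize_counts(doubled))

    def test_pluggable_method(self):
        counts = pd.DataFrame([[1.0, 3.0]], columns=["g1", "g2"])
        def sqrt_stab(df):
            return np.sqrt(df)
        out = normalize_counts(counts, method=sqrt_stab)
        np.testing.assert_allclose(out.to_numpy(), np.sqrt([[1.0, 3.0]]))
        assert out.attrs["normalization"] == "sqrt_stab"


class TestPca:
    def test_degenerate_single_variable_gene(self):
        X = pd.DataFrame(np.zeros((6, 4)), columns=list("abcd"))
        X["c"] = [0, 1, 2, 3, 4, 5]
        pcs = fit_pca(X, n_pcs=2)
        assert abs(pcs.loadings.loc["c", "PC1"]) == pytest.approx(1.0)
        assert pcs.scores["PC2"].std() == pytest.approx(0.0, abs=1e-9)

    def test_scores_match_dense_eigendecomposition(self, rng):
        """6 cells x 4 genes toy vs brute-force eig of the centered covariance."""
        X = rng.normal(size=(6, 4))
        df = pd.DataFrame(X, columns=list("abcd"))
        pcs = fit_pca(df, n_pcs=3)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (6 - 1))
        order = np.argsort(evals)[::-1][:3]
        expected = Xc @ evecs[:, order]
        got = pcs.scores.to_numpy()
        for j in range(3):  # eigenvector sign is arbitrary; align per column
            if np.dot(expected[:, j], got[:, j]) < 0:
                expected[:, j] *= -1
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_excluded_genes_absent_from_loadings(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        pcs = fit_pca(df, n_pcs=2, exclude_genes=["b", "zz"])
        assert "b" not in pcs.loadings.index and pcs.excluded_genes == ["b"]

    def test_rank_capping_warns(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.warns(Warning, match="n_pcs reduced"):
            pcs = fit_pca(df, n_pcs=50)
        assert pcs.n_pcs == 3

    def test_loadings_orthonormal(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 6)))
        pcs = fit_pca(df, n_pcs=4)
        L = pcs.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-10)


class TestDifferentiationIndex:
    def test_controls_have_mean_zero_sd_one(self, rng):
        scores = pd.DataFrame(rng.normal(size=(40, 5)),
                              index=[f"c{i}" for i in range(40)])
        controls = [f"c{i}" for i in range(25)]
        idx, ref = compute_differentiation_index(make_pcspace(scores), controls)
        assert idx[controls].mean() == pytest.approx(0.0, abs=1e-12)
        assert idx[controls].std(ddof=1) == pytest.approx(1.0)

    def test_hand_computed_two_pc_toy(self):
        """Controls at (+-2,0),(0,+-1); query at (3,0). All by hand."""
        scores = pd.DataFrame(
            [[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0], [3.0, 0.0]],
            index=["k1", "k2", "k3", "k4", "q"],
        )
        idx, ref = compute_differentiation_index(
            make_pcspace(scores), ["k1", "k2", "k3", "k4"]
        )
        # centroid (0,0); control distances [2,2,1,1]; mu=1.5; sigma=sqrt(1/3)
        sigma = np.sqrt(1.0 / 3.0)
        assert ref.mu == pytest.approx(1.5)
        assert ref.sigma == pytest.approx(sigma)
        assert idx["q"] == pytest.approx((3.0 - 1.5) / sigma)

    def test_cell_at_centroid_scores_minus_mu_over_sigma(self):
        scores = pd.DataFrame(
            [[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0], [0.0, 0.0]],
            index=["k1", "k2", "k3", "k4", "q"],
        )
        idx, ref = compute_differentiation_index(
            make_pcspace(scores), ["k1", "k2", "k3", "k4"]
        )
        assert idx["q"] == pytest.approx(-ref.mu / ref.sigma)

    def test_equidistant_controls_are_degenerate(self):
        """Controls at (+-1,0),(0,+-1) all sit 1 unit from the centroid: sigma=0."""
        scores = pd.DataFrame(
            [[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]],
            index=["k1", "k2", "k3", "k4"],
        )
        with pytest.raises(DegenerateControls):
            compute_differentiation_index(make_pcspace(scores),
                                          ["k1", "k2", "k3", "k4"])

    def test_too_few_controls(self):
        scores = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(DegenerateControls):
            compute_differentiation_index(make_pcspace(scores), ["a", "b"])

    def test_rotation_invariance(self, rng):
        """Euclidean distances are preserved by any orthogonal map of PC space."""
        scores = pd.DataFrame(rng.normal(size=(30, 6)),
                              index=[f"c{i}" for i in range(30)])
        controls = [f"c{i}" for i in range(12)]
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        rotated = pd.DataFrame(scores.to_numpy() @ Q, index=scores.index)
        idx1, _ = compute_differentiation_index(make_pcspace(scores), controls)
        idx2, _ = compute_differentiation_index(make_pcspace(rotated), controls)
        pd.testing.assert_series_equal(idx1, idx2, atol=1e-10, rtol=0)

    def test_constant_shift_invariance(self, rng):
        """Adding one vector to every cell is removed by PCA centering."""
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(25, 12)).astype(float),
            index=[f"c{i}" for i in range(25)],
            columns=[f"g{j}" for j in range(12)],
        )
        controls = [f"c{i}" for i in range(10)]
        norm = normalize_counts(counts)
        shift = rng.normal(size=12)
        shifted = norm + shift
        idx1, _ = compute_differentiation_index(fit_pca(norm, n_pcs=5), controls)
        idx2, _ = compute_differentiation_index(fit_pca(shifted, n_pcs=5), controls)
        pd.testing.assert_series_equal(idx1, idx2, atol=1e-8, rtol=0)


def mannwhitney_enumeration_oracle(x, y):
    """Exact one-sided (greater) p by enumerating all rank arrangements."""
    combined = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    count = total = 0
    for picks in itertools.combinations(range(n + m), n):
        xs = combined[list(picks)]
        ys = np.delete(combined, list(picks))
        u = sum(1 for xi in xs for yj in ys if xi > yj) \
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        total += 1
        if u >= u_obs:
            count += 1
    return count / total


class TestPotency:
    def _cells(self, groups):
        rows = []
        for name, cbs in groups.items():
            label = "control" if name == "control" else "single"
            rows += [{"cell_barcode": cb, "label": label,
                      "tf_name": "" if label == "control" else name} for cb in cbs]
        return pd.DataFrame(rows)

    def test_null_population_not_flagged(self, rng):
        vals = rng.normal(size=40)
        index = pd.Series(vals, index=[f"c{i}" for i in range(40)])
        cells = self._cells({"control": [f"c{i}" for i in range(30)],
                             "tfA": [f"c{i}" for i in range(30, 40)]})
        res = test_potency(index, cells)
        assert not res.loc[res.tf_name == "tfA", "potent"].item()

    def test_exact_p_matches_enumeration_at_3_vs_4(self):
        """n=3 vs n=4, no ties: p agrees with all C(7,3)=35 arrangements."""
        x = np.array([2.1, 3.5, 1.8])
        y = np.array([0.4, 1.1, 0.9, 2.0])
        index = pd.Series(np.concatenate([x, y]),
                          index=[f"t{i}" for i in range(3)] + [f"k{i}" for i in range(4)])
        cells = self._cells({"control": [f"k{i}" for i in range(4)],
                             "tfA": [f"t{i}" for i in range(3)]})
        res = test_potency(index, cells)
        assert res.loc[0, "p"] == pytest.approx(
            mannwhitney_enumeration_oracle(x, y), abs=1e-12
        )

    def test_small_groups_flagged_untested(self):
        index = pd.Series(np.arange(10.0), index=[f"c{i}" for i in range(10)])
        cells = self._cells({"control": [f"c{i}" for i in range(8)],
                             "tfA": ["c8", "c9"]})
        res = test_potency(index, cells)
        row = res.loc[res.tf_name == "tfA"].iloc[0]
        assert not row["tested"] and not row["potent"] and np.isnan(row["p"])

    def test_shifted_population_flagged(self, rng):
        ctrl = rng.normal(size=60)
        shifted = rng.normal(loc=3.0, size=15)
        names = [f"k{i}" for i in range(60)] + [f"t{i}" for i in range(15)]
        index = pd.Series(np.concatenate([ctrl, shifted]), index=names)
        cells = self._cells({"control": names[:60], "tfA": names[60:]})
        res = test_potency(index, cells)
        assert res.loc[res.tf_name == "tfA", "potent"].item()

    def test_type_one_error_controlled_on_pure_null_cohorts(self):
        """Fraction of null TFs flagged at adjusted p<0.01 stays near nominal.

        200 seeded pure-null replicates (all populations drawn from the
        control distribution), 5 populations each; bound 0.01 + 3*SE.
        """
        n_reps, n_pops = 200, 5
        flags = 0
        for seed in range(n_reps):
            rng = np.random.default_rng(10_000 + seed)
            vals = rng.normal(size=120 + 20 * n_pops)
            names = [f"c{i}" for i in range(len(vals))]
            index = pd.Series(vals, index=names)
            groups = {"control": names[:120]}
            for p in range(n_pops):
                groups[f"tf{p}"] = names[120 + 20 * p:120 + 20 * (p + 1)]
            res = test_potency(index, self._cells(groups))
            flags += int(res["potent"].sum())
        frac = flags / (n_reps * n_pops)
        se = np.sqrt(0.01 * 0.99 / (n_reps * n_pops))
        assert frac <= 0.01 + 3 * se


class TestGeneSets:
    def test_small_set_dropped_and_itf_gene_removed(self):
        universe = [f"g{i}" for i in range(40)] + ["TfA"]
        sets = {
            "tiny": [f"g{i}" for i in range(14)],          # 14 < 15 -> dropped
            "with_itf": ["TfA"] + [f"g{i}" for i in range(15)],
        }
        with pytest.warns(SetTooSmall):
            kept, dropped = filter_gene_sets(sets, universe, exclude_genes=["TfA"])
        assert "tiny" in dropped and "with_itf" in kept
        assert "TfA" not in kept["with_itf"] and len(kept["with_itf"]) == 15

    def test_full_gene_set_reproduces_global_index(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 25, size=(30, 20)),
            index=[f"c{i}" for i in range(30)],
            columns=[f"g{j}" for j in range(20)],
        )
        controls = [f"c{i}" for i in range(12)]
        res = geneset_indexes(counts, {"all": list(counts.columns)}, controls,
                              n_pcs=5)
        global_idx, _ = differentiation_index_pipeline(counts, controls, n_pcs=5)
        pd.testing.assert_series_equal(
            res.per_cell["all"], global_idx, check_names=False, atol=1e-8, rtol=0
        )

    def test_medians_tabulated_per_tf(self, rng):
        pops = (PopulationSpec("TfA", 20, 10, 1.5),)
        counts, cells, truth = simulate_expression_cohort(
            ExprSimParams(n_genes=120, n_control_cells=60, populations=pops, seed=5)
        )
        sets = {"s1": [f"g{i + 1:04d}" for i in range(60)],
                "s2": [f"g{i + 1:04d}" for i in range(60, 120)]}
        res = geneset_indexes(counts, sets,
                              cells.loc[cells.label == "control", "cell_barcode"],
                              cells=cells, exclude_genes=truth["itf_genes"],
                              n_pcs=10)
        assert set(res.medians.index) == {"TfA", "control"}
        assert list(res.medians.columns) == ["s1", "s2"]

    def test_ribosomal_prefix_helper(self):
        genes = ["Rps6", "Rpl13a", "rps2", "Gata3", "Rpsomething"]
        assert set(ribosomal_genes(genes)) == {"Rps6", "Rpl13a", "rps2", "Rpsomething"}


def percentile_oracle(values):
    out = []
    n = len(values)
    for i, v in enumerate(values):
        smaller = sum(1 for j, w in enumerate(values) if w < v)
        ties = sum(1 for j, w in enumerate(values) if w == v and j != i)
        out.append(100.0 * (smaller + 0.5 * ties) / (n - 1))
    return out


class TestPercentileRanks:
    def test_max_is_100_min_is_0(self):
        r = percentile_ranks(pd.Series([0.1, 2.5, -1.0, 0.7], index=list("abcd")))
        assert r["b"] == 100.0 and r["c"] == 0.0

    def test_all_ties_are_50(self):
        r = percentile_ranks(pd.Series([3.0, 3.0, 3.0]))
        assert (r == 50.0).all()

    def test_matches_pairwise_comparison_oracle(self):
        vals = [0.3, -1.2, 0.3, 4.0, 2.2]
        r = percentile_ranks(pd.Series(vals))
        np.testing.assert_allclose(r.to_numpy(), percentile_oracle(vals))

    def test_monotone_in_median(self, rng):
        vals = pd.Series(rng.normal(size=12))
        r = percentile_ranks(vals)
        order_v = vals.sort_values().index
        assert (r[order_v].diff().dropna() >= 0).all()


class TestSimilarity:
    def test_identical_rows_have_similarity_one(self):
        M = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4, 1, 0, 2]],
                         index=["a", "b", "c"])
        sim, _ = tf_similarity(M)
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        M = pd.DataFrame(rng.normal(size=(6, 8)),
                         index=[f"tf{i}" for i in range(6)])
        sim, order = tf_similarity(M)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sim), 1.0)
        assert sorted(order) == sorted(sim.index)

    def test_offdiagonals_match_hand_pearson(self):
        M = pd.DataFrame([[1.0, 2.0, 4.0, 3.0],
                          [2.0, 1.0, 5.0, 2.0],
                          [-1.0, 0.0, 1.0, 7.0]], index=["a", "b", "c"])
        sim, _ = tf_similarity(M)

        def pearson(x, y):
            xb, yb = np.mean(x), np.mean(y)
            num = np.sum((x - xb) * (y - yb))
            den = np.sqrt(np.sum((x - xb) ** 2) * np.sum((y - yb) ** 2))
            return num / den

        for i, j in itertools.combinations(M.index, 2):
            assert sim.loc[i, j] == pytest.approx(
                pearson(M.loc[i].to_numpy(), M.loc[j].to_numpy())
            )

    def test_zero_variance_row_dropped(self, rng):
        M = pd.DataFrame(rng.normal(size=(4, 5)), index=list("abcd"))
        M.loc["c"] = 2.0
        with pytest.warns(ZeroVarianceRow):
            sim, _ = tf_similarity(M)
        assert "c" not in sim.index
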