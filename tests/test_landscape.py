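"""Landscape comparison: shared matrix, PCA, PAM, motif-feature statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strma.landscape import (
    build_shared_matrix,
    fit_rate_vs_length,
    gc_anova,
    gc_extremes,
    kmedoids_select,
    kruskal_wallis_by_group,
    pairwise_rate_correlations,
    pca_scores,
)
from strma.normalization import NormalizedProfile
from strma.scanner import Motif


def profile(line_id, **copies):
    return NormalizedProfile(line_id, {Motif(m): c for m, c in copies.items()})


class TestSharedMatrix:
    def test_motif_missing_in_one_line_is_dropped(self):
        profiles = {
            "L1": profile("L1", A=10.0, AG=5.0),
            "L2": profile("L2", A=8.0, AG=3.0),
            "L3": profile("L3", A=6.0),
        }
        m = build_shared_matrix(profiles)
        assert m.motifs == ["A"]
        assert (m.matrix.to_numpy() > 0).all()

    def test_identical_lines_give_constant_columns(self):
        profiles = {f"L{i}": profile(f"L{i}", A=7.0, AT=3.0) for i in range(4)}
        m = build_shared_matrix(profiles)
        assert m.matrix.nunique().max() == 1

    def test_no_shared_motifs_raises(self):
        profiles = {"L1": profile("L1", A=1.0), "L2": profile("L2", C=1.0)}
        with pytest.raises(ValueError):
            build_shared_matrix(profiles)

    def test_planted_universal_motifs_are_exactly_the_columns(self, experiment):
        shared = build_shared_matrix(experiment.profiles)
        universal = set.intersection(
            *(
                {m.unit for m, c in p.copy_number.items() if c > 0}
                for p in experiment.profiles.values()
            )
        )
        assert set(shared.motifs) == universal
        assert shared.motifs == sorted(shared.motifs)


class TestPCA:
    def test_two_lines_one_axis(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 6.0]], index=["a", "b"], columns=["A", "C"])
        scores, var = pca_scores(m, n_pcs=2)
        assert var[0] == pytest.approx(1.0)

    def test_identical_rows_zero_variance(self):
        m = pd.DataFrame([[5.0, 1.0]] * 3, index=list("abc"), columns=["A", "C"])
        with pytest.warns(UserWarning):
            scores, var = pca_scores(m, n_pcs=2)
        assert np.allclose(scores.to_numpy(), 0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(20, 8))
        m = pd.DataFrame(X, index=[f"l{i}" for i in range(20)])
        scores, var = pca_scores(m, n_pcs=5)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # compare |scores| (signs fixed by a different convention here)
        expected = np.abs(Xc @ evecs[:, :5])
        assert np.allclose(np.abs(scores.to_numpy()), expected, atol=1e-8)
        assert np.allclose(var[:5], evals[:5] / evals.sum(), atol=1e-10)

    def test_row_permutation_equivariance(self, rng):
        X = rng.normal(size=(15, 6))
        idx = [f"l{i}" for i in range(15)]
        m = pd.DataFrame(X, index=idx)
        perm = rng.permutation(15)
        mp = m.iloc[perm]
        s1, _ = pca_scores(m, n_pcs=4)
        s2, _ = pca_scores(mp, n_pcs=4)
        assert np.allclose(s1.iloc[perm].to_numpy(), s2.to_numpy(), atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(12, 5))
        m = pd.DataFrame(X)
        s1, _ = pca_scores(m, n_pcs=3)
        s2, _ = pca_scores(m.copy(), n_pcs=3)
        # signs (the convention's job) must agree exactly; values to
        # numerical precision
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)
        assert np.array_equal(np.sign(s1.to_numpy()), np.sign(s2.to_numpy()))


class TestKMedoids:
    def test_two_separated_clouds(self, rng):
        a = rng.normal(0, 0.3, size=(12, 3))
        b = rng.normal(8, 0.3, size=(12, 3))
        scores = pd.DataFrame(np.vstack([a, b]), index=[f"l{i}" for i in range(24)])
        res = kmedoids_select(scores, k_grid=[2, 3, 4], seed=0)
        assert res.best_k == 2
        labels = res.assignments.to_numpy()
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1

    def test_duplicated_cloud_handled_without_crash(self, rng):
        pts = rng.normal(0, 1, size=(10, 2))
        scores = pd.DataFrame(np.vstack([pts, pts]), index=[f"l{i}" for i in range(20)])
        res = kmedoids_select(scores, k_grid=[2, 3], seed=1)
        assert res.best_k in (2, 3)

    def test_k_exceeding_lines_skipped(self, rng):
        scores = pd.DataFrame(rng.normal(size=(5, 2)), index=list("abcde"))
        with pytest.warns(UserWarning):
            res = kmedoids_select(scores, k_grid=[2, 5, 6], seed=0)
        assert 5 not in res.k_grid and 6 not in res.k_grid

    def test_six_genotype_recovery(self, experiment, genotype_map):
        """The simulated 6-genotype design yields six genotype-pure
        clusters, each holding one SC with its MA and EC descendants."""
        shared = build_shared_matrix(experiment.profiles)
        scores, _ = pca_scores(shared.matrix, n_pcs=10, log_transform=True)
        hits = 0
        for seed in range(10):
            res = kmedoids_select(scores, seed=seed)
            df = pd.DataFrame(
                {
                    "cluster": res.assignments,
                    "genotype": [genotype_map[l] for l in res.assignments.index],
                }
            )
            pure = (
                res.best_k == 6
                and df.groupby("cluster")["genotype"].nunique().max() == 1
                and df.groupby("genotype")["cluster"].nunique().max() == 1
            )
            hits += pure
        assert hits >= 9


class TestGcExtremes:
    def test_planted_at_rich_fast_motifs(self):
        # AT-rich motifs get 4x the rate of GC-rich ones
        u = {}
        at_rich = ["AAAT", "AATAT", "AAATAAT", "ATATATAT", "AATA"[:4], "AAAAT",
                   "AATT", "AAATT", "ATAAT", "AAATAT"]
        gc_rich = ["ACGC", "AGCG", "ACCGC", "AGGCC", "ACGCGC", "AGCCG",
                   "ACCG", "AGGC", "ACGG", "AGCC"]
        for m in at_rich:
            u[m] = 0.04
        for m in gc_rich:
            u[m] = 0.01
        top_gc, bottom_gc = gc_extremes(u, n=10, min_k=4)
        assert top_gc < bottom_gc

    def test_all_tied_rates_still_computable(self):
        u = {m: 0.01 for m in ["AAAT", "AAAC", "AATG", "ACAT", "AGAT", "ACGT"]}
        top_gc, bottom_gc = gc_extremes(u, n=3, min_k=4)
        assert 0 <= top_gc <= 1 and 0 <= bottom_gc <= 1

    def test_n_one_picks_max_and_min(self):
        u = {"AAAT": 0.5, "ACGC": 0.001}
        top_gc, bottom_gc = gc_extremes(u, n=1, min_k=4)
        assert top_gc == pytest.approx(0.0)  # AAAT is GC-free
        assert bottom_gc == pytest.approx(0.75)  # ACGC

    def test_too_few_motifs_raises(self):
        with pytest.raises(ValueError, match="2"):
            gc_extremes({"AAAT": 0.1, "ACGC": 0.2}, n=2, min_k=4)

    def test_short_motifs_excluded(self):
        u = {"A": 9.9, "AT": 9.8, "AAAT": 0.3, "ACGC": 0.2, "AGAT": 0.1, "AATG": 0.05}
        top_gc, bottom_gc = gc_extremes(u, n=2, min_k=4)
        # the extreme-rate 1-/2-mers must not enter the ranking:
        # top pair is {AAAT, ACGC}, bottom pair {AGAT, AATG}
        assert top_gc == pytest.approx((0.0 + 0.75) / 2)
        assert bottom_gc == pytest.approx(0.25)


class TestKruskalWallis:
    def test_matches_bruteforce_rank_statistic(self):
        groups = {"a": [1, 2, 3], "b": [10, 11, 12]}
        H, p = kruskal_wallis_by_group(groups)
        # brute-force: ranks 1..6, no ties
        ranks = {"a": [1, 2, 3], "b": [4, 5, 6]}
        n = 6
        expected = 12 / (n * (n + 1)) * sum(
            len(r) * (np.mean(r) - (n + 1) / 2) ** 2 for r in ranks.values()
        )
        assert H == pytest.approx(expected)

    def test_all_tied_values(self):
        H, p = kruskal_wallis_by_group({"a": [5, 5], "b": [5, 5, 5]})
        assert H == 0.0
        assert p == 1.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis_by_group({"a": [1, 2]})

    def test_type_one_error_calibrated_under_null(self, rng):
        """Identical group distributions: rejection rate ~ alpha."""
        alpha, n_sim, rejects = 0.05, 400, 0
        for _ in range(n_sim):
            vals = rng.normal(size=18)
            groups = {"a": vals[:6], "b": vals[6:12], "c": vals[12:]}
            _, p = kruskal_wallis_by_group(groups)
            rejects += p < alpha
        rate = rejects / n_sim
        assert 0.02 <= rate <= 0.09  # within Monte-Carlo error of 0.05

    def test_matches_permutation_null_small_data(self, rng):
        """Chi-square p close to the exact permutation p on small samples."""
        for _ in range(10):
            vals = rng.normal(size=12)
            groups = {"a": vals[:4], "b": vals[4:8], "c": vals[8:]}
            H, p = kruskal_wallis_by_group(groups)
            stat = lambda v: kruskal_wallis_by_group(
                {"a": v[:4], "b": v[4:8], "c": v[8:]}
            )[0]
            perm_hits = 0
            n_perm = 300
            for _ in range(n_perm):
                v = rng.permutation(vals)
                perm_hits += stat(v) >= H - 1e-12
            perm_p = perm_hits / n_perm
            assert abs(p - perm_p) < 0.12


class TestRateFeatureModels:
    def test_exact_linear_relationship_recovered(self):
        u = {m: 0.002 * len(m) + 0.001 for m in ["A", "AT", "AAG", "AAAT", "AACCT", "AACCCT"]}
        fit = fit_rate_vs_length(u)
        assert fit["slope"] == pytest.approx(0.002, abs=1e-10)
        assert fit["intercept"] == pytest.approx(0.001, abs=1e-10)
        assert fit["p_slope"] < 1e-6

    def test_regression_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_rate_vs_length({"A": 0.1, "AT": 0.2})

    def test_identical_vectors_correlate_perfectly(self):
        u = {"g1": {"A": 0.1, "AT": -0.2, "AAG": 0.05}, "g2": {"A": 0.1, "AT": -0.2, "AAG": 0.05}}
        df = pairwise_rate_correlations(u)
        assert df.iloc[0]["r"] == pytest.approx(1.0)

    def test_dropping_a_dominant_motif_changes_r(self):
        u = {
            "g1": {"C": 0.9, "AT": 0.01, "AAG": -0.02, "AAAT": 0.005},
            "g2": {"C": 0.8, "AT": -0.01, "AAG": 0.03, "AAAT": -0.02},
        }
        with_c = pairwise_rate_correlations(u).iloc[0]["r"]
        without_c = pairwise_rate_correlations(u, drop_motifs=["C"]).iloc[0]["r"]
        assert with_c > 0.9
        assert without_c < with_c

    def test_anova_detects_planted_category_effect(self, rng):
        """Balanced two-way design with a pure category effect: the
        category factor is significant, genotype is not (checked against a
        permutation oracle for the category factor)."""
        rows = []
        for geno in ["g1", "g2", "g3"]:
            for cat, shift in [("high", 0.0), ("low", 0.25)]:
                for _ in range(10):
                    rows.append(
                        {"genotype": geno, "category": cat, "gc": rng.normal(0.4 + shift, 0.08)}
                    )
        table = pd.DataFrame(rows)
        anova = gc_anova(table)
        p_cat = anova.loc["C(category)", "PR(>F)"]
        p_geno = anova.loc["C(genotype)", "PR(>F)"]
        assert p_cat < 0.001
        assert p_geno > 0.01
        # permutation oracle for the category effect
        obs = abs(
            table[table.category == "high"]["gc"].mean()
            - table[table.category == "low"]["gc"].mean()
        )
        hits = 0
        for _ in range(500):
            perm = rng.permutation(table["category"].to_numpy())
            d = abs(
                table["gc"][perm == "high"].mean() - table["gc"][perm == "low"].mean()
            )
            hits += d >= obs
        assert hits / 500 < 0.01  # agrees: category effect is real
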