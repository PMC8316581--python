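import numpy as np
import pytest

from comosub import (
    SimulationDesign,
    assign_genes,
    assign_samples,
    convex_nmf_fit,
    dunn_pairwise,
    generate_disease_dataset,
    kruskal_wallis_gene,
    select_cluster_genes,
)
from comosub.datatypes import FoldChangeMatrix
from comosub.nmf import ConvexNMFFit
from comosub.preprocess import log2_fold_change

from _oracles import dunn_brute, kruskal_wallis_brute

WORKED_GROUPS = [[1, 2], [3, 4], [5, 6]]


def _fake_fit(H=None, W=None, k=3):
    n = H.shape[0] if H is not None else W.shape[1]
    return ConvexNMFFit(
        F=np.zeros((n, k)),
        H=H if H is not None else np.zeros((n, k)),
        W=W if W is not None else np.zeros((2, k)),
        objective_trace=np.zeros(1),
        assignment_trace=np.zeros((1, n), dtype=int),
        k=k,
        seed=0,
    )


class TestAssignments:
    def test_sample_argmax(self):
        fit = _fake_fit(H=np.array([[0.1, 0.7, 0.2]]))
        assert assign_samples(fit)[0] == 2

    def test_sample_tie_goes_low(self):
        fit = _fake_fit(H=np.array([[0.5, 0.5, 0.0]]))
        assert assign_samples(fit)[0] == 1

    def test_random_h_matches_brute_argmax(self):
        rng = np.random.default_rng(0)
        H = rng.uniform(size=(30, 4))
        fit = _fake_fit(H=H, k=4)
        labels = assign_samples(fit)
        for i in range(30):
            assert labels[i] == int(np.argmax(H[i])) + 1

    def test_gene_max_and_min(self):
        fit = _fake_fit(W=np.array([[-1.0, 0.0, 2.0]]))
        up, up_valid = assign_genes(fit, "max")
        down, down_valid = assign_genes(fit, "min")
        assert (up[0], down[0]) == (3, 1)
        assert up_valid[0] and down_valid[0]

    def test_constant_row_flagged(self):
        fit = _fake_fit(W=np.array([[1.0, 1.0, 1.0]]))
        labels, valid = assign_genes(fit, "max")
        assert not valid[0]
        assert labels[0] == 0

    def test_random_w_matches_brute_force(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(50, 3))
        fit = _fake_fit(W=W)
        up, _ = assign_genes(fit, "max")
        down, _ = assign_genes(fit, "min")
        np.testing.assert_array_equal(up, np.argmax(W, axis=1) + 1)
        np.testing.assert_array_equal(down, np.argmin(W, axis=1) + 1)

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            assign_genes(_fake_fit(W=np.ones((2, 3))), "sideways")


class TestKruskalWallis:
    def test_worked_example(self):
        H, p = kruskal_wallis_gene(WORKED_GROUPS)
        assert H == pytest.approx(32 / 7, abs=1e-10)
        assert p == pytest.approx(0.1017, abs=2e-4)

    def test_identical_constants_give_p_one(self):
        assert kruskal_wallis_gene([[2, 2], [2, 2], [2, 2]]) == (0.0, 1.0)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            kruskal_wallis_gene([[1, 2], [3, 4]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis_gene([[1, 2], [], [3]])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 8, size=rng.integers(3, 10)).astype(float) for _ in range(4)]
        H, p = kruskal_wallis_gene(groups)
        Hb, pb = kruskal_wallis_brute(groups)
        assert H == pytest.approx(Hb, abs=1e-10)
        assert p == pytest.approx(pb, abs=1e-10)


class TestDunn:
    def test_worked_example(self):
        z, p = dunn_pairwise(WORKED_GROUPS, (1, 3))
        assert z == pytest.approx((1.5 - 5.5) / np.sqrt(3.5), abs=1e-10)
        assert p == pytest.approx(0.0325, abs=2e-4)

    def test_same_cluster_pair_is_null(self):
        assert dunn_pairwise(WORKED_GROUPS, (2, 2)) == (0.0, 1.0)

    def test_all_tied_pool_gives_p_one(self):
        z, p = dunn_pairwise([[1, 1], [1, 1], [1, 1]], (1, 2))
        assert (z, p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [rng.integers(0, 6, size=rng.integers(3, 9)).astype(float) for _ in range(3)]
        i, j = sorted(rng.choice([1, 2, 3], size=2, replace=False))
        z, p = dunn_pairwise(groups, (i, j))
        zb, pb = dunn_brute(groups, i, j)
        assert z == pytest.approx(zb, abs=1e-10)
        assert p == pytest.approx(pb, abs=1e-10)

    def test_pair_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            dunn_pairwise(WORKED_GROUPS, (1, 5))


class TestSelectClusterGenes:
    def test_planted_markers_recovered(self, small_cohort, small_fold_change):
        _, truth = small_cohort
        fit = convex_nmf_fit(small_fold_change.values, k=3, max_iter=150, seed=2)
        assignment = select_cluster_genes(small_fold_change, fit, alpha=0.05)
        labels = np.asarray([assignment.sample_cluster[p] for p in small_fold_change.patient_ids])
        # map fitted cluster labels onto planted ones by majority membership
        planted = np.asarray([truth.sample_cluster[p] for p in small_fold_change.patient_ids])
        for c_fit in range(1, 4):
            members = planted[labels == c_fit]
            assert members.size > 0
            c_true = np.bincount(members).argmax()
            up_true = truth.up_modules[int(c_true)]
            recovered = len(assignment.G_up[c_fit] & up_true) / len(up_true)
            assert recovered >= 0.9

    def test_filtering_only_removes_genes(self, small_fold_change):
        fit = convex_nmf_fit(small_fold_change.values, k=3, max_iter=150, seed=2)
        assignment = select_cluster_genes(small_fold_change, fit, alpha=0.05)
        for c in range(1, 4):
            for g in assignment.G_up[c]:
                assert assignment.up_assignment[g] == c
            for g in assignment.G_down[c]:
                assert assignment.down_assignment[g] == c

    def test_gene_differing_elsewhere_excluded(self):
        # a gene assigned to cluster 1 whose only separation is between
        # clusters 2 and 3 must fail the Dunn pairs involving cluster 1
        rng = np.random.default_rng(3)
        n_per = 10
        gene = np.concatenate([
            rng.normal(0.0, 0.05, n_per),
            rng.normal(0.0, 0.05, n_per),
            rng.normal(1.0, 0.05, n_per),
        ])
        filler = rng.normal(0, 0.05, size=(3, 3 * n_per))
        values = np.vstack([gene, filler])
        fc = FoldChangeMatrix(
            gene_ids=["g_target", "f1", "f2", "f3"],
            patient_ids=[f"p{i}" for i in range(3 * n_per)],
            values=values,
            control_means=np.ones(4),
        )
        H = np.zeros((3 * n_per, 3))
        for c in range(3):
            H[c * n_per : (c + 1) * n_per, c] = 1.0
        W = np.array([[1.0, 0.1, 0.9], [0.5, 0.4, 0.3], [0.3, 0.4, 0.5], [0.2, 0.5, 0.3]])
        fit = ConvexNMFFit(
            F=np.zeros((3 * n_per, 3)), H=H, W=W,
            objective_trace=np.zeros(1),
            assignment_trace=np.zeros((1, 3 * n_per), dtype=int), k=3, seed=0,
        )
        assignment = select_cluster_genes(fc, fit, alpha=0.05)
        assert "g_target" not in assignment.G_up[1]

    def test_requires_k_at_least_three(self, small_fold_change):
        fit = convex_nmf_fit(small_fold_change.values, k=2, max_iter=30, seed=0)
        with pytest.raises(ValueError, match="k >= 3"):
            select_cluster_genes(small_fold_change, fit)


def test_null_design_respects_bonferroni_control():
    """With no planted effect, selected-gene counts stay at false-positive level."""
    n_sel = []
    n_tested = []
    for rep in range(5):
        design = SimulationDesign(
            n_genes=200, patients_per_cluster=[12, 12, 12], n_controls=10,
            effect_size=0.0, module_size=10, shared_candidate_size=5, seed=500 + rep,
        )
        ds, _ = generate_disease_dataset(design, "N")
        fc = log2_fold_change(ds)
        fit = convex_nmf_fit(fc.values, k=3, max_iter=100, seed=rep)
        assignment = select_cluster_genes(fc, fit, alpha=0.05)
        n_sel.append(sum(len(s) for s in assignment.G_up.values())
                     + sum(len(s) for s in assignment.G_down.values()))
        n_tested.append(sum(len(df) for df in assignment.per_gene_stats.values()))
    assert np.mean(n_sel) <= 0.05 * np.mean(n_tested)
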