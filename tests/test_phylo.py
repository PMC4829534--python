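"""Phi correlations, Manhattan distances, neighbor joining, bootstraps and
the sampling-variance partition of terminal branches."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

import txturn
from txturn.phylo import (bipartitions, manhattan_distances,
                          neighbor_joining, robinson_foulds,
                          split_replicate_counts, terminal_branch_lengths)
from txturn.presence import PresenceMatrix


def _pm(cols: dict) -> PresenceMatrix:
    return PresenceMatrix(values=pd.DataFrame(cols, dtype=np.int8), tau=1)


class TestPhiCorrelation:
    def test_perfect_association(self):
        pm = _pm({"A": [1, 1, 0, 0], "B": [1, 1, 0, 0]})
        corr = txturn.correlation_matrix(pm)
        assert corr.values.loc["A", "B"] == pytest.approx(1.0)

    def test_perfect_negative_association(self):
        pm = _pm({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1]})
        corr = txturn.correlation_matrix(pm)
        assert corr.values.loc["A", "B"] == pytest.approx(-1.0)

    def test_contingency_table_value(self):
        # n11=40, n10=10, n01=10, n00=40 -> phi = (1600-100)/2500 = 0.6
        a = [1] * 50 + [0] * 50
        b = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        corr = txturn.correlation_matrix(_pm({"A": a, "B": b}))
        assert corr.values.loc["A", "B"] == pytest.approx(0.6)

    def test_phi_equals_pearson_on_binary(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.integers(0, 2, size=(200, 4)),
                         columns=list("ABCD"))
        corr = txturn.correlation_matrix(_pm(X.to_dict("list")))
        expected = X.corr().to_numpy()
        np.testing.assert_allclose(corr.values.to_numpy(), expected,
                                   atol=1e-12)

    def test_zero_variance_flagged(self):
        pm = _pm({"A": [1, 1, 1], "B": [1, 0, 1], "C": [0, 1, 0]})
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            corr = txturn.correlation_matrix(pm)
        assert corr.values.loc["A", "B"] == 0.0
        assert corr.flagged.loc["A", "B"]
        assert "A" in corr.zero_variance_taxa

    def test_spearman_two_columns(self):
        cm = pd.DataFrame({"A": [1, 2, 3, 4], "B": [2, 4, 6, 9]})
        corr = txturn.correlation_matrix(cm, method="spearman")
        assert corr.values.loc["A", "B"] == pytest.approx(1.0)


class TestManhattanDistances:
    def test_identity_correlation(self):
        corr = txturn.CorrelationMatrix(
            values=pd.DataFrame(np.eye(2), index=list("AB"), columns=list("AB")),
            method="phi")
        d = manhattan_distances(corr)
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "A"] == 0.0

    def test_permutation_equivariance(self, small_presence):
        corr = txturn.correlation_matrix(small_presence)
        d = manhattan_distances(corr)
        perm = list(reversed(small_presence.taxa))
        pm2 = PresenceMatrix(values=small_presence.values[perm], tau=1)
        d2 = manhattan_distances(txturn.correlation_matrix(pm2))
        pd.testing.assert_frame_equal(d.loc[perm, perm], d2,
                                      check_exact=False, atol=1e-12)


def _random_additive_tree(n, rng):
    nodes = [TreeNode(name=f"T{i:02d}") for i in range(n)]
    for node in nodes:
        node.length = rng.uniform(0.1, 2.0)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode()
        parent.length = rng.uniform(0.1, 2.0)
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes))
                 if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    return root


def _path_distances(tree):
    tips = list(tree.tips())
    names = [t.name for t in tips]
    D = np.zeros((len(tips), len(tips)))
    for a in range(len(tips)):
        for b in range(a + 1, len(tips)):
            D[a, b] = D[b, a] = tips[a].distance(tips[b])
    return pd.DataFrame(D, index=names, columns=names)


class TestNeighborJoining:
    def test_three_point_formulas(self):
        d = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = neighbor_joining(d)
        lengths = terminal_branch_lengths(tree)
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_exact_on_additive_matrices(self):
        """NJ must recover topology and branch lengths from any additive
        distance matrix (oracle: path lengths on the generating tree)."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            true = _random_additive_tree(n, rng)
            D = _path_distances(true)
            est = neighbor_joining(D)
            assert robinson_foulds(est, true) == 0
            D_est = _path_distances(est)
            np.testing.assert_allclose(
                D_est.loc[D.index, D.columns].to_numpy(), D.to_numpy(),
                atol=1e-9)

    def test_matches_skbio_nj_topology(self):
        """Independent library cross-check on a non-additive matrix."""
        rng = np.random.default_rng(7)
        M = rng.uniform(1, 10, size=(6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"T{i}" for i in range(6)]
        ours = neighbor_joining(pd.DataFrame(D, index=ids, columns=ids))
        theirs = skbio_nj(DistanceMatrix(D, ids=ids))
        assert robinson_foulds(ours, theirs) == 0

    def test_tie_break_deterministic(self):
        ids = list("ABCD")
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=ids, columns=ids)
        t1 = neighbor_joining(d)
        t2 = neighbor_joining(d.loc[ids, ids])
        assert str(t1) == str(t2)

    def test_negative_branches_clamped_and_flagged(self):
        d = pd.DataFrame([[0, 1, 10, 10], [1, 0, 1, 1],
                          [10, 1, 0, 1], [10, 1, 1, 0]],
                         index=list("ABCD"), columns=list("ABCD"), dtype=float)
        tree = neighbor_joining(d)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0
        assert len(tree.clamped) > 0

    def test_too_few_taxa(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            neighbor_joining(d)


class TestBootstrap:
    def test_identical_taxa_cherry_at_full_support(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(300, 4))
        cols = {"A": base[:, 0], "Acopy": base[:, 0], "B": base[:, 1],
                "C": base[:, 2], "D": base[:, 3]}
        pm = _pm({k: list(v) for k, v in cols.items()})
        tree, report = txturn.bootstrap_supports(pm, n_boot=30, seed=1)
        # the A|Acopy cherry is canonicalized as its complement B|C|D
        cherry = report[report["bipartition"] == "B|C|D"]
        assert (cherry["support"] == 100.0).all() and len(cherry) == 1

    def test_single_replicate_supports_binary(self, small_presence):
        _, report = txturn.bootstrap_supports(small_presence, n_boot=1, seed=2)
        assert set(report["support"]).issubset({0.0, 100.0})

    def test_strong_signal_full_support(self):
        model = txturn.TurnoverModel(n_windows=4_000, seed=5, depth=50.0,
                                     lognorm_sigma=0.2)
        ds = txturn.simulate_dataset(model)
        mask = txturn.CommonGenomeMask(
            np.ones(model.n_windows, dtype=bool), (), 1)
        pm = txturn.binarize(ds.counts, 1, mask)
        tree, report = txturn.bootstrap_supports(pm, n_boot=50, seed=3)
        assert report["support"].median() >= 70.0


class TestVariancePartition:
    def test_identical_replicates_zero_variance(self, small_presence):
        part = txturn.partition_branch_variance([small_presence] * 3)
        assert part.percent_variable == pytest.approx(0.0)

    def test_arithmetic_of_partition(self):
        # lengths 2,4,6 for one taxon, others fixed: robust=2, variable=2
        lengths = pd.DataFrame({
            "X": [2.0, 4.0, 6.0],
            **{f"T{i}": [1.0, 1.0, 1.0] for i in range(9)},
        })
        mean = lengths.mean(axis=0)
        robust = lengths.min(axis=0)
        variable = mean - robust
        pct = 100 * variable.sum() / mean.sum()
        assert pct == pytest.approx(100 * 2 / (4 + 9))

    def test_robust_plus_variable_equals_mean(self, small_dataset, small_mask):
        reps = split_replicate_counts(
            small_dataset.counts, 3,
            int(small_dataset.counts.counts.sum(axis=0).min()) // 3, seed=0)
        pms = [txturn.binarize(r, 1, small_mask) for r in reps]
        part = txturn.partition_branch_variance(pms)
        np.testing.assert_allclose(
            part.per_taxon["robust"] + part.per_taxon["variable"],
            part.per_taxon["mean"])
        assert 0 <= part.percent_variable <= 100

    def test_replicate_mismatch_errors(self, small_presence):
        other = PresenceMatrix(
            values=small_presence.values.iloc[:, :5].copy(), tau=1)
        with pytest.raises(ValueError):
            txturn.partition_branch_variance([small_presence, other])


class TestSplitReplicates:
    def test_disjoint_exhaustive_partition(self):
        frags = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(300) * 10,
            "end": np.arange(300) * 10 + 5,
            "sample_id": "s",
        })
        sets = txturn.split_replicates(frags, 3, 100, seed=1)
        assert all(len(s) == 100 for s in sets)
        keys = [set(map(tuple, s[["start", "end"]].to_numpy())) for s in sets]
        assert not (keys[0] & keys[1] or keys[0] & keys[2] or keys[1] & keys[2])
        assert len(keys[0] | keys[1] | keys[2]) == 300

    def test_determinism(self):
        frags = pd.DataFrame({"chrom": "chr1", "start": np.arange(60),
                              "end": np.arange(60) + 1, "sample_id": "s"})
        a = txturn.split_replicates(frags, 2, 20, seed=5)
        b = txturn.split_replicates(frags, 2, 20, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_insufficient_fragments(self):
        frags = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [1],
                              "sample_id": "s"})
        with pytest.raises(ValueError, match="'s'"):
            txturn.split_replicates(frags, 3, 100, seed=0)

    def test_count_split_bounds(self, small_dataset):
        cm = small_dataset.counts
        size = int(cm.counts.sum(axis=0).min()) // 3
        sets = split_replicate_counts(cm, 3, size, seed=2)
        total = sum(s.counts for s in sets)
        assert (total.to_numpy() <= cm.counts.to_numpy()).all()
        for s in sets:
            assert (s.counts.sum(axis=0) == size).all()


class TestTopologyRecovery:
    def test_default_model_tree_recovered(self):
        """The phi/Manhattan/NJ pipeline recovers the generating topology
        on a default-sized simulation."""
        model = txturn.TurnoverModel(n_windows=10_000, seed=123)
        ds = txturn.simulate_dataset(model)
        genomic = txturn.simulate_genomic_coverage(model)
        mask = txturn.common_genome_mask(genomic, genomic.taxa)
        pm = txturn.binarize(ds.counts, 1, mask)
        tree = txturn.build_sharing_tree(pm)
        assert robinson_foulds(tree, ds.true_tree) == 0
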