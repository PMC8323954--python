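"""Distance models and UPGMA construction with bootstrap."""

import math

import numpy as np
import pytest

from mitodiv.genome_model import Msa
from mitodiv.phylo import (
    DistanceMatrix,
    SaturationWarning,
    UpgmaTreeBuilder,
    bootstrap_support,
    pairwise_distance,
    read_newick,
    upgma,
)


class TestDistances:
    def test_identical_sequences_zero(self):
        msa = Msa([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        for model in ("p-distance", "tn93", "t92"):
            assert pairwise_distance(msa, model=model).d[0, 1] == 0.0

    def test_p_distance_simple(self):
        msa = Msa([("a", "ACGT"), ("b", "ACGA")])
        assert pairwise_distance(msa).d[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_ignores_gap_and_n_columns(self):
        msa = Msa([("a", "ACGT-A"), ("b", "ACNTTA")])
        # comparable columns: 1,2(no: N),4,6 -> A,C,T,A vs A,C,T,A; col3 G/N and
        # col5 -/T dropped
        assert pairwise_distance(msa).d[0, 1] == 0.0

    def test_tn93_matches_direct_formula_evaluation(self):
        # designed pair with known substitution counts, evaluated against an
        # independent transcription of the TN93 closed form
        a = "AAAAAAAAGGGGGGGGCCCCCCCCTTTTTTTT" * 3
        b = list(a)
        b[0] = "G"; b[1] = "G"          # A->G transitions
        b[16] = "T"; b[17] = "T"        # C->T transitions
        b[8] = "T"; b[24] = "G"         # transversions
        msa = Msa([("x", a), ("y", "".join(b))])
        got = pairwise_distance(msa, model="tn93").d[0, 1]

        xs, ys = a, "".join(b)
        n = len(xs)
        P1 = sum(1 for u, v in zip(xs, ys) if {u, v} == {"A", "G"}) / n
        P2 = sum(1 for u, v in zip(xs, ys) if {u, v} == {"C", "T"}) / n
        Q = sum(
            1 for u, v in zip(xs, ys)
            if u != v and {u, v} not in ({"A", "G"}, {"C", "T"})
        ) / n
        pooled = xs + ys
        gA, gC, gG, gT = (pooled.count(base) / len(pooled) for base in "ACGT")
        gR, gY = gA + gG, gC + gT
        k1 = 2 * gA * gG / gR
        k2 = 2 * gC * gT / gY
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        expected = (
            -k1 * math.log(1 - P1 / k1 - Q / (2 * gR))
            - k2 * math.log(1 - P2 / k2 - Q / (2 * gY))
            - k3 * math.log(1 - Q / (2 * gR * gY))
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_models_reduce_to_p_distance_at_small_divergence(self):
        a = "ACGT" * 100
        b = list(a)
        b[0] = "G"  # single transition: p = 0.0025
        msa = Msa([("x", a), ("y", "".join(b))])
        p = pairwise_distance(msa).d[0, 1]
        for model in ("tn93", "t92"):
            d = pairwise_distance(msa, model=model).d[0, 1]
            assert d == pytest.approx(p, rel=0.02)

    def test_saturated_pair_hits_ceiling_with_warning(self):
        msa = Msa([("a", "ACACACAC"), ("b", "CACACACA")])
        with pytest.warns(SaturationWarning):
            d = pairwise_distance(msa, model="t92", ceiling=7.0).d[0, 1]
        assert d == 7.0

    def test_gamma_correction_increases_distance(self):
        a = "ACGTAGCTTGCA" * 20
        rng = np.random.default_rng(3)
        b = list(a)
        for i in rng.choice(len(a), size=30, replace=False):
            b[i] = str(rng.choice([c for c in "ACGT" if c != a[i]]))
        msa = Msa([("x", a), ("y", "".join(b))])
        plain = pairwise_distance(msa, model="tn93").d[0, 1]
        gamma = pairwise_distance(msa, model="tn93", gamma=0.18).d[0, 1]
        assert gamma > plain


def naive_upgma_heights(taxa, d):
    """Independent reference: recompute cluster means from the original
    matrix at every step instead of Lance-Williams updates."""
    clusters = [frozenset([t]) for t in taxa]
    idx = {t: i for i, t in enumerate(taxa)}
    heights = {}

    def cdist(c1, c2):
        return sum(d[idx[a], idx[b]] for a in c1 for b in c2) / (len(c1) * len(c2))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = cdist(clusters[i], clusters[j])
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, i, j = best
        merged = clusters[i] | clusters[j]
        heights[merged] = dij / 2
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


class TestUpgma:
    def test_two_taxa_split_the_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.tree.leaf_node_iter()}
        assert lengths == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}

    def test_closest_pair_joins_first(self):
        d = np.array([[0, 0.2, 0.8], [0.2, 0, 0.9], [0.8, 0.9, 0]])
        tree = upgma(DistanceMatrix(["A", "B", "C"], d))
        assert frozenset({"A", "B"}) in tree.clades()

    def test_matches_naive_reference_on_random_matrices(self):
        rng = np.random.default_rng(5)
        taxa = list("abcde")
        for _ in range(50):
            x = rng.uniform(0.1, 1.0, size=(5, 5))
            d = np.triu(x, 1)
            d = d + d.T
            tree = upgma(DistanceMatrix(taxa, d))
            ref = naive_upgma_heights(taxa, d)
            got_clades = tree.clades() | {frozenset(taxa)}
            assert got_clades == set(ref)
            # and the join heights agree
            for node in tree.tree.preorder_internal_node_iter():
                leaves = frozenset(l.taxon.label for l in node.leaf_iter())
                assert node.distance_from_tip() == pytest.approx(ref[leaves])

    def test_ultrametric(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.uniform(0.05, 1.0, size=(6, 6))
            d = np.triu(x, 1); d = d + d.T
            tree = upgma(DistanceMatrix([f"t{i}" for i in range(6)], d))
            depths = list(tree.leaf_root_distances().values())
            assert max(depths) - min(depths) < 1e-9

    def test_newick_round_trip(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 0.2, 0.6], [0.2, 0, 0.5], [0.6, 0.5, 0]]
        ))
        nwk = upgma(dm).newick()
        back = read_newick(nwk)
        assert {l.taxon.label for l in back.leaf_node_iter()} == {"a", "b", "c"}


class TestBootstrap:
    @staticmethod
    def _two_clade_msa(seed=0):
        rng = np.random.default_rng(seed)
        anc = rng.choice(list("ACGT"), size=300)
        cladeA, cladeB = anc.copy(), anc.copy()
        swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for i in range(0, 300, 5):
            cladeB[i] = swap[str(anc[i])]
        recs = []
        for k in range(3):
            for name, base in (("A", cladeA), ("B", cladeB)):
                s = base.copy()
                s[50 + 10 * k + (0 if name == "A" else 5)] = "A"
                recs.append((f"{name}{k}", "".join(s)))
        return Msa(recs)

    def test_deep_split_fully_supported(self):
        msa = self._two_clade_msa()
        _, supports = bootstrap_support(msa, n_reps=50, seed=4)
        clade = frozenset({"A0", "A1", "A2"})
        assert supports.get(clade, supports.get(frozenset({"B0", "B1", "B2"}))) >= 0.95

    def test_single_replicate_supports_are_binary(self):
        msa = self._two_clade_msa(seed=2)
        _, supports = bootstrap_support(msa, n_reps=1, seed=7)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_same_seed_reproducible(self):
        msa = self._two_clade_msa(seed=3)
        _, s1 = bootstrap_support(msa, n_reps=20, seed=42)
        _, s2 = bootstrap_support(msa, n_reps=20, seed=42)
        assert s1 == s2


class TestBuilder:
    def test_estimator_interface(self, quartet):
        msa, _, _ = quartet
        b = UpgmaTreeBuilder(model="tn93", n_bootstrap=5, seed=1)
        assert b.get_params()["model"] == "tn93"
        b.fit(msa)
        assert b.distance_matrix_.d.shape == (4, 4)
        assert b.tree_.newick().count("mito") == 4
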