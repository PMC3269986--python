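"""Haplotype-tree machinery: K2P, NJ, bootstrap, rooting, clustering.

The K2P implementation is cross-checked against R ape's ``dist.dna``
(K80, pairwise deletion) and the NJ implementation against
scikit-bio's ``nj`` — both independent of the in-package code paths.
"""

import math
import subprocess

import dendropy
import numpy as np
import pytest

from haploweb.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloError,
    bootstrap_nj,
    cluster_by_distance,
    collapse_haplotypes,
    edge_bipartitions,
    k2p_distance,
    nj_tree,
    root_with_outgroup,
)
from haploweb.simdata import SimulationConfig, _mutate, _random_seq, simulate_dataset


def random_additive_tree(rng, n_taxa):
    """Random binary topology with uniform branch lengths; returns
    (dendropy tree, DistanceMatrix of its exact path distances)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lb)) for lb in labels]
    for nd in nodes:
        nd.edge.length = float(rng.uniform(0.05, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.05, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j in range(i + 1, n_taxa):
            d = pdm.patristic_distance(
                tns.get_taxon(a), tns.get_taxon(labels[j])
            )
            m[i, j] = m[j, i] = d
    return tree, DistanceMatrix(tuple(labels), m)


def path_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


class TestCollapse:
    def test_distinct_sequences_identity_mapping(self):
        aln = Alignment(("a", "b"), ("ACGT", "AGGT"))
        collapsed, members = collapse_haplotypes(aln)
        assert collapsed.ids == ("a", "b")
        assert members == {"a": ["a"], "b": ["b"]}

    def test_member_counts_sum(self):
        rows = [(f"s{i:02d}", "AAAA") for i in range(40)]
        rows += [(f"s{i:02d}", "CCCC") for i in range(40, 65)]
        rows += [(f"s{i:02d}", "GGGG") for i in range(65, 70)]
        collapsed, members = collapse_haplotypes(Alignment.from_pairs(rows))
        assert len(collapsed) == 3
        assert sum(len(v) for v in members.values()) == 70
        # representative is the smallest member id
        assert set(members) == {"s00", "s40", "s65"}


class TestK2P:
    def test_identical_sequences_zero(self):
        dm = k2p_distance(Alignment(("a", "b"), ("ACGT", "ACGT")))
        assert dm.matrix[0, 1] == 0

    def test_single_transition_closed_form(self):
        # one A<->G transition in 4 sites: P=1/4, Q=0
        dm = k2p_distance(Alignment(("a", "b"), ("ACGT", "GCGT")))
        assert dm.matrix[0, 1] == pytest.approx(-0.5 * math.log(0.5), abs=1e-9)

    def test_pairwise_vs_complete_deletion(self):
        # the gapped column hides a difference only under complete deletion
        aln = Alignment(("a", "b", "c"), ("ACGTA", "AC-TA", "GCGTA"))
        pw = k2p_distance(aln, "pairwise")
        comp = k2p_distance(aln, "complete")
        assert pw.get("a", "c") != comp.get("a", "c")
        gap_free = Alignment(("a", "b"), ("ACGTA", "GCTTA"))
        assert np.allclose(
            k2p_distance(gap_free, "pairwise").matrix,
            k2p_distance(gap_free, "complete").matrix,
        )

    def test_small_divergence_reduces_to_p_plus_q(self, rng):
        """First-order behaviour: d -> P+Q as P,Q -> 0."""
        x = _random_seq(rng, 2000)
        y = _mutate(rng, x, 0.005)
        dm = k2p_distance(Alignment(("x", "y"), (x, y)))
        p_plus_q = sum(a != b for a, b in zip(x, y)) / 2000
        assert p_plus_q <= 0.01
        assert dm.matrix[0, 1] == pytest.approx(p_plus_q, rel=0.05)

    def test_saturated_distance_capped(self):
        aln = Alignment(("a", "b"), ("A" * 40, "G" * 40))  # all transitions
        dm = k2p_distance(aln)
        assert dm.matrix[0, 1] == 5.0

    def test_zero_comparable_sites_error(self):
        with pytest.raises(PhyloError):
            k2p_distance(Alignment(("a", "b"), ("A---", "-CG-")))

    def test_agrees_with_ape_dist_dna(self, rng, tmp_path):
        """Independent oracle: R ape's K80 with pairwise deletion."""
        root = _random_seq(rng, 300)
        ids = tuple(f"t{i}" for i in range(6))
        seqs = []
        for i in range(6):
            s = _mutate(rng, root, 0.08)
            if i % 2:
                s = s[:20] + "--" + s[22:]
            seqs.append(s)
        aln = Alignment(ids, tuple(seqs))
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{i}\n{s}\n" for i, s in zip(ids, seqs)))
        out = subprocess.run(
            [
                "Rscript", "-e",
                f'suppressMessages(library(ape));'
                f'a<-read.dna("{fasta}",format="fasta");'
                f'd<-dist.dna(a,model="K80",pairwise.deletion=TRUE);'
                f'cat(sprintf("%.12f",as.vector(d)),sep="\\n")',
            ],
            capture_output=True, text=True, check=True,
        )
        ape_vals = [float(v) for v in out.stdout.split()]
        dm = k2p_distance(aln, "pairwise")
        mine = dm.matrix[np.tril_indices(6, k=-1)]  # ape emits columnwise lower triangle
        assert np.allclose(sorted(mine), sorted(ape_vals), atol=1e-9)


class TestNJ:
    def test_three_taxa_closed_form(self):
        ids = ("a", "b", "c")
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(DistanceMatrix(ids, m))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_error(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]])))

    def test_additive_four_taxon_recovery(self):
        # ((a,b),(c,d)) with known branch lengths
        ids = ("a", "b", "c", "d")
        m = np.array(
            [
                [0, 3.0, 3.5, 5.5],
                [3.0, 0, 4.5, 6.5],
                [3.5, 4.5, 0, 4.0],
                [5.5, 6.5, 4.0, 0],
            ]
        )
        dm = DistanceMatrix(ids, m)
        tree = nj_tree(dm)
        assert set(edge_bipartitions(tree)) == {frozenset({"c", "d"})}
        for (a, b), d in path_distances(tree).items():
            assert d == pytest.approx(dm.get(a, b), abs=1e-9)

    def test_recovers_random_additive_trees(self):
        """On additive matrices NJ returns the generating topology and
        branch lengths (random 5-8 taxon trees)."""
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = int(rng.integers(5, 9))
            true_tree, dm = random_additive_tree(rng, n)
            est = nj_tree(dm)
            assert set(edge_bipartitions(est)) == set(edge_bipartitions(true_tree))
            for pair, d in path_distances(est).items():
                assert d == pytest.approx(dm.get(*pair), abs=1e-8)

    def test_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        root = _random_seq(rng, 300)
        ids = tuple(f"t{i}" for i in range(7))
        aln = Alignment(ids, tuple(_mutate(rng, root, 0.08) for _ in ids))
        dm = k2p_distance(aln)
        mine = nj_tree(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=list(ids)))
        labels = set(ids)
        ref = min(labels)
        sk_bps = set()
        for node in sk.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(labels - side)
            if 2 <= len(side) <= len(labels) - 2:
                sk_bps.add(side)
        assert set(edge_bipartitions(mine)) == sk_bps

    def test_species_form_clades_on_mito_tree(self, small_dataset):
        mito_aln = Alignment.from_pairs(
            sorted((m, rec.seq) for m, rec in small_dataset.mito.items())
        )
        tree = nj_tree(k2p_distance(mito_aln))
        bps = set(edge_bipartitions(tree))
        for species in ("sp2", "sp3"):  # sp1 contains the reference taxon
            clade = frozenset(m for m in mito_aln.ids if m.startswith(species))
            assert clade in bps


class TestBootstrap:
    def test_deterministic_given_seed(self, small_dataset):
        aln = Alignment.from_pairs(
            sorted((m, rec.seq) for m, rec in small_dataset.mito.items())
        )
        t1 = bootstrap_nj(aln, 25, seed=4)
        t2 = bootstrap_nj(aln, 25, seed=4)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_single_replicate_quantizes_support(self, small_dataset):
        aln = Alignment.from_pairs(
            sorted((m, rec.seq) for m, rec in small_dataset.mito.items())
        )
        tree = bootstrap_nj(aln, 1, seed=0)
        supports = {
            int(nd.label)
            for nd in tree.preorder_node_iter()
            if nd.label is not None and not nd.is_leaf()
        }
        assert supports <= {0, 100}

    def test_deep_split_strongly_supported(self, rng):
        """Two deeply divergent 10-taxon groups: the group split reaches
        >=95% support at 100 replicates."""
        root = _random_seq(rng, 400)
        anc_a = _mutate(rng, root, 0.15)
        anc_b = _mutate(rng, root, 0.15)
        rows = [(f"a{i}", _mutate(rng, anc_a, 0.01)) for i in range(5)]
        rows += [(f"b{i}", _mutate(rng, anc_b, 0.01)) for i in range(5)]
        tree = bootstrap_nj(Alignment.from_pairs(rows), 100, seed=1)
        split = frozenset(f"b{i}" for i in range(5))
        bps = edge_bipartitions(tree)
        assert split in bps
        assert int(bps[split].head_node.label) >= 95

    def test_supports_invariant_to_taxon_order(self, rng):
        root = _random_seq(rng, 200)
        rows = [(f"t{i}", _mutate(rng, root, 0.1)) for i in range(6)]
        t1 = bootstrap_nj(Alignment.from_pairs(rows), 30, seed=2)
        rows_permuted = [rows[i] for i in (3, 0, 5, 1, 4, 2)]
        t2 = bootstrap_nj(Alignment.from_pairs(rows_permuted), 30, seed=2)

        def support_map(tree):
            return {
                bp: int(edge.head_node.label)
                for bp, edge in edge_bipartitions(tree).items()
                if edge.head_node.label is not None
            }

        assert support_map(t1) == support_map(t2)

    def test_small_alignment_returns_tree_without_supports(self):
        aln = Alignment(("a", "b", "c"), ("ACGTT", "ACGTA", "GGGTA"))
        tree = bootstrap_nj(aln, 10, seed=0)
        assert all(
            nd.label is None for nd in tree.preorder_node_iter() if not nd.is_leaf()
        )


class TestRooting:
    def test_single_outgroup_pendant_edge(self):
        ids = ("a", "b", "c", "og")
        m = np.array(
            [
                [0, 0.2, 0.3, 1.0],
                [0.2, 0, 0.3, 1.0],
                [0.3, 0.3, 0, 1.0],
                [1.0, 1.0, 1.0, 0],
            ]
        )
        tree = root_with_outgroup(nj_tree(DistanceMatrix(ids, m)), ["og"])
        assert tree.is_rooted
        children = tree.seed_node.child_nodes()
        sides = [frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in children]
        assert frozenset({"og"}) in sides

    def test_all_taxa_outgroup_rejected(self):
        ids = ("a", "b", "c")
        m = np.array([[0, 0.2, 0.3], [0.2, 0, 0.3], [0.3, 0.3, 0]])
        tree = nj_tree(DistanceMatrix(ids, m))
        with pytest.raises(PhyloError):
            root_with_outgroup(tree, ["a", "b", "c"])

    def test_non_monophyletic_outgroup_rejected(self, rng):
        root = _random_seq(rng, 300)
        anc1, anc2 = _mutate(rng, root, 0.15), _mutate(rng, root, 0.15)
        rows = [(f"a{i}", _mutate(rng, anc1, 0.01)) for i in range(3)]
        rows += [(f"b{i}", _mutate(rng, anc2, 0.01)) for i in range(3)]
        tree = nj_tree(k2p_distance(Alignment.from_pairs(rows)))
        with pytest.raises(PhyloError, match="not monophyletic"):
            root_with_outgroup(tree, ["a0", "b0"])

    def test_simulated_ingroup_outgroup_root_placement(self, rng):
        """With an outgroup clade, the ingroup root falls between the
        divergent ingroup species."""
        root = _random_seq(rng, 400)
        og_anc = _mutate(rng, root, 0.35)
        in_anc = _mutate(rng, root, 0.05)
        anc_a = _mutate(rng, in_anc, 0.12)
        anc_bc = _mutate(rng, in_anc, 0.02)
        anc_b = _mutate(rng, anc_bc, 0.06)
        anc_c = _mutate(rng, anc_bc, 0.06)
        rows = [(f"og{i}", _mutate(rng, og_anc, 0.01)) for i in range(2)]
        for name, anc in (("a", anc_a), ("b", anc_b), ("c", anc_c)):
            rows += [(f"{name}{i}", _mutate(rng, anc, 0.01)) for i in range(3)]
        tree = nj_tree(k2p_distance(Alignment.from_pairs(sorted(rows))))
        rooted = root_with_outgroup(tree, ["og0", "og1"])
        bc = frozenset(f"{n}{i}" for n in "bc" for i in range(3))
        clades = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in rooted.preorder_node_iter()
        }
        assert bc in clades


class TestClusterByDistance:
    @staticmethod
    def dm_from(groups, rng):
        root = _random_seq(rng, 300)
        rows = []
        for g, n in groups:
            anc = _mutate(rng, root, 0.2)
            rows += [(f"{g}{i}", _mutate(rng, anc, 0.01)) for i in range(n)]
        return k2p_distance(Alignment.from_pairs(sorted(rows)))

    def test_threshold_above_max_one_cluster(self, rng):
        dm = self.dm_from([("x", 3), ("y", 3)], rng)
        assert len(cluster_by_distance(dm, dm.matrix.max() + 1)) == 1

    def test_threshold_below_min_all_singletons(self, rng):
        dm = self.dm_from([("x", 3), ("y", 3)], rng)
        nonzero = dm.matrix[dm.matrix > 0]
        assert len(cluster_by_distance(dm, nonzero.min() / 2)) == len(dm)

    def test_auto_threshold_recovers_species(self, small_dataset):
        mito_aln = Alignment.from_pairs(
            sorted((m, rec.seq) for m, rec in small_dataset.mito.items())
        )
        clusters = cluster_by_distance(k2p_distance(mito_aln), "auto")
        got = {frozenset(c) for c in clusters}
        want = {
            frozenset(m for m in mito_aln.ids if m.startswith(sp))
            for sp in ("sp1", "sp2", "sp3")
        }
        assert got == want

    def test_identical_distances_demand_explicit_threshold(self):
        m = np.full((3, 3), 0.4)
        np.fill_diagonal(m, 0.0)
        with pytest.raises(PhyloError):
            cluster_by_distance(DistanceMatrix(("a", "b", "c"), m), "auto")

    def test_monotone_under_taxon_addition(self, rng):
        """Adding a taxon never splits an existing cluster at fixed t."""
        dm = self.dm_from([("x", 4), ("y", 4)], rng)
        t = 0.05
        full = {frozenset(c) for c in cluster_by_distance(dm, t)}
        sub_ids = dm.ids[:-1]
        sub = DistanceMatrix(sub_ids, dm.matrix[:-1, :-1])
        for cluster in cluster_by_distance(sub, t):
            containing = [c for c in full if cluster <= c]
            assert len(containing) == 1
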