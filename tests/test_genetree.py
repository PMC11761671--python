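import numpy as np
import pytest

from dupliscan.genetree import (
    GeneTree,
    MultipleAlignment,
    align_codons_from_protein,
    build_nj_tree,
    nj_from_distances,
    poisson_distance_matrix,
    progressive_align,
    reconcile,
    root_on_label_set,
)
from dupliscan.io_core import parse_newick

from oracles import random_rooted_tree, reconciliation_oracle


class TestCodonBackthreading:
    def test_gap_expands_to_triplet(self):
        aln = MultipleAlignment(rows={"x": "M-K", "y": "MGK"})
        out = align_codons_from_protein(aln, {"x": "ATGAAA", "y": "ATGGGAAAG"})
        assert out.rows["x"] == "ATG---AAA"
        assert out.rows["y"] == "ATGGGAAAG"

    def test_terminal_stop_stripped(self):
        aln = MultipleAlignment(rows={"x": "MK"})
        out = align_codons_from_protein(aln, {"x": "ATGAAATAA"})
        assert out.rows["x"] == "ATGAAA"

    def test_length_mismatch_names_sequence(self):
        aln = MultipleAlignment(rows={"x": "MK"})
        with pytest.raises(ValueError, match="x"):
            align_codons_from_protein(aln, {"x": "ATGAAAGGG"})

    def test_translation_mismatch_is_error(self):
        aln = MultipleAlignment(rows={"x": "MK"})
        with pytest.raises(ValueError, match="does not translate"):
            align_codons_from_protein(aln, {"x": "ATGGGG"})


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        aln = progressive_align({"a": "MKLVH", "b": "MKLVH", "c": "MKLVH"})
        assert all(r == "MKLVH" for r in aln.rows.values())

    def test_single_gap_at_deleted_residue(self):
        aln = progressive_align({"x": "MKLV", "y": "MKV"})
        assert aln.rows == {"x": "MKLV", "y": "MK-V"}

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty sequence"):
            progressive_align({"a": "MK", "b": ""})

    def test_column_recovery_on_simulated_indels(self):
        """Aligning simulated proteins (true alignment known, indels present)
        recovers >= 90% of the true aligned residue pairs."""
        from dupliscan.io_core import translate
        from dupliscan.simulate import GTNode, SimConfig, evolve_codons

        cfg = SimConfig(codon_length=120, codon_indel_rate=0.08, base_omega=0.5)
        rng = np.random.default_rng(5)
        root = GTNode(event="root")
        tips = []
        for i in range(5):
            c = GTNode(length=0.25)
            c.gene_id = f"t{i}"
            root.children.append(c)
            tips.append(c)
        true_aln = evolve_codons(root, cfg, rng)

        prots = {}
        for t in tips:
            cds = "".join(c for _, c in t.seq)
            prots[t.gene_id] = translate(cds)
        est = progressive_align(prots)

        def residue_pairs(rows):
            pairs = set()
            names = list(rows)
            idx = {n: np.cumsum([c != "-" for c in rows[n]]) for n in names}
            L = len(rows[names[0]])
            for col in range(L):
                present = [(n, idx[n][col] - 1) for n in names if rows[n][col] != "-"]
                for i in range(len(present)):
                    for j in range(i + 1, len(present)):
                        pairs.add((present[i], present[j]))
            return pairs

        true_prot_rows = {
            n: "".join(
                "-" if row[i : i + 3] == "---" else "X"
                for i in range(0, len(row), 3)
            )
            for n, row in true_aln.rows.items()
        }
        truth = residue_pairs(true_prot_rows)
        got = residue_pairs(est.rows)
        recovery = len(truth & got) / len(truth)
        assert recovery >= 0.9


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = nj_from_distances(D, ["A", "B", "C"])
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_four_taxon_additive_recovery(self):
        # distances from ((A:1,B:2):1,(C:1,D:1))
        D = np.array(
            [[0, 3, 3, 3], [3, 0, 4, 4], [3, 4, 0, 2], [3, 4, 2, 0]], float
        )
        tree = nj_from_distances(D, ["A", "B", "C", "D"])
        from dupliscan.genetree import _splits

        assert frozenset(
            {frozenset({"A", "B"}), frozenset({"C", "D"})}
        ) in _splits(tree)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(1.0)

    def test_identical_sequences_star_with_zero_lengths(self):
        aln = MultipleAlignment(rows={c: "MKLVMKLV" for c in "ABCD"})
        gt = build_nj_tree(aln, bootstrap=0)
        assert all((l.edge.length or 0) == 0 for l in gt.tree.leaf_node_iter())

    def test_zero_comparable_columns_is_error(self):
        aln = MultipleAlignment(rows={"a": "MK--", "b": "--LV", "c": "MKLV"})
        with pytest.raises(ValueError, match="no comparable columns"):
            poisson_distance_matrix(aln)

    def test_recovers_random_additive_trees(self, rng):
        """NJ reconstructs the exact unrooted topology from the additive
        distance matrix of any random tree (no estimation noise)."""
        import dendropy

        from dupliscan.genetree import _splits

        for rep in range(30):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            truth = parse_newick(random_rooted_tree(labels, rng))
            pdm = truth.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in truth.taxon_namespace}
            D = np.array(
                [[pdm.distance(taxa[a], taxa[b]) for b in labels] for a in labels]
            )
            est = nj_from_distances(D, labels)
            assert _splits(est) == _splits(truth)

    def test_bootstrap_support_high_for_clear_split(self):
        rows = {
            "a1": "MKLVMKLVMKLVMKLV",
            "a2": "MKLVMKLVMKLVMKIV",
            "b1": "WTRHWTRHWTRHWTRH",
            "b2": "WTRHWTRHWTRHWTRY",
        }
        gt = build_nj_tree(MultipleAlignment(rows=rows), bootstrap=50, seed=3)
        supports = [
            float(n.label)
            for n in gt.tree.preorder_node_iter()
            if not n.is_leaf() and n.label
        ]
        assert supports and max(supports) == 100.0

    def test_outgroup_clade_rooting(self):
        t = parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        assert root_on_label_set(t, {"D", "E"})
        root_children = t.seed_node.child_nodes()
        sides = [
            {l.taxon.label for l in c.leaf_iter()} for c in root_children
        ]
        assert {"D", "E"} in sides


class TestReconcile:
    def test_congruent_single_copy_no_duplications(self):
        sp = parse_newick("((A,B),C);")
        gt = GeneTree(parse_newick("((a,b),c);"), {"a": "A", "b": "B", "c": "C"})
        res = reconcile(gt, sp)
        assert res.n_duplications == 0
        assert res.implied_losses == 0
        assert res.post_dup_branches == set()

    def test_terminal_duplication(self):
        sp = parse_newick("(A,B);")
        gt = GeneTree(parse_newick("((a1,a2),b);"), {"a1": "A", "a2": "A", "b": "B"})
        res = reconcile(gt, sp)
        assert res.n_duplications == 1
        assert list(res.dup_placements.values()) == ["A"]
        # both children of the duplication node are post-duplication branches
        assert ("n1", "a1") in res.post_dup_branches
        assert ("n1", "a2") in res.post_dup_branches

    def test_root_duplication_no_losses(self):
        sp = parse_newick("(A,B);")
        gt = GeneTree(
            parse_newick("((a1,b1),(a2,b2));"),
            {"a1": "A", "b1": "B", "a2": "A", "b2": "B"},
        )
        res = reconcile(gt, sp)
        assert res.n_duplications == 1
        assert res.implied_losses == 0

    def test_unknown_species_is_error(self):
        sp = parse_newick("(A,B);")
        gt = GeneTree(parse_newick("(a,q);"), {"a": "A", "q": "Q"})
        with pytest.raises(ValueError, match="not in species tree"):
            reconcile(gt, sp)

    def test_incongruence_implies_duplication(self):
        """A single-copy gene tree conflicting with the species tree cannot
        be explained without duplication."""
        sp = parse_newick("((A,B),C);")
        gt = GeneTree(parse_newick("((a,c),b);"), {"a": "A", "b": "B", "c": "C"})
        assert reconcile(gt, sp).n_duplications >= 1

    def test_matches_exhaustive_oracle(self, rng):
        """LCA reconciliation equals the exhaustive minimum-cost mapping on
        random gene/species tree pairs."""
        for rep in range(40):
            n_sp = int(rng.integers(2, 5))
            sp_labels = [chr(65 + i) for i in range(n_sp)]
            sp = parse_newick(random_rooted_tree(sp_labels, rng))
            n_genes = int(rng.integers(2, 7))
            species_of = {
                f"g{i}": sp_labels[int(rng.integers(0, n_sp))] for i in range(n_genes)
            }
            gt_tree = parse_newick(random_rooted_tree(list(species_of), rng))
            gt = GeneTree(gt_tree, species_of)
            res = reconcile(gt, sp)
            dups, losses = reconciliation_oracle(gt_tree, sp, species_of)
            assert res.n_duplications == dups
            assert res.implied_losses == losses
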