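import itertools
import math

import numpy as np
import pytest

from dupliscan.genetree import GeneTree, MultipleAlignment
from dupliscan.io_core import CODON_TABLE, STOP_CODONS, parse_newick
from dupliscan.selection import (
    BranchSelectionRecord,
    branch_neutrality_test,
    branch_omega,
    compare_dup_branches,
    count_sites,
    fitch_score,
    gene_branch_records,
    reconstruct_ancestral_codons,
    summarize_selection,
)

from oracles import fitch_score_oracle, random_rooted_tree, wilcoxon_exact_oracle


class TestCountSites:
    @pytest.mark.parametrize(
        "codon,syn",
        [("TTT", 1 / 3), ("ATG", 0.0), ("GGG", 1.0), ("TGG", 0.0)],
    )
    def test_known_codons(self, codon, syn):
        s, n = count_sites(codon)
        assert s == pytest.approx(syn)
        assert s + n == pytest.approx(3.0)

    def test_all_sense_codons_match_neighbor_enumeration(self):
        """For every sense codon, the site split equals a direct enumeration
        of its nine single-base neighbors with stop mutations discarded."""
        for codon in sorted(CODON_TABLE):
            aa = CODON_TABLE[codon]
            syn = counted = 0
            for pos, b in itertools.product(range(3), "ACGT"):
                if b == codon[pos]:
                    continue
                nb = codon[:pos] + b + codon[pos + 1 :]
                if nb in STOP_CODONS:
                    continue
                counted += 1
                syn += CODON_TABLE[nb] == aa
            s, n = count_sites(codon)
            assert s == pytest.approx(3 * syn / counted)
            assert n == pytest.approx(3 - 3 * syn / counted)

    def test_ambiguous_codon_skipped(self):
        assert count_sites("ANG") == (0.0, 0.0)

    def test_stop_codon_is_error(self):
        with pytest.raises(ValueError, match="stop codon"):
            count_sites("TAA")


class TestBranchOmega:
    def test_identical_sequences(self):
        rec = branch_omega("ATGAAA", "ATGAAA")
        assert rec.N == rec.S == 0
        assert math.isnan(rec.omega)
        assert branch_neutrality_test(rec) == 1.0

    def test_single_synonymous_change(self):
        parent = "TTT" + "ATG" * 99
        child = "TTC" + "ATG" * 99
        rec = branch_omega(parent, child)
        assert rec.S == pytest.approx(1.0)
        assert rec.N == pytest.approx(0.0)
        assert rec.omega == pytest.approx(0.0)

    def test_omega_arithmetic(self):
        rec = BranchSelectionRecord(("p", "c"), N=10, S=10, N_sites=300, S_sites=100, omega=0)
        omega = (rec.N / rec.N_sites) / (rec.S / rec.S_sites)
        assert omega == pytest.approx(1 / 3)

    def test_site_counts_sum_to_three_per_codon(self, rng):
        codons = sorted(CODON_TABLE)
        seq = "".join(codons[i] for i in rng.integers(0, len(codons), size=200))
        rec = branch_omega(seq, seq)
        assert rec.N_sites + rec.S_sites == pytest.approx(3 * 200, abs=1e-6)

    def test_pathway_counts_equal_hamming_distance(self):
        """N + S between two sense codons equals their nucleotide Hamming
        distance whenever a stop-free pathway exists."""
        from dupliscan.selection import _pathway_counts

        codons = sorted(CODON_TABLE)
        checked = 0
        for c1, c2 in itertools.product(codons[::3], codons[::5]):
            n, s = _pathway_counts(c1, c2)
            ham = sum(a != b for a, b in zip(c1, c2))
            assert n + s == pytest.approx(ham)
            checked += 1
        assert checked > 100

    def test_pathway_symmetry(self):
        from dupliscan.selection import _pathway_counts

        for c1, c2 in [("TTT", "GGA"), ("ATG", "CCC"), ("AAA", "AGG")]:
            assert _pathway_counts(c1, c2) == pytest.approx(_pathway_counts(c2, c1))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            branch_omega("ATGAAA", "ATG")


class TestFitch:
    def test_identical_tips_reconstruct_identically(self):
        gt = GeneTree(parse_newick("((A,B),C);"), {})
        aln = MultipleAlignment(rows={x: "ATGGCA" for x in "ABC"}, alphabet="codon")
        anc = reconstruct_ancestral_codons(aln, gt)
        assert anc["n0"] == anc["n1"] == "ATGGCA"

    def test_single_variant_column(self):
        gt = GeneTree(parse_newick("((A,B),C);"), {})
        aln = MultipleAlignment(
            rows={"A": "ATG", "B": "ATA", "C": "ATA"}, alphabet="codon"
        )
        anc = reconstruct_ancestral_codons(aln, gt)
        assert anc["n0"] == "ATA"  # root
        assert anc["n1"] == "ATA"  # one change, on the branch to A

    def test_missing_tip_is_error(self):
        gt = GeneTree(parse_newick("((A,B),C);"), {})
        aln = MultipleAlignment(rows={"A": "ATG", "B": "ATG"}, alphabet="codon")
        with pytest.raises(ValueError, match="missing from alignment"):
            reconstruct_ancestral_codons(aln, gt)

    def test_score_matches_exhaustive_enumeration(self, rng):
        bases = "ACGT"
        for rep in range(25):
            n = int(rng.integers(3, 7))
            labels = [f"t{i}" for i in range(n)]
            tree = parse_newick(random_rooted_tree(labels, rng))
            L = int(rng.integers(2, 6))
            tips = {
                l: "".join(bases[i] for i in rng.integers(0, 4, size=L)) for l in labels
            }
            gt = GeneTree(tree, {})
            aln = MultipleAlignment(rows=tips)
            assert fitch_score(aln, gt) == fitch_score_oracle(tree, tips)

    def test_reconstruction_attains_parsimony_score(self, rng):
        """Changes implied by the reconstructed ancestors equal the Fitch
        score (the top-down pass loses no optimality)."""
        for rep in range(10):
            labels = [f"t{i}" for i in range(5)]
            tree = parse_newick(random_rooted_tree(labels, rng))
            tips = {
                l: "".join("ACGT"[i] for i in rng.integers(0, 4, size=4)) for l in labels
            }
            gt = GeneTree(tree, {})
            aln = MultipleAlignment(rows=tips)
            anc = reconstruct_ancestral_codons(aln, gt)
            from dupliscan.genetree import node_ids

            ids = node_ids(gt.tree)
            changes = 0
            for node in gt.tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                p, c = anc[ids[node.parent_node]], anc[ids[node]]
                changes += sum(a != b for a, b in zip(p, c))
            assert changes == fitch_score(aln, gt)


class TestNeutralityTest:
    def test_no_nonsynonymous_gives_p_one(self):
        rec = BranchSelectionRecord(("p", "c"), N=0, S=5, N_sites=300, S_sites=100, omega=0)
        assert branch_neutrality_test(rec) == 1.0

    def test_closed_form_binomial_tail(self):
        rec = BranchSelectionRecord(("p", "c"), N=10, S=0, N_sites=300, S_sites=100, omega=float("nan"))
        assert branch_neutrality_test(rec) == pytest.approx(0.75**10)

    def test_zero_substitutions_p_one(self):
        rec = BranchSelectionRecord(("p", "c"), N=0, S=0, N_sites=300, S_sites=100, omega=float("nan"))
        assert branch_neutrality_test(rec) == 1.0


class TestDupContrast:
    def _records(self, dup_omegas, nondup_omegas):
        recs = []
        for i, w in enumerate(dup_omegas):
            recs.append(
                BranchSelectionRecord((f"d{i}", "x"), 1, 1, 3, 1, w, post_duplication=True)
            )
        for i, w in enumerate(nondup_omegas):
            recs.append(BranchSelectionRecord((f"n{i}", "x"), 1, 1, 3, 1, w))
        return recs

    def test_exact_enumeration_small_groups(self):
        _, _, p = compare_dup_branches(self._records([4, 5, 6], [1, 2, 3]))
        assert p == pytest.approx(1 / 20)

    def test_matches_enumeration_oracle(self, rng):
        for rep in range(12):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            dup, nondup = list(vals[:n1]), list(vals[n1:])
            _, _, p = compare_dup_branches(self._records(dup, nondup))
            assert p == pytest.approx(wilcoxon_exact_oracle(dup, nondup))

    def test_undefined_omegas_excluded(self):
        recs = self._records([4, 5, 6], [1, 2, 3])
        recs.append(
            BranchSelectionRecord(("d9", "x"), 1, 0, 3, 1, float("nan"), post_duplication=True)
        )
        med_dup, med_non, p = compare_dup_branches(recs)
        assert med_dup == 5.0 and p == pytest.approx(1 / 20)

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError, match="each branch class"):
            compare_dup_branches(self._records([], [1, 2, 3]))


class TestGeneBranchRecords:
    def test_summary_consistency(self, rng):
        from dupliscan.simulate import GTNode, SimConfig, evolve_codons

        cfg = SimConfig(codon_length=150, codon_indel_rate=0.0, base_omega=0.3)
        root = GTNode(event="root")
        for i in range(3):
            c = GTNode(length=0.3)
            c.gene_id = f"t{i}"
            root.children.append(c)
        aln = evolve_codons(root, cfg, np.random.default_rng(2))
        gt = GeneTree(parse_newick("(t0,t1,t2);"), {})
        recs = gene_branch_records(aln, gt)
        summ = summarize_selection("g", recs)
        assert summ.n_branches == len(recs) == 3
        assert summ.n_omega_gt1 <= summ.n_branches
        assert all(0 <= r.p_value <= 1 and r.fdr_q >= r.p_value - 1e-12 for r in recs)
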