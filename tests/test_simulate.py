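import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

from dupliscan.genetree import GeneTree
from dupliscan.io_core import parse_newick, translate
from dupliscan.selection import branch_omega
from dupliscan.simulate import (
    GTNode,
    SimConfig,
    evolve_codons,
    evolve_expression,
    simulate_cohort,
    simulate_family,
    simulate_gene_tree,
    write_cohort,
    _nb_draw,
)


def _dir_digest(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestGeneTreeSimulation:
    def test_no_events_gives_one_copy_per_species(self):
        cfg = SimConfig(dup_rate=0.0, loss_rate=0.0)
        sp = parse_newick(cfg.species_tree)
        rng = np.random.default_rng(1)
        root = simulate_gene_tree(sp, cfg, rng)
        tips = root.tips()
        assert sorted(t.species for t in tips) == sorted(
            l.taxon.label for l in sp.leaf_node_iter()
        )
        # congruent: reconciling the true tree yields zero duplications
        from dupliscan.genetree import reconcile
        from dupliscan.simulate import gene_tree_newick

        for i, t in enumerate(tips):
            t.gene_id = f"g{i}"
        gt = GeneTree(
            parse_newick(gene_tree_newick(root)),
            {t.gene_id: t.species for t in tips},
        )
        res = reconcile(gt, sp)
        assert res.n_duplications == 0 and res.implied_losses == 0

    def test_duplication_count_matches_pure_birth_expectation(self):
        """Mean realized duplications (loss-free) match the analytic
        pure-birth expectation integrated over the species tree."""
        lam = 1.0
        cfg = SimConfig(dup_rate=lam, loss_rate=0.0)
        sp = parse_newick(cfg.species_tree)

        def expected(node, m):
            # m = expected lineage count entering this node
            total = 0.0
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                total += m * (math.exp(lam * t) - 1.0)
                total += expected(child, m * math.exp(lam * t))
            return total

        exp_events = expected(sp.seed_node, 1.0)
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(400):
            root = simulate_gene_tree(sp, cfg, rng)
            counts.append(sum(1 for n in root.walk() if n.event == "duplication"))
        assert np.mean(counts) == pytest.approx(exp_events, rel=0.1)

    def test_loss_can_extinguish_family(self):
        cfg = SimConfig(dup_rate=0.0, loss_rate=50.0)
        sp = parse_newick(cfg.species_tree)
        assert simulate_gene_tree(sp, cfg, np.random.default_rng(0)) is None


class TestCodonEvolution:
    def _star(self, n, length):
        root = GTNode(event="root")
        for i in range(n):
            c = GTNode(length=length)
            c.gene_id = f"t{i}"
            root.children.append(c)
        return root

    def test_omega_zero_keeps_protein_identical(self):
        cfg = SimConfig(codon_length=100, base_omega=0.0, codon_indel_rate=0.0)
        root = self._star(3, 0.5)
        evolve_codons(root, cfg, np.random.default_rng(3))
        root_prot = translate("".join(c for _, c in root.seq))
        for t in root.tips():
            assert translate("".join(c for _, c in t.seq)) == root_prot

    def test_no_stops_ever_introduced(self):
        cfg = SimConfig(codon_length=200, base_omega=2.0, codon_indel_rate=0.01)
        root = self._star(4, 0.6)
        evolve_codons(root, cfg, np.random.default_rng(4))
        for t in root.tips():
            prot = translate("".join(c for _, c in t.seq))
            assert "*" not in prot

    def test_true_alignment_consistent_with_tip_sequences(self):
        cfg = SimConfig(codon_length=80, codon_indel_rate=0.1)
        root = self._star(4, 0.4)
        aln = evolve_codons(root, cfg, np.random.default_rng(5))
        for t in root.tips():
            assert aln.rows[t.gene_id].replace("-", "") == "".join(c for _, c in t.seq)

    def test_estimated_omega_tracks_truth(self):
        """Branches simulated at low vs high omega estimate in the right
        order when counted against the known ancestor."""
        rng = np.random.default_rng(29)
        correct = 0
        for rep in range(30):
            cfg_lo = SimConfig(codon_length=500, base_omega=0.2, codon_indel_rate=0.0)
            cfg_hi = SimConfig(codon_length=500, base_omega=2.0, codon_indel_rate=0.0)
            root_codons = None
            root = self._star(1, 0.4)
            aln = evolve_codons(root, cfg_lo, rng)
            lo = branch_omega(
                "".join(c for _, c in root.seq), "".join(c for _, c in root.tips()[0].seq)
            )
            root2 = self._star(1, 0.4)
            evolve_codons(root2, cfg_hi, rng)
            hi = branch_omega(
                "".join(c for _, c in root2.seq),
                "".join(c for _, c in root2.tips()[0].seq),
            )
            if not math.isnan(lo.omega) and not math.isnan(hi.omega):
                correct += lo.omega < hi.omega
        assert correct >= 28


class TestExpressionEvolution:
    def test_zero_rate_keeps_root_value(self):
        cfg = SimConfig(bm_sigma2=0.0, testis_shift_prob=0.0)
        root = GTNode(event="root")
        for i in range(3):
            c = GTNode(length=1.0)
            c.gene_id = f"t{i}"
            root.children.append(c)
        evolve_expression(root, cfg, np.random.default_rng(6))
        for t in root.tips():
            assert t.expr == (cfg.root_log_tpm, cfg.root_log_tpm)

    def test_two_tip_contrast_variance(self):
        """var(tip1 - tip2) over replicates equals 2 sigma^2 for unit
        branches (the BM closed form)."""
        cfg = SimConfig(bm_sigma2=0.7, testis_shift_prob=0.0)
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(1000):
            root = GTNode(event="root")
            a, b = GTNode(length=1.0), GTNode(length=1.0)
            root.children = [a, b]
            evolve_expression(root, cfg, rng)
            diffs.append(a.expr[0] - b.expr[0])
        assert np.var(diffs) == pytest.approx(2 * 0.7, rel=0.15)

    def test_certain_shift_elevates_new_copy(self):
        cfg = SimConfig(
            dup_rate=2.0,
            loss_rate=0.0,
            bm_sigma2=1e-6,
            testis_shift_prob=1.0,
            testis_shift_size=3.0,
        )
        sp = parse_newick(cfg.species_tree)
        rng = np.random.default_rng(8)
        shifted = 0
        for _ in range(20):
            res = simulate_family(cfg, rng, "f", sp)
            if res is None:
                continue
            root, truth = res
            for t in root.tips():
                if t.new_copy and t.shift > 0:
                    shifted += 1
                    assert t.expr[1] > cfg.root_log_tpm + 2.0
        assert shifted > 0


class TestCounts:
    def test_zero_tpm_zero_counts(self):
        counts = _nb_draw(np.zeros(10), 0.05, np.random.default_rng(9))
        assert (counts == 0).all()

    def test_tiny_dispersion_behaves_like_poisson(self):
        rng = np.random.default_rng(10)
        mean = np.full(5000, 50.0)
        draws = _nb_draw(mean, 1e-12, rng)
        assert np.var(draws) == pytest.approx(50.0, rel=0.1)

    def test_tpm_roundtrip_correlation(self):
        """counts_to_tpm on simulated counts recovers the latent TPM."""
        import pandas as pd

        from dupliscan.expression import counts_to_tpm

        rng = np.random.default_rng(31)
        n = 1000
        tpm_true = rng.gamma(0.6, 800.0, size=n)
        tpm_true = tpm_true / tpm_true.sum() * 1e6
        lengths = rng.integers(300, 3000, size=n).astype(float)
        share = tpm_true * lengths
        mean = 1e6 * share / share.sum()
        lengths_map = {f"g{i}": lengths[i] for i in range(n)}
        # at the default overdispersion, recovery is tight on the log scale
        counts = _nb_draw(mean, 0.05, rng)
        df = pd.DataFrame({"s": counts}, index=[f"g{i}" for i in range(n)])
        est = counts_to_tpm(df, lengths_map)["s"].to_numpy()
        assert np.corrcoef(np.log1p(tpm_true), np.log1p(est))[0, 1] >= 0.98
        # in the Poisson sampling limit the raw-scale correlation is >= 0.99
        counts_p = _nb_draw(mean, 1e-12, rng)
        dfp = pd.DataFrame({"s": counts_p}, index=df.index)
        est_p = counts_to_tpm(dfp, lengths_map)["s"].to_numpy()
        assert np.corrcoef(tpm_true, est_p)[0, 1] >= 0.99


class TestCohort:
    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = SimConfig(n_families=3, n_background_genes=20, seed=77,
                        spacer_min=5000, spacer_max=9000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), d1)
        write_cohort(simulate_cohort(cfg), d2)
        assert _dir_digest(d1) == _dir_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        base = dict(n_families=3, n_background_genes=20, spacer_min=5000, spacer_max=9000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(SimConfig(seed=1, **base)), d1)
        write_cohort(simulate_cohort(SimConfig(seed=2, **base)), d2)
        assert _dir_digest(d1) != _dir_digest(d2)

    def test_truth_ledger_consistent_with_files(self, small_cohort):
        truth_genes = {
            c["gene_id"]
            for fam in small_cohort.truth["families"]
            for c in fam["copies"]
        }
        emitted = {
            r.gene_id for recs in small_cohort.gene_records.values() for r in recs
        }
        assert truth_genes == emitted

    def test_counts_match_metadata(self, small_cohort):
        assert set(small_cohort.counts.columns) == set(small_cohort.sample_meta.index)
        assert (small_cohort.counts.to_numpy() >= 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="dup_rate"):
            SimConfig(dup_rate=-1)
        with pytest.raises(ValueError, match="tandem_fraction"):
            SimConfig(tandem_fraction=1.5)
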