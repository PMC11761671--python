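"""Synthetic-data generator: gene families evolving along a species tree with
duplication and loss, codon sequences under branch-specific omega, conserved
or scrambled flanking synteny, two-tissue expression under Brownian motion
with occasional testis-bias shifts, and negative-binomial read counts — plus
a truth ledger recording every latent quantity the analysis stages estimate.

The generative model, stage by stage:

- Gene copy number follows a birth-death process along the species tree
  (duplications at ``dup_rate`` and losses at ``loss_rate`` per branch-length
  unit per lineage). A new copy is tandem with probability
  ``tandem_fraction`` (placed 5-50 kb from its parent on the same scaffold,
  inheriting the conserved neighbourhood) and otherwise a retro-style
  dispersed copy (intron-less, on a separate scaffold with novel random
  flanks). A duplicate is pseudogenized (premature stop) with probability
  ``pseudogenization_prob``.
- Codon sequences evolve by proposal/acceptance: nucleotide changes proposed
  at rate ``mu`` per site with transition bias ``kappa``; synonymous
  proposals are always accepted, nonsynonymous ones with probability omega
  (capped at 1; omega > 1 acts as a nonsynonymous rate multiplier via an
  extra nonsynonymous-only proposal stream); proposals creating stops are
  rejected. Branches descending from duplication nodes use
  ``post_dup_omega``, all others ``base_omega``. Whole-codon indels are
  recorded in a true alignment.
- Intergenic spacers and introns descend from ancestral random sequence by
  Jukes-Cantor substitution along the species tree, so orthologous
  neighbourhoods stay alignable while diverging.
- Log expression (ln(TPM+1)) evolves per tissue by independent Brownian
  motion with variance ``bm_sigma2`` per branch-length unit; at a
  duplication the new copy's testis trait jumps by ``testis_shift_size``
  with probability ``testis_shift_prob``. Background (single-copy) genes for
  the percentile analysis share one sigma2, with a heavy-tail fraction at a
  larger rate.
- Read counts per sample are negative-binomial around
  library_size x TPM x length shares, so TPM normalization of the emitted
  counts recovers the latent expression up to sampling error.

Everything is driven by one integer-seeded generator: the same config and
seed reproduce byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .genetree import MultipleAlignment
from .io_core import (
    CODON_TABLE,
    STOP_CODONS,
    GeneRecord,
    Genome,
    Scaffold,
    parse_newick,
    reverse_complement,
    write_fasta,
    write_gff_genes,
    write_newick,
)

DEFAULT_SPECIES_TREE = (
    "((((A:0.10,B:0.10):0.08,C:0.18):0.08,(D:0.12,E:0.12):0.14):0.12,F:0.38);"
)

_SENSE_CODONS = sorted(CODON_TABLE)
_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort. Rates are per branch-length
    unit (expected neutral substitutions per site); see docs/methods.md for
    the reasoning behind each default."""

    species_tree: str = DEFAULT_SPECIES_TREE
    n_families: int = 20
    n_background_genes: int = 1000
    dup_rate: float = 0.8
    loss_rate: float = 0.2
    tandem_fraction: float = 0.7
    pseudogenization_prob: float = 0.1
    codon_length: int = 500
    base_omega: float = 0.2
    post_dup_omega: float = 1.5
    kappa: float = 2.0
    mu: float = 1.0
    codon_indel_rate: float = 0.005
    indel_mean_codons: float = 1.5
    bm_sigma2: float = 0.5
    heavy_tail_fraction: float = 0.1
    heavy_tail_factor: float = 4.0
    root_log_tpm: float = 4.0
    testis_shift_prob: float = 0.5
    testis_shift_size: float = 1.5
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    n_replicates: int = 1
    genes_per_scaffold: int = 20
    spacer_min: int = 10_000
    spacer_max: int = 100_000
    tandem_offset_min: int = 5_000
    tandem_offset_max: int = 50_000
    n_introns_max: int = 2
    intron_min: int = 80
    intron_max: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dup_rate", "loss_rate", "mu", "bm_sigma2", "codon_indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tandem_fraction", "pseudogenization_prob", "testis_shift_prob",
                     "heavy_tail_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# gene-tree birth-death simulation
# ---------------------------------------------------------------------------


class GTNode:
    """Node of a simulated gene tree. ``length`` is in species-tree
    branch-length units; ``event`` is root/speciation/duplication/tip."""

    __slots__ = (
        "children", "length", "event", "species", "gene_id", "post_dup",
        "new_copy", "mode", "pseudo", "shift", "seq", "expr", "node_id",
    )

    def __init__(self, length: float = 0.0, event: str = "tip"):
        self.children: list[GTNode] = []
        self.length = length
        self.event = event
        self.species: str | None = None
        self.gene_id: str | None = None
        self.post_dup = False
        self.new_copy = False     # the child lineage created by a duplication
        self.mode = "ancestral"   # ancestral | tandem | dispersed
        self.pseudo = False
        self.shift = 0.0          # testis-bias jump applied at birth
        self.seq: list | None = None
        self.expr: tuple[float, float] | None = None
        self.node_id: str | None = None

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def tips(self) -> list["GTNode"]:
        return [n for n in self.walk() if not n.children]


def _birth_death_segment(
    stub: GTNode, t: float, cfg: SimConfig, rng, counters: dict | None = None
) -> list[GTNode]:
    """Evolve one lineage over a time span; returns the stubs alive at the
    end (the same node, or the leaves of an in-branch duplication subtree)."""
    rate = cfg.dup_rate + cfg.loss_rate
    remaining = t
    node = stub
    while True:
        wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if wait >= remaining:
            node.length += remaining
            return [node]
        node.length += wait
        remaining -= wait
        if rng.random() < cfg.loss_rate / rate:
            node.event = "loss"
            if counters is not None:
                counters["losses"] = counters.get("losses", 0) + 1
            return []
        # duplication: node becomes an internal duplication node
        node.event = "duplication"
        kept = GTNode()
        new = GTNode()
        new.new_copy = True
        new.mode = "tandem" if rng.random() < cfg.tandem_fraction else "dispersed"
        new.pseudo = rng.random() < cfg.pseudogenization_prob
        if rng.random() < cfg.testis_shift_prob:
            new.shift = cfg.testis_shift_size
        node.children = [kept, new]
        out = []
        for child in node.children:
            out.extend(_birth_death_segment(child, remaining, cfg, rng, counters))
        return out


def simulate_gene_tree(
    sp_tree: dendropy.Tree, cfg: SimConfig, rng, counters: dict | None = None
) -> GTNode | None:
    """Birth-death gene tree along the species tree. Returns the pruned
    surviving tree (unary nodes suppressed) or None on family extinction.
    ``counters`` (if given) accumulates the number of loss events."""

    root = GTNode(event="root")

    def descend(sp_node: dendropy.Node, stubs: list[GTNode]) -> None:
        if not stubs:
            return
        if sp_node.is_leaf():
            for s in stubs:
                s.event = "tip"
                s.species = sp_node.taxon.label
            return
        for s in stubs:
            s.event = "speciation"
        for child in sp_node.child_nodes():
            t = child.edge.length or 0.0
            next_stubs: list[GTNode] = []
            for s in stubs:
                stub = GTNode()
                stub.mode, stub.pseudo = "ancestral", s.pseudo
                s.children.append(stub)
                next_stubs.extend(_birth_death_segment(stub, t, cfg, rng, counters))
            descend(child, next_stubs)

    descend(sp_tree.seed_node, [root])
    root = _prune(root)
    if root is None:
        return None
    _mark_post_dup(root, False)
    i = 0
    for n in root.walk():
        if n.children:
            n.node_id = f"n{i}"
            i += 1
    return root


def _prune(node: GTNode) -> GTNode | None:
    """Drop dead subtrees and suppress unary internal nodes (their lengths
    collapse onto the surviving child)."""
    if not node.children:
        return None if node.event == "loss" else node
    kept = []
    for c in node.children:
        p = _prune(c)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        # birth attributes of the vanished path are inherited by the child
        child.mode = child.mode if child.mode != "ancestral" else node.mode
        child.new_copy = child.new_copy or node.new_copy
        child.shift = child.shift + node.shift
        child.pseudo = child.pseudo or node.pseudo
        return child
    node.children = kept
    return node


def _mark_post_dup(node: GTNode, flag: bool) -> None:
    node.post_dup = node.post_dup or flag
    nxt = flag or node.event == "duplication"
    for c in node.children:
        c.post_dup = c.post_dup or nxt
        _mark_post_dup(c, nxt)


def gene_tree_newick(root: GTNode) -> str:
    def fmt(n: GTNode) -> str:
        if not n.children:
            return f"{n.gene_id}:{n.length:.6g}"
        inner = ",".join(fmt(c) for c in n.children)
        return f"({inner}){n.node_id}:{n.length:.6g}"

    return fmt(root) + ";"


# ---------------------------------------------------------------------------
# codon evolution with a true alignment
# ---------------------------------------------------------------------------


def random_root_codons(n: int, rng) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n)
    return [_SENSE_CODONS[i] for i in idx]


def _propose_base(base: str, kappa: float, rng) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    tv = [b for b in _BASES if b != base and b != _TRANSITION[base]]
    return tv[0] if rng.random() < 0.5 else tv[1]


def evolve_branch_codons(
    entries: list[tuple[int, str]],
    t: float,
    omega: float,
    cfg: SimConfig,
    rng,
    order: list[int],
    uid_counter: list[int],
) -> list[tuple[int, str]]:
    """Evolve one branch: substitution proposals plus whole-codon indels.

    ``entries`` is the parent's sequence as (column uid, codon) pairs;
    ``order`` is the global alignment column order, extended in place when
    insertions create new columns.
    """
    if omega < 0:
        raise ValueError("omega < 0")
    seq = list(entries)
    L_nt = 3 * len(seq)
    lam_main = cfg.mu * L_nt * t
    lam_extra = cfg.mu * L_nt * t * max(0.0, omega - 1.0)
    n_main = rng.poisson(lam_main) if lam_main > 0 else 0
    n_extra = rng.poisson(lam_extra) if lam_extra > 0 else 0
    for stream, n_prop in (("main", n_main), ("extra", n_extra)):
        for _ in range(n_prop):
            if not seq:
                break
            pos = int(rng.integers(0, 3 * len(seq)))
            ci, off = divmod(pos, 3)
            uid, codon = seq[ci]
            new = codon[:off] + _propose_base(codon[off], cfg.kappa, rng) + codon[off + 1 :]
            if new in STOP_CODONS:
                continue
            syn = CODON_TABLE[new] == CODON_TABLE[codon]
            if stream == "main":
                accept = syn or (rng.random() < min(1.0, omega))
            else:
                accept = not syn
            if accept:
                seq[ci] = (uid, new)

    if cfg.codon_indel_rate > 0 and seq:
        n_ind = rng.poisson(cfg.codon_indel_rate * len(seq) * t)
        for _ in range(n_ind):
            if not seq:
                break
            k = 1 + rng.geometric(1.0 / cfg.indel_mean_codons) - 1
            k = int(min(k, 3))
            if rng.random() < 0.5 and len(seq) > k:  # deletion
                start = int(rng.integers(0, len(seq) - k + 1))
                del seq[start : start + k]
            else:  # insertion
                at = int(rng.integers(0, len(seq) + 1))
                new_entries = []
                for _j in range(k):
                    uid_counter[0] += 1
                    new_entries.append((uid_counter[0], random_root_codons(1, rng)[0]))
                anchor = order.index(seq[at - 1][0]) + 1 if at > 0 else 0
                for j, e in enumerate(new_entries):
                    order.insert(anchor + j, e[0])
                seq[at:at] = new_entries
    return seq


def evolve_codons(
    root: GTNode, cfg: SimConfig, rng, root_codons: list[str] | None = None
) -> MultipleAlignment:
    """Evolve codon sequences down a gene tree, branch omega chosen by the
    post-duplication flag. Stores each node's sequence on the node and
    returns the true tip alignment (gaps for deleted/absent columns)."""
    codons = root_codons or random_root_codons(cfg.codon_length, rng)
    root.seq = [(i, c) for i, c in enumerate(codons)]
    order = [i for i, _ in root.seq]
    uid_counter = [len(order) - 1]

    def recurse(node: GTNode) -> None:
        for c in node.children:
            omega = cfg.post_dup_omega if c.post_dup else cfg.base_omega
            c.seq = evolve_branch_codons(
                node.seq, c.length, omega, cfg, rng, order, uid_counter
            )
            recurse(c)

    recurse(root)

    pos_of = {uid: i for i, uid in enumerate(order)}
    rows: dict[str, str] = {}
    for tip in root.tips():
        row = ["---"] * len(order)
        for uid, codon in tip.seq:
            row[pos_of[uid]] = codon
        rows[tip.gene_id or f"tip{id(tip)}"] = "".join(row)
    return MultipleAlignment(rows=rows, alphabet="codon")


def branch_true_omegas(root: GTNode, cfg: SimConfig) -> dict[tuple[str, str], float]:
    out = {}

    def rec(node: GTNode) -> None:
        pid = node.node_id or node.gene_id
        for c in node.children:
            cid = c.node_id or c.gene_id
            out[(pid, cid)] = cfg.post_dup_omega if c.post_dup else cfg.base_omega
            rec(c)

    rec(root)
    return out


# ---------------------------------------------------------------------------
# expression evolution
# ---------------------------------------------------------------------------


def evolve_expression(root: GTNode, cfg: SimConfig, rng) -> None:
    """Independent per-tissue Brownian motion down the gene tree from the root
    (ovary, testis) log values, with the configured testis jump applied at the
    birth of new duplicate copies. Stores (ovary, testis) on every node."""
    root.expr = (cfg.root_log_tpm, cfg.root_log_tpm)

    def rec(node: GTNode) -> None:
        for c in node.children:
            sd = math.sqrt(cfg.bm_sigma2 * max(c.length, 0.0))
            o = node.expr[0] + rng.normal(0.0, sd)
            t = node.expr[1] + rng.normal(0.0, sd) + c.shift
            c.expr = (o, t)
            rec(c)

    rec(root)


def tip_tpm(node: GTNode) -> tuple[float, float]:
    """Back-transform a tip's log values to TPM (log convention ln(TPM+1))."""
    o, t = node.expr
    return max(math.exp(o) - 1.0, 0.0), max(math.exp(t) - 1.0, 0.0)


def simulate_background_rates(
    sp_tree: dendropy.Tree, cfg: SimConfig, rng, n: int | None = None
) -> pd.DataFrame:
    """Single-copy background genes: per-tissue BM tip values on the species
    tree. A ``heavy_tail_fraction`` of genes evolves at
    ``heavy_tail_factor`` x sigma2. Returns tidy rows
    (gene, species, ovary_tpm, testis_tpm, sigma2_class)."""
    n = n if n is not None else cfg.n_background_genes
    species = [l.taxon.label for l in sp_tree.leaf_node_iter()]
    # precompute branch order for one BM pass
    rows = []
    for i in range(n):
        heavy = rng.random() < cfg.heavy_tail_fraction
        s2 = cfg.bm_sigma2 * (cfg.heavy_tail_factor if heavy else 1.0)
        vals = {"__root__": (cfg.root_log_tpm, cfg.root_log_tpm)}
        node_vals: dict[dendropy.Node, tuple[float, float]] = {}
        for node in sp_tree.preorder_node_iter():
            if node.parent_node is None:
                node_vals[node] = (cfg.root_log_tpm, cfg.root_log_tpm)
                continue
            po, pt = node_vals[node.parent_node]
            sd = math.sqrt(s2 * (node.edge.length or 0.0))
            node_vals[node] = (po + rng.normal(0.0, sd), pt + rng.normal(0.0, sd))
        for leaf in sp_tree.leaf_node_iter():
            o, t = node_vals[leaf]
            rows.append(
                dict(
                    gene=f"bg{i}",
                    species=leaf.taxon.label,
                    ovary_tpm=max(math.exp(o) - 1.0, 0.0),
                    testis_tpm=max(math.exp(t) - 1.0, 0.0),
                    heavy=heavy,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genomes, placement, counts
# ---------------------------------------------------------------------------


def _random_dna(n: int, rng) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _to_str(arr: np.ndarray) -> str:
    return "".join("ACGT"[b] for b in arr)


_TO_STR_TABLE = np.frombuffer(b"ACGT", dtype="S1")


def _arr_to_seq(arr: np.ndarray) -> str:
    return _TO_STR_TABLE[arr].tobytes().decode()


def _jc_mutate(arr: np.ndarray, t: float, mu: float, rng) -> np.ndarray:
    """Jukes-Cantor substitution of an int8 base array over time t."""
    p = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * mu * t))
    out = arr.copy()
    n_mut = rng.binomial(len(arr), p)
    if n_mut:
        pos = rng.choice(len(arr), size=n_mut, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut, dtype=np.int8)) % 4
    return out


def _evolve_skeleton(
    sp_tree: dendropy.Tree, ancestral: np.ndarray, mu: float, rng
) -> dict[str, np.ndarray]:
    """Evolve the concatenated neutral skeleton (spacers + introns) down the
    species tree; one evolved copy per species."""
    out: dict[str, np.ndarray] = {}
    state: dict[dendropy.Node, np.ndarray] = {}
    for node in sp_tree.preorder_node_iter():
        if node.parent_node is None:
            state[node] = ancestral
        else:
            state[node] = _jc_mutate(state[node.parent_node], node.edge.length or 0.0, mu, rng)
        if node.is_leaf():
            out[node.taxon.label] = state[node]
    return out


@dataclass
class FamilyTruth:
    family_id: str
    gene_tree_newick: str
    events: dict[str, str]
    n_duplications: int
    loss_free: bool
    branch_omegas: dict[str, float]  # "parent>child" -> omega
    true_alignment: dict[str, str]
    copies: list[dict]
    expression: dict[str, tuple[float, float]]
    ortholog_pairs: list[tuple[str, str]]


@dataclass
class SimCohort:
    cfg: SimConfig
    species_tree: dendropy.Tree
    genomes: dict[str, Genome]
    gene_records: dict[str, list[GeneRecord]]  # per species
    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: dict[str, float]
    truth: dict


def _ortholog_pairs(root: GTNode) -> list[tuple[str, str]]:
    """Cross-species tip pairs whose gene-tree LCA is a speciation node."""
    pairs = []

    def tipset(n: GTNode) -> list[GTNode]:
        return n.tips()

    def rec(node: GTNode) -> None:
        if not node.children:
            return
        if node.event in ("speciation", "root"):
            for i in range(len(node.children)):
                for j in range(i + 1, len(node.children)):
                    for a in tipset(node.children[i]):
                        for b in tipset(node.children[j]):
                            if a.species != b.species:
                                pairs.append((a.gene_id, b.gene_id))
        for c in node.children:
            rec(c)

    rec(root)
    return pairs


def simulate_family(cfg: SimConfig, rng, family_id: str, sp_tree: dendropy.Tree):
    """One family: gene tree, codon evolution, expression. Returns
    (root GTNode, FamilyTruth) or None if the family went extinct."""
    counters: dict = {"losses": 0}
    root = simulate_gene_tree(sp_tree, cfg, rng, counters)
    if root is None:
        return None
    loss_free = counters["losses"] == 0

    for i, tip in enumerate(root.tips()):
        tip.gene_id = f"{family_id}_{tip.species}_c{i}"

    aln = evolve_codons(root, cfg, rng)
    evolve_expression(root, cfg, rng)

    events = {n.node_id: n.event for n in root.walk() if n.children}
    omegas = {
        f"{p}>{c}": w for (p, c), w in branch_true_omegas(root, cfg).items()
    }
    truth = FamilyTruth(
        family_id=family_id,
        gene_tree_newick=gene_tree_newick(root),
        events=events,
        n_duplications=sum(1 for e in events.values() if e == "duplication"),
        loss_free=loss_free,
        branch_omegas=omegas,
        true_alignment=dict(aln.rows),
        copies=[],
        expression={
            (n.node_id or n.gene_id): n.expr for n in root.walk()
        },
        ortholog_pairs=_ortholog_pairs(root),
    )
    return root, truth


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Generate the full synthetic cohort: genomes + annotations per species,
    family CDS/protein sets, a counts table with sample metadata, and the
    truth ledger."""
    rng = np.random.default_rng(cfg.seed)
    sp_tree = parse_newick(cfg.species_tree)
    species = [l.taxon.label for l in sp_tree.leaf_node_iter()]

    families = []
    f = 0
    attempts = 0
    while len(families) < cfg.n_families and attempts < cfg.n_families * 20:
        attempts += 1
        res = simulate_family(cfg, rng, f"fam{f}", sp_tree)
        if res is None:
            f += 1
            continue
        families.append(res)
        f += 1

    # --- genome layout -----------------------------------------------------
    # ancestral skeleton: per family slot, a spacer and per-gene introns
    n_fam = len(families)
    spacer_lens = rng.integers(cfg.spacer_min, cfg.spacer_max + 1, size=n_fam + 1)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_fam)]
    n_introns = [int(rng.integers(0, cfg.n_introns_max + 1)) for _ in range(n_fam)]
    intron_lens = [
        [int(rng.integers(cfg.intron_min, cfg.intron_max + 1)) for _ in range(k)]
        for k in n_introns
    ]
    # skeleton = concat(spacers) + concat(introns); record offsets
    seg_offsets = []
    total = 0
    for ln in spacer_lens:
        seg_offsets.append((total, total + int(ln)))
        total += int(ln)
    intron_offsets: list[list[tuple[int, int]]] = []
    for lens in intron_lens:
        offs = []
        for ln in lens:
            offs.append((total, total + ln))
            total += ln
        intron_offsets.append(offs)
    ancestral = _random_dna(total, rng)
    skeletons = _evolve_skeleton(sp_tree, ancestral, cfg.mu, rng)

    genomes: dict[str, Genome] = {}
    gene_records: dict[str, list[GeneRecord]] = {sp: [] for sp in species}
    copy_meta: list[dict] = []

    # per-family tandem offsets (species-specific draws happen in tip order,
    # which is deterministic)
    for sp in species:
        skel = skeletons[sp]
        parts: list[str] = []
        pos = 0
        scaffold_name = f"{sp}_scaf1"
        retro_parts: list[str] = []
        retro_pos = 0
        retro_name = f"{sp}_scaf_retro"

        for fi, (root, truth) in enumerate(families):
            s0, s1 = seg_offsets[fi]
            spacer = _arr_to_seq(skel[s0:s1])
            parts.append(spacer)
            pos += len(spacer)
            tips_here = [t for t in root.tips() if t.species == sp]
            # tandem/ancestral copies on the main scaffold, retro copies on
            # the species-specific novel scaffold
            placed_main = [t for t in tips_here if t.mode != "dispersed"]
            placed_retro = [t for t in tips_here if t.mode == "dispersed"]
            for k, tip in enumerate(placed_main):
                if k > 0:
                    gap = int(rng.integers(cfg.tandem_offset_min, cfg.tandem_offset_max + 1))
                    filler = _arr_to_seq(_random_dna(gap, rng))
                    parts.append(filler)
                    pos += gap
                cds = _tip_cds(tip, rng)
                seg, intervals, strand = _gene_segment(
                    cds, skel, intron_offsets[fi], strands[fi], pos
                )
                parts.append(seg)
                rec = GeneRecord(
                    gene_id=tip.gene_id,
                    species=sp,
                    scaffold=scaffold_name,
                    strand=strand,
                    cds_intervals=intervals,
                    cds_seq=cds,
                )
                gene_records[sp].append(rec)
                copy_meta.append(_copy_row(tip, truth, rec))
                pos += len(seg)
            for tip in placed_retro:
                gap = int(rng.integers(55_000, 70_000))
                filler = _arr_to_seq(_random_dna(gap, rng))
                retro_parts.append(filler)
                retro_pos += gap
                cds = _tip_cds(tip, rng)
                start = retro_pos
                retro_parts.append(cds)
                rec = GeneRecord(
                    gene_id=tip.gene_id,
                    species=sp,
                    scaffold=retro_name,
                    strand="+",
                    cds_intervals=[(start, start + len(cds))],
                    cds_seq=cds,
                )
                gene_records[sp].append(rec)
                copy_meta.append(_copy_row(tip, truth, rec))
                retro_pos += len(cds)
        # terminal spacer
        s0, s1 = seg_offsets[n_fam]
        parts.append(_arr_to_seq(skel[s0:s1]))
        scaffolds = [Scaffold(scaffold_name, "".join(parts))]
        if retro_parts:
            retro_parts.append(_arr_to_seq(_random_dna(55_000, rng)))
            scaffolds.append(Scaffold(retro_name, "".join(retro_parts)))
        genomes[sp] = Genome(scaffolds)

    for root, truth in families:
        truth.copies = [r for r in copy_meta if r["family"] == truth.family_id]

    # --- expression & counts ----------------------------------------------
    background = simulate_background_rates(sp_tree, cfg, rng)
    gene_lengths: dict[str, float] = {}
    expected_tpm: dict[tuple[str, str, str], float] = {}
    for root, truth in families:
        fam = truth.family_id
        gene_lengths[fam] = 3.0 * cfg.codon_length
        for sp in species:
            o_sum = t_sum = 0.0
            for tip in root.tips():
                if tip.species != sp:
                    continue
                o, t = tip_tpm(tip)
                o_sum += o
                t_sum += t
            expected_tpm[(fam, sp, "ovary")] = o_sum
            expected_tpm[(fam, sp, "testis")] = t_sum
    for _, r in background.iterrows():
        expected_tpm[(r["gene"], r["species"], "ovary")] = r["ovary_tpm"]
        expected_tpm[(r["gene"], r["species"], "testis")] = r["testis_tpm"]
    bg_lengths = {
        f"bg{i}": float(rng.integers(500, 3001)) for i in range(cfg.n_background_genes)
    }
    gene_lengths.update(bg_lengths)

    gene_ids = [t.family_id for _, t in families] + sorted(
        bg_lengths, key=lambda g: int(g[2:])
    )
    samples = []
    meta_rows = []
    counts = {}
    for sp in species:
        for tissue in ("ovary", "testis"):
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{sp}_{tissue}_r{rep}"
                samples.append(sid)
                meta_rows.append(dict(sample=sid, species=sp, tissue=tissue, replicate=rep))
                tpm = np.array([expected_tpm.get((g, sp, tissue), 0.0) for g in gene_ids])
                lens = np.array([gene_lengths[g] for g in gene_ids])
                share = tpm * lens
                tot = share.sum()
                mean = cfg.library_size * share / tot if tot > 0 else np.zeros_like(share)
                counts[sid] = _nb_draw(mean, cfg.nb_dispersion, rng)
    counts_df = pd.DataFrame(counts, index=gene_ids)
    meta_df = pd.DataFrame(meta_rows).set_index("sample")

    truth_dict = {
        "config": asdict(cfg),
        "families": [_truth_json(t) for _, t in families],
        "background": {
            "heavy_genes": sorted(
                set(background.loc[background["heavy"], "gene"]), key=lambda g: int(g[2:])
            ),
            "sigma2": cfg.bm_sigma2,
            "heavy_factor": cfg.heavy_tail_factor,
        },
        "expected_tpm": {f"{g}|{sp}|{ti}": v for (g, sp, ti), v in expected_tpm.items()},
    }
    return SimCohort(
        cfg=cfg,
        species_tree=sp_tree,
        genomes=genomes,
        gene_records=gene_records,
        counts=counts_df,
        sample_meta=meta_df,
        gene_lengths=gene_lengths,
        truth=truth_dict,
    )


def _tip_cds(tip: GTNode, rng) -> str:
    """Tip CDS string with terminal stop; pseudogenized copies get a premature
    stop mid-sequence."""
    codons = [c for _, c in tip.seq]
    if tip.pseudo and len(codons) > 4:
        codons[len(codons) // 2] = "TAA"
    return "".join(codons) + "TAA"


def _gene_segment(
    cds: str,
    skel: np.ndarray,
    intron_offsets: list[tuple[int, int]],
    strand: str,
    genomic_start: int,
) -> tuple[str, list[tuple[int, int]], str]:
    """Build the genomic segment of a gene (exons interleaved with the
    species' evolved introns) and its CDS intervals in scaffold coordinates."""
    n_ex = len(intron_offsets) + 1
    L = len(cds)
    # split CDS into n_ex exon pieces at codon boundaries
    base = (L // 3) // n_ex
    sizes = [base * 3] * n_ex
    sizes[-1] = L - base * 3 * (n_ex - 1)
    pieces = []
    k = 0
    for s in sizes:
        pieces.append(cds[k : k + s])
        k += s
    introns = [_arr_to_seq(skel[a:b]) for a, b in intron_offsets]
    tx_parts = []
    exon_spans = []  # transcript-orientation offsets within the segment
    off = 0
    for i, ex in enumerate(pieces):
        exon_spans.append((off, off + len(ex)))
        tx_parts.append(ex)
        off += len(ex)
        if i < len(introns):
            tx_parts.append(introns[i])
            off += len(introns[i])
    seg = "".join(tx_parts)
    if strand == "+":
        intervals = [(genomic_start + a, genomic_start + b) for a, b in exon_spans]
        return seg, intervals, "+"
    seg_rc = reverse_complement(seg)
    Lseg = len(seg)
    intervals = [
        (genomic_start + Lseg - b, genomic_start + Lseg - a) for a, b in exon_spans
    ]
    intervals.sort()
    return seg_rc, intervals, "-"


def _copy_row(tip: GTNode, truth: FamilyTruth, rec: GeneRecord) -> dict:
    return dict(
        family=truth.family_id,
        gene_id=tip.gene_id,
        species=tip.species,
        mode=tip.mode,
        pseudogene=tip.pseudo,
        scaffold=rec.scaffold,
        start=rec.span[0],
        end=rec.span[1],
        strand=rec.strand,
        testis_shift=tip.shift,
    )


def _nb_draw(mean: np.ndarray, dispersion: float, rng) -> np.ndarray:
    out = np.zeros(len(mean), dtype=np.int64)
    pos = mean > 0
    if dispersion < 1e-9:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _truth_json(t: FamilyTruth) -> dict:
    d = asdict(t)
    d["expression"] = {k: list(v) for k, v in t.expression.items()}
    d["ortholog_pairs"] = [list(p) for p in t.ortholog_pairs]
    return d


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimCohort, out_dir: str | Path) -> None:
    """Emit the cohort as plain-text files: per-species genome FASTA + GFF3,
    family CDS/protein FASTA, species tree Newick, counts + metadata TSV,
    and the truth ledger as JSON."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "families").mkdir(exist_ok=True)
    for sp, genome in cohort.genomes.items():
        write_fasta(out / "genomes" / f"{sp}.fasta", [(s.name, s.sequence) for s in genome])
        write_gff_genes(out / "annotations" / f"{sp}.gff3", cohort.gene_records[sp])
    by_family: dict[str, list[GeneRecord]] = {}
    for recs in cohort.gene_records.values():
        for r in recs:
            fam = r.gene_id.split("_")[0]
            by_family.setdefault(fam, []).append(r)
    for fam, recs in sorted(by_family.items()):
        write_fasta(out / "families" / f"{fam}.cds.fasta", [(r.gene_id, r.cds_seq) for r in recs])
        write_fasta(
            out / "families" / f"{fam}.prot.fasta",
            [(r.gene_id, r.protein_seq) for r in recs],
        )
    write_newick(out / "species_tree.nwk", cohort.species_tree)
    cohort.counts.to_csv(out / "counts.tsv", sep="\t")
    cohort.sample_meta.to_csv(out / "samples.tsv", sep="\t")
    pd.Series(cohort.gene_lengths, name="length").rename_axis("gene").to_csv(
        out / "gene_lengths.tsv", sep="\t"
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True, default=float)
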