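"""Protein multiple alignment, codon back-threading, neighbor-joining gene
trees with bootstrap, and gene-tree/species-tree reconciliation.

Tree inference here is deliberately distance-based: Poisson-corrected protein
distances and neighbor joining, with classical nonparametric bootstrap
(column resampling) for node support. Reconciliation is standard LCA mapping:
each gene-tree node maps to the species-tree LCA of its descendant species; a
node is a duplication iff it maps to the same species node as one of its
children, and losses are implied by skipped species-tree edges along each
gene-tree branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .io_core import parse_newick, translate

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}

from Bio.Align import substitution_matrices as _subs

_B62M = _subs.load("BLOSUM62")
_S = np.zeros((20, 20))
for _i, _a in enumerate(_AA):
    for _j, _b in enumerate(_AA):
        _S[_i, _j] = _B62M[_a, _b]


@dataclass
class MultipleAlignment:
    """Rows of equal-length aligned sequences over a protein or codon
    alphabet; codon alignments gap in whole-codon units."""

    rows: dict[str, str]
    alphabet: str = "protein"  # or "codon"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.alphabet == "codon" and self.length % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, i: int) -> dict[str, str]:
        return {k: v[i] for k, v in self.rows.items()}


@dataclass
class GeneTree:
    """A rooted gene phylogeny plus the species of each tip."""

    tree: dendropy.Tree
    species_map: dict[str, str]  # gene_id -> species

    def tips(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]


@dataclass
class ReconciliationResult:
    node_events: dict[str, str]  # internal node id -> speciation | duplication
    n_duplications: int
    dup_placements: dict[str, str]  # duplication node id -> species-tree node label
    implied_losses: int
    post_dup_branches: set[tuple[str, str]]  # (parent id, child id)


# ---------------------------------------------------------------------------
# codon back-threading
# ---------------------------------------------------------------------------


def align_codons_from_protein(
    protein_aln: MultipleAlignment, cds: dict[str, str]
) -> MultipleAlignment:
    """Expand a protein alignment into a codon alignment by threading each
    row's CDS through it (one codon per amino-acid column, '---' per gap).

    Each CDS (terminal stop codon stripped if present) must translate exactly
    to its ungapped protein row.
    """
    out: dict[str, str] = {}
    for name, row in protein_aln.rows.items():
        if name not in cds:
            raise ValueError(f"no CDS for alignment row {name!r}")
        seq = cds[name]
        if len(seq) >= 3 and seq[-3:] in {"TAA", "TAG", "TGA"}:
            seq = seq[:-3]
        prot = row.replace("-", "")
        if len(seq) != 3 * len(prot):
            raise ValueError(
                f"{name}: CDS length {len(seq)} does not match {len(prot)} aligned residues"
            )
        if translate(seq) != prot:
            raise ValueError(f"{name}: CDS does not translate to the aligned protein")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        pieces, k = [], 0
        for ch in row:
            if ch == "-":
                pieces.append("---")
            else:
                pieces.append(codons[k])
                k += 1
        out[name] = "".join(pieces)
    return MultipleAlignment(rows=out, alphabet="codon")


# ---------------------------------------------------------------------------
# progressive protein alignment
# ---------------------------------------------------------------------------


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 20) residue frequency profile; gaps contribute nothing."""
    L = len(rows[0])
    prof = np.zeros((L, 20))
    for r in rows:
        for i, ch in enumerate(r):
            j = _AA_INDEX.get(ch)
            if j is not None:
                prof[i, j] += 1
    n = len(rows)
    return prof / n


def _profile_nw(
    rows_a: list[str], rows_b: list[str], gap_open: float = -10.0, gap_extend: float = -1.0
) -> tuple[list[str], list[str]]:
    """Profile-profile Needleman-Wunsch with affine gaps (Gotoh).

    Deterministic tie rule in traceback: match > gap-in-B > gap-in-A.
    Returns the two row groups re-gapped to a common length.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    n, m = pa.shape[0], pb.shape[0]
    # column-column substitution scores
    sub = pa @ _S @ pb.T  # (n, m)

    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + gap_extend * (j - 1)

    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 from M, 1 from Ix, 2 from Iy
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 open (from M), 1 extend
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], Ix[i - 1], Iy[i - 1]
        for j in range(1, m + 1):
            best = Mi1[j - 1]
            arg = 0
            if Xi1[j - 1] > best:
                best, arg = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, arg = Yi1[j - 1], 2
            M[i, j] = best + sub[i - 1, j - 1]
            ptrM[i, j] = arg

            o, e = M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend
            if o >= e:
                Ix[i, j], ptrX[i, j] = o, 0
            else:
                Ix[i, j], ptrX[i, j] = e, 1

            o, e = M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend
            if o >= e:
                Iy[i, j], ptrY[i, j] = o, 0
            else:
                Iy[i, j], ptrY[i, j] = e, 1

    # traceback
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    ops: list[int] = []  # 0 match col, 1 gap-in-B, 2 gap-in-A
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:  # boundary: forced gaps
                state = 1 if j == 0 else 2
                continue
            ops.append(0)
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append(1)
            nxt = 0 if (i == 1 or ptrX[i, j] == 0) else 1
            i -= 1
            state = 0 if nxt == 0 else 1
        else:
            ops.append(2)
            nxt = 0 if (j == 1 or ptrY[i, j] == 0) else 1
            j -= 1
            state = 0 if nxt == 0 else 2
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
        if op in (0, 2):
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += "-"
    return out_a, out_b


def progressive_align(
    proteins: dict[str, str], gap_open: float = -10.0, gap_extend: float = -1.0
) -> MultipleAlignment:
    """Progressive protein alignment: k-mer distance guide tree (average
    linkage), profile-profile Needleman-Wunsch with affine gaps at each merge.

    Deterministic for a given input (ties in the guide clustering are broken
    by insertion order of the sequence names).
    """
    names = list(proteins)
    if any(not proteins[n] for n in names):
        raise ValueError("empty sequence in alignment input")
    if len(names) == 1:
        return MultipleAlignment(rows=dict(proteins))

    # guide clustering on k-mer distances (simple deterministic average linkage)
    clusters: list[tuple[list[str], list[str]]] = [([n], [proteins[n]]) for n in names]
    dist: dict[tuple[int, int], float] = {}
    seqs = {n: proteins[n] for n in names}

    def cdist(a: tuple, b: tuple) -> float:
        tot = 0.0
        for x in a[0]:
            for y in b[0]:
                tot += _kmer_distance(seqs[x], seqs[y])
        return tot / (len(a[0]) * len(b[0]))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        a, b = clusters[i], clusters[j]
        ra, rb = _profile_nw(a[1], b[1], gap_open, gap_extend)
        mergedc = (a[0] + b[0], ra + rb)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [mergedc]

    ids, rows = clusters[0]
    ordered = {n: rows[ids.index(n)] for n in names}
    return MultipleAlignment(rows=ordered)


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

MAX_DISTANCE = 10.0


def poisson_distance_matrix(aln: MultipleAlignment, max_distance: float = MAX_DISTANCE) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected protein distances d = -ln(1 - p), with p the
    mismatch fraction over columns where both rows are ungapped."""
    names = list(aln.rows)
    arrs = {n: np.frombuffer(aln.rows[n].encode(), dtype="S1") for n in names}
    gap = np.frombuffer(b"-", dtype="S1")[0]
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[names[i]], arrs[names[j]]
            ok = (a != gap) & (b != gap)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {names[i]!r} and {names[j]!r}"
                )
            p = float((a[ok] != b[ok]).sum()) / m
            d = max_distance if p >= 1.0 else -np.log(1.0 - p)
            D[i, j] = D[j, i] = min(d, max_distance)
    return D, names


def nj_from_distances(D: np.ndarray, names: list[str]) -> dendropy.Tree:
    """Neighbor joining on a distance matrix; negative branch lengths are
    clamped to zero."""
    dm = DistanceMatrix(D, ids=names)
    sk = _skbio_nj(dm)
    tree = parse_newick(str(sk).strip())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def root_tree(tree: dendropy.Tree, root_on: str | None = None) -> dendropy.Tree:
    """Root on the named outgroup tip (its terminal edge split at the
    midpoint); midpoint rooting when no outgroup is given."""
    if root_on is None:
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.suppress_unifurcations()
        return tree
    leaf = None
    for l in tree.leaf_node_iter():
        if l.taxon.label == root_on:
            leaf = l
            break
    if leaf is None:
        raise ValueError(f"outgroup tip {root_on!r} not in tree")
    el = leaf.edge.length
    if el is None:
        tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    else:
        tree.reroot_at_edge(leaf.edge, length1=el / 2, length2=el / 2, update_bipartitions=False)
    tree.suppress_unifurcations()
    return tree


def root_on_label_set(tree: dendropy.Tree, labels: set[str]) -> bool:
    """Root on the edge separating exactly ``labels`` from the other tips,
    if such an edge exists (lengths split evenly). Returns False when the
    label set is not a clade in any rooting."""
    all_tips = {l.taxon.label for l in tree.leaf_node_iter()}
    labels = set(labels)
    if not labels or labels == all_tips or not labels <= all_tips:
        return False
    if len(labels) == 1:
        root_tree(tree, next(iter(labels)))
        return True
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if side == labels or side == all_tips - labels:
            el = node.edge.length
            if el is None:
                tree.reroot_at_edge(node.edge, update_bipartitions=False)
            else:
                tree.reroot_at_edge(
                    node.edge, length1=el / 2, length2=el / 2, update_bipartitions=False
                )
            tree.suppress_unifurcations()
            return True
    return False


def _splits(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Unrooted bipartitions induced by internal edges, as pairs of tip-label
    sets."""
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_tips - side
        if len(side) > 1 and len(other) > 1:
            out.add(frozenset({side, other}))
    return out


def build_nj_tree(
    aln: MultipleAlignment,
    species_map: dict[str, str] | None = None,
    bootstrap: int = 100,
    root_on: str | None = None,
    root_on_set: set[str] | None = None,
    seed: int = 0,
) -> GeneTree:
    """Neighbor-joining gene tree from a protein alignment.

    Support values (percent of ``bootstrap`` column-resampled replicates
    containing each internal bipartition) are written to internal node
    labels. Rooting is on the ``root_on_set`` clade (e.g. all outgroup-species
    tips) when given and monophyletic, else on the ``root_on`` tip, else
    midpoint (logged by the caller as a warning where that matters).
    """
    if len(aln.rows) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    D, names = poisson_distance_matrix(aln)
    tree = nj_from_distances(D, names)
    if root_on_set and root_on_label_set(tree, root_on_set):
        pass
    else:
        tree = root_tree(tree, root_on)

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        L = aln.length
        cols = {n: np.array(list(aln.rows[n])) for n in names}
        counts: dict[frozenset, int] = {}
        for _ in range(bootstrap):
            idx = rng.integers(0, L, size=L)
            rep = MultipleAlignment(rows={n: "".join(cols[n][idx]) for n in names})
            try:
                Dr, _ = poisson_distance_matrix(rep)
            except ValueError:
                continue
            for sp in _splits(nj_from_distances(Dr, names)):
                counts[sp] = counts.get(sp, 0) + 1
        all_tips = frozenset(names)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            sp = frozenset({side, all_tips - side})
            if len(side) > 1 and len(all_tips - side) > 1:
                node.label = f"{100.0 * counts.get(sp, 0) / bootstrap:.0f}"

    return GeneTree(tree=tree, species_map=dict(species_map or {}))


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------


def node_ids(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    """Stable node identifiers: tip label for leaves, 'n<i>' in preorder for
    internal nodes."""
    ids = {}
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"n{i}"
            i += 1
    return ids


def _species_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))


def reconcile(gene_tree: GeneTree, species_tree: dendropy.Tree) -> ReconciliationResult:
    """LCA-map a gene tree onto the species tree.

    A gene-tree internal node is a duplication iff its species mapping equals
    the mapping of at least one child; implied losses are the species-tree
    edges skipped along each gene-tree branch. ``post_dup_branches`` holds
    every branch in the subtrees rooted at duplication nodes' children
    (including the stems).
    """
    # species-tree bookkeeping
    sp_leaf = {l.taxon.label: l for l in species_tree.leaf_node_iter()}
    depth: dict[dendropy.Node, int] = {}
    for node in species_tree.preorder_node_iter():
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1

    def sp_lca(u: dendropy.Node, v: dendropy.Node) -> dendropy.Node:
        while u is not v:
            if depth[u] >= depth[v]:
                u = u.parent_node
            else:
                v = v.parent_node
        return u

    ids = node_ids(gene_tree.tree)
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    events: dict[str, str] = {}
    dup_nodes: list[dendropy.Node] = []

    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            gid = node.taxon.label
            sp = gene_tree.species_map.get(gid, gid)
            if sp not in sp_leaf:
                raise ValueError(f"tip {gid!r}: species {sp!r} not in species tree")
            mapping[node] = sp_leaf[sp]
        else:
            children = node.child_nodes()
            m = mapping[children[0]]
            for c in children[1:]:
                m = sp_lca(m, mapping[c])
            mapping[node] = m
            if any(mapping[c] is m for c in children):
                events[ids[node]] = "duplication"
                dup_nodes.append(node)
            else:
                events[ids[node]] = "speciation"

    losses = 0
    for node in gene_tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        mu, mv = mapping[node.parent_node], mapping[node]
        d = depth[mv] - depth[mu]
        if events[ids[node.parent_node]] == "duplication":
            losses += d
        else:
            losses += d - 1

    post_dup: set[tuple[str, str]] = set()
    for dn in dup_nodes:
        for sub in dn.preorder_iter():
            for c in sub.child_nodes():
                post_dup.add((ids[sub], ids[c]))

    return ReconciliationResult(
        node_events=events,
        n_duplications=len(dup_nodes),
        dup_placements={ids[n]: _species_label(mapping[n]) for n in dup_nodes},
        implied_losses=losses,
        post_dup_branches=post_dup,
    )
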