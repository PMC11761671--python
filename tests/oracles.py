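"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from first principles (exhaustive
enumeration, closed forms, or dense linear algebra) without touching the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# random tree generation
# ---------------------------------------------------------------------------


def random_rooted_tree(labels: list[str], rng, min_bl=0.1, max_bl=1.0) -> str:
    """Random rooted binary topology with uniform random branch lengths,
    as a Newick string."""
    nodes = [f"{l}:{rng.uniform(min_bl, max_bl):.4f}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.uniform(min_bl, max_bl):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0].rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# reconciliation oracle: exhaustive mapping search
# ---------------------------------------------------------------------------


def reconciliation_oracle(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                          species_of: dict[str, str]) -> tuple[int, int]:
    """Minimum (duplications, losses) over all consistent mappings of gene
    internal nodes to species nodes. A mapping is consistent when every node
    maps to an ancestor-or-self of each child's mapping. Events: a node is a
    duplication iff some child maps to the same species node; each branch
    contributes (depth difference) losses, minus one when the parent is a
    speciation. Returns the lexicographic minimum of (dups + losses, dups)."""
    sp_nodes = list(species_tree.preorder_node_iter())
    parent = {n: n.parent_node for n in sp_nodes}
    depth = {}
    for n in sp_nodes:
        depth[n] = 0 if parent[n] is None else depth[parent[n]] + 1

    def ancestors_or_self(n):
        out = []
        while n is not None:
            out.append(n)
            n = parent[n]
        return out

    def is_anc_or_self(a, b):  # a ancestor-or-self of b
        while b is not None:
            if a is b:
                return True
            b = parent[b]
        return False

    sp_leaf = {l.taxon.label: l for l in species_tree.leaf_node_iter()}
    g_nodes = list(gene_tree.postorder_node_iter())
    internals = [n for n in g_nodes if not n.is_leaf()]
    fixed = {}
    for n in g_nodes:
        if n.is_leaf():
            fixed[n] = sp_leaf[species_of[n.taxon.label]]

    # candidate species nodes per internal node: ancestors-or-self of the LCA
    # of its descendant species (anything lower cannot dominate the children)
    def lca(a, b):
        x, y = a, b
        while x is not y:
            if depth[x] >= depth[y]:
                x = parent[x]
            else:
                y = parent[y]
        return x

    tip_lca = {}
    for n in g_nodes:
        if n.is_leaf():
            tip_lca[n] = fixed[n]
        else:
            m = None
            for c in n.child_nodes():
                m = tip_lca[c] if m is None else lca(m, tip_lca[c])
            tip_lca[n] = m
    candidates = {n: ancestors_or_self(tip_lca[n]) for n in internals}

    best = None
    for combo in itertools.product(*(candidates[n] for n in internals)):
        M = dict(fixed)
        M.update(dict(zip(internals, combo)))
        ok = True
        for n in internals:
            for c in n.child_nodes():
                if not is_anc_or_self(M[n], M[c]):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        dups = losses = 0
        events = {}
        for n in internals:
            # speciation at M(n) requires the children to map into distinct
            # child subtrees of M(n); anything else is a duplication
            subtrees = []
            for c in n.child_nodes():
                if M[c] is M[n]:
                    subtrees.append(None)
                else:
                    x = M[c]
                    while parent[x] is not M[n]:
                        x = parent[x]
                    subtrees.append(x)
            distinct = (
                len(subtrees) == len(set(id(s) for s in subtrees)) and None not in subtrees
            )
            events[n] = "spec" if distinct else "dup"
            if events[n] == "dup":
                dups += 1
        for n in g_nodes:
            if n.parent_node is None:
                continue
            d = depth[M[n]] - depth[M[n.parent_node]]
            losses += d if events[n.parent_node] == "dup" else d - 1
        key = (dups + losses, dups)
        if best is None or key < best:
            best = key
    total, dups = best
    return dups, total - dups


# ---------------------------------------------------------------------------
# Fitch parsimony oracle: exhaustive ancestor assignment
# ---------------------------------------------------------------------------


def fitch_score_oracle(tree: dendropy.Tree, tip_states: dict[str, str]) -> int:
    """Minimum number of changes per column, minimized by brute force over
    all internal-node state assignments, summed across columns."""
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.postorder_node_iter() if n.is_leaf()]
    L = len(next(iter(tip_states.values())))
    bases = "ACGT"
    total = 0
    for col in range(L):
        best = None
        leaf_state = {n: tip_states[n.taxon.label][col] for n in leaves}
        missing = {n for n, s in leaf_state.items() if s not in bases}
        for combo in itertools.product(bases, repeat=len(internals)):
            assign = dict(zip(internals, combo))
            changes = 0
            for n in internals:
                for c in n.child_nodes():
                    if c.is_leaf():
                        if c in missing:
                            continue
                        if leaf_state[c] != assign[n]:
                            changes += 1
                    elif assign[c] != assign[n]:
                        changes += 1
            if best is None or changes < best:
                best = changes
        total += best
    return total


# ---------------------------------------------------------------------------
# exact one-sided Wilcoxon rank-sum by enumeration
# ---------------------------------------------------------------------------


def wilcoxon_exact_oracle(x: list[float], y: list[float]) -> float:
    """P(rank sum of a random |x|-subset >= observed rank sum of x) over all
    rank splits of the pooled sample (alternative: x > y). Assumes no ties."""
    pooled = sorted(x + y)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(rank[v] for v in x)
    n = len(x)
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        total += 1
        if sum(combo) >= obs:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# BM ancestral states by dense GLS
# ---------------------------------------------------------------------------


def bm_gls_oracle(tree: dendropy.Tree, tip_values: dict[str, float]) -> dict[str, float]:
    """ML ancestral states under Brownian motion from the full covariance
    matrix: cov(i, j) = shared root-path length. Returns estimates keyed the
    same way as the pruning implementation (tip label, or 'n<i>' preorder)."""
    depth = {}
    for n in tree.preorder_node_iter():
        depth[n] = (0.0 if n.parent_node is None else depth[n.parent_node]) + (
            n.edge.length or 0.0
        )

    def depth_of(n):
        d = 0.0
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        return d

    def mrca_depth(a, b):
        anc = set()
        x = a
        while x is not None:
            anc.add(x)
            x = x.parent_node
        y = b
        while y not in anc:
            y = y.parent_node
        return depth_of(y)

    tips = [n for n in tree.leaf_node_iter()]
    labels = [n.taxon.label for n in tips]
    C = np.array([[mrca_depth(a, b) for b in tips] for a in tips])
    for i, t in enumerate(tips):
        C[i, i] = depth_of(t)
    y = np.array([tip_values[l] for l in labels])
    one = np.ones(len(tips))
    Ci = np.linalg.inv(C)
    root = float(one @ Ci @ y / (one @ Ci @ one))

    out = {}
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            out[node.taxon.label] = tip_values[node.taxon.label]
            continue
        name = f"n{i}"
        i += 1
        cv = np.array([mrca_depth(node, t) for t in tips])
        out[name] = float(root + cv @ Ci @ (y - root * one))
    return out


def brown_forsythe_oracle(groups: list[list[float]]) -> tuple[float, float]:
    """Brown-Forsythe statistic straight from the formula: one-way ANOVA F on
    absolute deviations from group medians."""
    from scipy.stats import f as fdist

    z = [np.abs(np.asarray(g) - np.median(g)) for g in groups]
    k = len(z)
    n = sum(len(g) for g in z)
    grand = np.concatenate(z).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in z)
    stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(fdist.sf(stat, k - 1, n - k))
    return float(stat), p
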