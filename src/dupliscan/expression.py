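"""Expression-evolution analysis: TPM normalization, tissue-bias calls,
variance testing across species, Brownian-motion ancestral reconstruction of
log expression, branch-specific regulatory rates, and percentile placement
against a genome-wide background gene set.

The regulatory-evolution rate of a gene is computed by reconstructing the
maximum-likelihood ancestral log-expression values under Brownian motion on
the species tree, taking one delta per branch (child value minus parent
value), and summarizing the gene by the standard deviation of those deltas.
A gene's rate is then placed as a percentile within the distribution of the
same statistic over a large background gene set.

Log transform convention: ln(TPM + 1); replicates are averaged on the TPM
scale before the log. Species without expression data are pruned from the
tree per gene rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CountMatrix

MIN_EXPRESSED_TPM = 1.0
_EPS_BRANCH = 1e-8


@dataclass
class TissueProfile:
    gene_id: str
    species: str
    ovary_tpm: float
    testis_tpm: float
    bias: str  # ovary | testis | unexpressed
    tie: bool = False


@dataclass
class AncestralStateResult:
    """ML ancestral trait values under Brownian motion."""

    node_values: dict[str, float]  # node id -> estimated log-TPM
    sigma2: float  # ML rate (contrast sum / n tips)
    sigma2_unbiased: float  # contrast sum / (n tips - 1)
    root_id: str


@dataclass
class RegEvolRecord:
    gene_id: str
    tissue: str
    branch_deltas: dict[tuple[str, str], float]
    rate_sd: float
    percentile: float = math.nan


def log_tpm(x, base: str = "ln", pseudocount: float = 1.0):
    arr = np.log(np.asarray(x, dtype=float) + pseudocount)
    if base == "log2":
        arr = arr / math.log(2)
    return arr


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------


def counts_to_tpm(counts: CountMatrix | pd.DataFrame, gene_lengths: dict[str, float]) -> pd.DataFrame:
    """Length-normalize read counts to transcripts per million.

    Per sample: rate_g = count_g / length_g(kb); TPM_g = 1e6 * rate_g / sum(rate).
    Every column of the result sums to 1e6. An all-zero sample is an error.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lengths = pd.Series({g: gene_lengths[g] for g in df.index}, dtype=float)
    if (lengths < 1).any():
        raise ValueError("gene length < 1 bp")
    rate = df.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    empty = colsum[colsum == 0]
    if len(empty):
        raise ValueError(f"empty library: {list(empty.index)}")
    return rate.div(colsum, axis=1) * 1e6


# ---------------------------------------------------------------------------
# tissue bias
# ---------------------------------------------------------------------------


def classify_bias(
    ovary_tpm: float, testis_tpm: float, min_expressed_tpm: float = MIN_EXPRESSED_TPM
) -> tuple[str, bool]:
    """(bias, tie_flag) for replicate-averaged per-tissue TPM.

    Unexpressed when both tissues fall below ``min_expressed_tpm``; otherwise
    the more-expressed tissue wins, exact ties going to ovary (listed-first
    convention, flagged)."""
    if max(ovary_tpm, testis_tpm) < min_expressed_tpm:
        return "unexpressed", False
    if testis_tpm > ovary_tpm:
        return "testis", False
    return "ovary", testis_tpm == ovary_tpm


def tissue_profiles(
    tpm: pd.DataFrame, sample_meta: pd.DataFrame, min_expressed_tpm: float = MIN_EXPRESSED_TPM
) -> list[TissueProfile]:
    """Replicate-averaged per-(gene, species) tissue profile and bias call."""
    out: list[TissueProfile] = []
    for species, meta_sp in sample_meta.groupby("species", sort=True):
        means = {}
        for tissue in ("ovary", "testis"):
            cols = meta_sp.index[meta_sp["tissue"] == tissue]
            cols = [c for c in cols if c in tpm.columns]
            means[tissue] = tpm[cols].mean(axis=1) if cols else None
        if means["ovary"] is None or means["testis"] is None:
            continue
        for gene in tpm.index:
            o, t = float(means["ovary"][gene]), float(means["testis"][gene])
            bias, tie = classify_bias(o, t, min_expressed_tpm)
            out.append(TissueProfile(gene, str(species), o, t, bias, tie))
    return out


# ---------------------------------------------------------------------------
# variance test
# ---------------------------------------------------------------------------


def brown_forsythe(groups: list[np.ndarray | list[float]]) -> tuple[float, float]:
    """Brown-Forsythe test of equal variance: one-way ANOVA F on absolute
    deviations from group medians."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("degenerate: zero spread in every group")
    stat, p = stats.levene(*arrays, center="median")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------


def _prune_to_tips(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(keep))
    t.suppress_unifurcations()
    return t


def _bm_node_ids(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    from .genetree import node_ids

    return node_ids(tree)


def bm_ancestral_states(
    tree: dendropy.Tree, tip_values: dict[str, float]
) -> AncestralStateResult:
    """ML ancestral states of a continuous trait under Brownian motion.

    Two-pass message passing (equivalent to the GLS solution with the BM
    covariance matrix): a rootward pass combines each subtree into a
    (mean, variance) message; a tipward pass sends the complement message
    down so every internal node's estimate uses all tips. Species in the tree
    without a value are pruned; zero-length branches are replaced by a tiny
    epsilon. sigma2 is the ML rate from the phylogenetically independent
    contrasts.
    """
    tips_with_values = {l.taxon.label for l in tree.leaf_node_iter()} & set(tip_values)
    if len(tips_with_values) < 2:
        raise ValueError("need >= 2 tips with trait values")
    work = _prune_to_tips(tree, tips_with_values)
    for edge in work.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length is None or edge.length <= 0):
            edge.length = _EPS_BRANCH

    ids = _bm_node_ids(work)
    post = list(work.postorder_node_iter())
    pre = list(work.preorder_node_iter())

    # rootward pass: down[v] = (mean, var) of the trait at v given v's subtree
    down: dict[dendropy.Node, tuple[float, float]] = {}
    contrasts: list[tuple[float, float]] = []
    for node in post:
        if node.is_leaf():
            down[node] = (tip_values[node.taxon.label], 0.0)
        else:
            msgs = [
                (down[c][0], down[c][1] + c.edge.length) for c in node.child_nodes()
            ]
            for (m1, v1), (m2, v2) in zip(msgs, msgs[1:]):
                contrasts.append((m1 - m2, v1 + v2))
            w = [1.0 / v for _, v in msgs]
            mean = sum(wi * mi for wi, (mi, _) in zip(w, msgs)) / sum(w)
            down[node] = (mean, 1.0 / sum(w))

    # tipward pass: up[v] = (mean, var) of the trait at v given everything
    # outside v's subtree
    up: dict[dendropy.Node, tuple[float, float] | None] = {work.seed_node: None}
    for node in pre:
        for child in node.child_nodes():
            msgs = []
            if up[node] is not None:
                msgs.append(up[node])
            for sib in node.child_nodes():
                if sib is not child:
                    msgs.append((down[sib][0], down[sib][1] + sib.edge.length))
            if not msgs:
                up[child] = None
                continue
            w = [1.0 / v if v > 0 else 1.0 / _EPS_BRANCH for _, v in msgs]
            mean = sum(wi * mi for wi, (mi, _) in zip(w, msgs)) / sum(w)
            var = 1.0 / sum(w)
            up[child] = (mean, var + child.edge.length)

    node_values: dict[str, float] = {}
    for node in pre:
        msgs = []
        if node.is_leaf():
            node_values[ids[node]] = tip_values[node.taxon.label]
            continue
        if up[node] is not None:
            msgs.append(up[node])
        for c in node.child_nodes():
            msgs.append((down[c][0], down[c][1] + c.edge.length))
        w = [1.0 / v if v > 0 else 1.0 / _EPS_BRANCH for _, v in msgs]
        node_values[ids[node]] = sum(wi * mi for wi, (mi, _) in zip(w, msgs)) / sum(w)

    n = len(tips_with_values)
    rss = sum(c * c / v for c, v in contrasts)
    result = AncestralStateResult(
        node_values=node_values,
        sigma2=rss / n if contrasts else 0.0,
        sigma2_unbiased=rss / (n - 1) if contrasts else 0.0,
        root_id=ids[work.seed_node],
    )
    result._tree = work  # retained so branch deltas can reuse the pruned tree
    result._ids = ids
    return result


def branch_reg_rates(
    asr: AncestralStateResult,
    gene_id: str = "",
    tissue: str = "",
    normalize_by_length: bool = False,
) -> RegEvolRecord:
    """One regulatory delta per branch (child minus parent on the log scale)
    and their standard deviation (ddof=1). ``normalize_by_length`` divides
    each delta by its branch length before the SD."""
    tree = asr._tree
    ids = asr._ids
    deltas: dict[tuple[str, str], float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        d = asr.node_values[ids[node]] - asr.node_values[ids[node.parent_node]]
        if normalize_by_length:
            d /= node.edge.length
        deltas[(ids[node.parent_node], ids[node])] = d
    if len(deltas) < 2:
        raise ValueError("rate SD undefined with fewer than 2 branches")
    sd = float(np.std(list(deltas.values()), ddof=1))
    return RegEvolRecord(gene_id=gene_id, tissue=tissue, branch_deltas=deltas, rate_sd=sd)


def percentile_vs_background(focal_rate_sd: float, background: list[float]) -> float:
    """Percentile of a focal rate SD within a background distribution:
    100 x (strictly below + half of ties) / n. A background smaller than 100
    genes is allowed but warned about by callers."""
    if not background:
        raise ValueError("empty background")
    arr = np.asarray(background, dtype=float)
    below = float((arr < focal_rate_sd).sum())
    ties = float((arr == focal_rate_sd).sum())
    return 100.0 * (below + 0.5 * ties) / len(arr)
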