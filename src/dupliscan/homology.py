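"""Local-alignment HSP generation, the coverage x identity homology statistic,
and tiered reciprocal-best-hit (RBH) ortholog/paralog calling.

The aligner is a deterministic seed-and-extend local aligner: exact k-mer
seeds grouped by diagonal, X-drop ungapped extension, then a greedy collinear
chaining step that plays the role of banded gapped extension. There is no
E-value model; filtering is by raw score and alignment length
(``min_hsp_score`` / ``min_hsp_len`` act as the significance surrogate).

The homology statistic between two genes is

    sum over retained HSPs of (query coverage % of the HSP) x (identity),

with query coverage intervals merged greedily in descending score order so no
query base is counted twice, capped at 100.

Ortholog calling is tiered: CDS nucleotide first; genes with no hit escalate
to protein vs protein; genes still without a hit can be searched against a
six-frame translation of the other species' scaffolds. Two genes are RBH
orthologs iff each is the other's best hit at the tier where both directions
have hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io_core import GeneRecord, Genome, translate

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62: dict[tuple[str, str], int] = {}
for _a in _BLOSUM62.alphabet:
    for _b in _BLOSUM62.alphabet:
        _B62[(_a, _b)] = int(_BLOSUM62[_a, _b])

TIERS = ("cds_nucleotide", "protein", "translated_genome")


@dataclass(frozen=True)
class AlignParams:
    """Scoring configuration for the seed-and-extend aligner."""

    alphabet: str = "nt"  # "nt" or "aa"
    k: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: int = 20
    min_hsp_score: float = 40.0
    min_hsp_len: int = 20
    max_chain_gap: int = 60
    max_seed_hits: int = 500  # repeat guard: k-mers more frequent than this are skipped

    @staticmethod
    def nucleotide(**kw) -> "AlignParams":
        return AlignParams(**kw)

    @staticmethod
    def protein(**kw) -> "AlignParams":
        defaults = dict(
            alphabet="aa", k=4, xdrop=25, min_hsp_score=40.0, min_hsp_len=12, max_chain_gap=30
        )
        defaults.update(kw)
        return AlignParams(**defaults)

    def score_pair(self, a: str, b: str) -> int:
        if self.alphabet == "nt":
            if a == "N" or b == "N":
                return self.mismatch
            return self.match if a == b else self.mismatch
        return _B62.get((a, b), -4)


@dataclass
class Hsp:
    """One local alignment segment (high-scoring segment pair)."""

    query_id: str
    subject_id: str
    q_interval: tuple[int, int]  # 0-based half-open on the query
    s_interval: tuple[int, int]
    matches: int
    aln_len: int
    score: float
    gaps: int = 0

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError("HSP with aln_len < 1")
        if not (0 <= self.matches <= self.aln_len):
            raise ValueError("matches outside [0, aln_len]")

    @property
    def identity_frac(self) -> float:
        return self.matches / self.aln_len


@dataclass
class HomologyScore:
    query_id: str
    subject_id: str
    pct_blast_identity: float
    n_hsps: int
    tier: str
    total_score: float = 0.0


@dataclass
class HomologCall:
    gene_a: str
    gene_b: str
    relation: str  # rbh_ortholog | one_way_hit | none
    tier: str
    forward_score: HomologyScore | None = None
    reverse_score: HomologyScore | None = None


# ---------------------------------------------------------------------------
# seed-and-extend local alignment
# ---------------------------------------------------------------------------

_AMBIG = {"nt": "N", "aa": "X*"}


import functools


def _build_kmer_index(seq: str, k: int, ambig: str) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    clean = not any(c in seq for c in ambig)
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if not clean and any(c in ambig for c in w):
            continue
        index.setdefault(w, []).append(i)
    return index


_cached_kmer_index = functools.lru_cache(maxsize=1024)(_build_kmer_index)


def _kmer_index(seq: str, k: int, ambig: str) -> dict[str, list[int]]:
    # gene-scale subjects recur across many queries (all-vs-all RBH), so they
    # are cached; long genomic regions are not, to bound memory
    if len(seq) <= 20_000:
        return _cached_kmer_index(seq, k, ambig)
    return _build_kmer_index(seq, k, ambig)


def _extend_ungapped(
    query: str, subject: str, q0: int, s0: int, k: int, p: AlignParams
) -> tuple[int, int, int, int, float]:
    """X-drop ungapped extension around an exact k-mer seed at (q0, s0).

    Returns (q_start, q_end, s_start, s_end, score) of the maximal-scoring
    ungapped segment through the seed, trimmed to its best endpoints.
    """
    # seed itself (exact match)
    seed_score = sum(p.score_pair(c, c) for c in query[q0 : q0 + k])

    # rightward from q0+k
    best_r, run, br_i = 0.0, 0.0, 0
    i = 0
    qn, sn = len(query), len(subject)
    while q0 + k + i < qn and s0 + k + i < sn:
        run += p.score_pair(query[q0 + k + i], subject[s0 + k + i])
        if run > best_r:
            best_r, br_i = run, i + 1
        if run < best_r - p.xdrop:
            break
        i += 1

    # leftward from q0-1
    best_l, run, bl_i = 0.0, 0.0, 0
    i = 1
    while q0 - i >= 0 and s0 - i >= 0:
        run += p.score_pair(query[q0 - i], subject[s0 - i])
        if run > best_l:
            best_l, bl_i = run, i
        if run < best_l - p.xdrop:
            break
        i += 1

    q_start, q_end = q0 - bl_i, q0 + k + br_i
    return q_start, q_end, q_start - (q0 - s0), q_end - (q0 - s0), seed_score + best_l + best_r


@dataclass
class _Seg:
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    aln_len: int
    score: float
    gaps: int = 0


def _count_matches(query: str, subject: str, q_start: int, q_end: int, s_start: int) -> int:
    return sum(
        1 for i in range(q_end - q_start) if query[q_start + i] == subject[s_start + i]
    )


def _chain_segments(segs: list[_Seg], p: AlignParams) -> list[_Seg]:
    """Greedy collinear chaining: merge segment pairs on nearby diagonals when
    bridging them (gap penalties plus assumed-mismatch cost) still improves
    the score. Plays the role of banded gapped extension."""
    segs = sorted(segs, key=lambda s: (s.q_start, s.s_start))
    merged = True
    while merged:
        merged = False
        out: list[_Seg] = []
        i = 0
        while i < len(segs):
            a = segs[i]
            j = i + 1
            fused = False
            while j < len(segs):
                b = segs[j]
                qgap = b.q_start - a.q_end
                sgap = b.s_start - a.s_end
                if qgap > p.max_chain_gap:
                    break
                if sgap < -p.k or qgap < -p.k or sgap > p.max_chain_gap:
                    j += 1
                    continue
                # trim small overlaps off the front of b
                trim = max(-qgap, -sgap, 0)
                qgap_t, sgap_t = qgap + trim, sgap + trim
                b_score = b.score - trim * p.match
                b_matches = max(b.matches - trim, 0)
                indel = abs(qgap_t - sgap_t)
                thru = min(qgap_t, sgap_t)
                penalty = (p.gap_open + p.gap_extend * (indel - 1)) if indel else 0
                penalty += p.mismatch * thru if p.alphabet == "nt" else -1 * thru
                cand = a.score + b_score + penalty
                if cand > max(a.score, b.score):
                    a = _Seg(
                        q_start=a.q_start,
                        q_end=b.q_end,
                        s_start=a.s_start,
                        s_end=b.s_end,
                        matches=a.matches + b_matches,
                        aln_len=a.aln_len + (b.aln_len - trim) + max(qgap_t, sgap_t),
                        score=cand,
                        gaps=a.gaps + b.gaps + indel,
                    )
                    segs.pop(j)
                    fused = merged = True
                else:
                    j += 1
            out.append(a)
            i += 1
        segs = sorted(out, key=lambda s: (s.q_start, s.s_start))
    return segs


def local_align(
    query: str,
    subject: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[Hsp]:
    """Find local alignments (HSPs) between two sequences.

    Deterministic: exact k-mer seeds, per-diagonal X-drop ungapped extension
    with coverage skipping, then greedy collinear chaining. HSPs below
    ``min_hsp_score`` or shorter than ``min_hsp_len`` are dropped; results are
    sorted by score descending (ties by query then subject start).
    """
    p = params or AlignParams()
    if len(query) < p.k or len(subject) < p.k:
        return []
    ambig = _AMBIG[p.alphabet]
    index = _kmer_index(subject, p.k, ambig)
    q_clean = not any(c in query for c in ambig)

    diagonals: dict[int, list[int]] = {}
    for q in range(len(query) - p.k + 1):
        w = query[q : q + p.k]
        hits = index.get(w)
        if not hits or len(hits) > p.max_seed_hits:
            continue
        if not q_clean and any(c in ambig for c in w):
            continue
        for s in hits:
            diagonals.setdefault(q - s, []).append(q)

    segs: list[_Seg] = []
    for d in sorted(diagonals):
        covered_end = -1
        for q in sorted(diagonals[d]):
            if q < covered_end:
                continue
            qs, qe, ss, se, score = _extend_ungapped(query, subject, q, q - d, p.k, p)
            covered_end = qe
            if score <= 0:
                continue
            matches = _count_matches(query, subject, qs, qe, ss)
            segs.append(_Seg(qs, qe, ss, se, matches, qe - qs, score))

    segs = _chain_segments(segs, p)
    hsps = [
        Hsp(
            query_id=query_id,
            subject_id=subject_id,
            q_interval=(s.q_start, s.q_end),
            s_interval=(s.s_start, s.s_end),
            matches=s.matches,
            aln_len=s.aln_len,
            score=s.score,
            gaps=s.gaps,
        )
        for s in segs
        if s.score >= p.min_hsp_score and s.aln_len >= p.min_hsp_len
    ]
    hsps.sort(key=lambda h: (-h.score, h.q_interval[0], h.s_interval[0]))
    return hsps


# ---------------------------------------------------------------------------
# the homology statistic
# ---------------------------------------------------------------------------


def percent_blast_identity(
    query: GeneRecord | int,
    hsps: Sequence[Hsp],
    tier: str = "cds_nucleotide",
) -> HomologyScore:
    """Sum of per-HSP (query coverage % x identity), HSPs taken in descending
    score order with already-covered query bases excluded, capped at 100.

    ``query`` is a GeneRecord (CDS length used for the nucleotide tier,
    protein length otherwise) or an explicit query length.
    """
    if isinstance(query, GeneRecord):
        qlen = len(query.cds_seq) if tier == "cds_nucleotide" else len(query.protein_seq)
        qid = query.gene_id
    else:
        qlen, qid = int(query), "query"
    if qlen < 1:
        raise ValueError("query length < 1")
    sid = hsps[0].subject_id if hsps else ""
    for h in hsps:
        if h.q_interval[1] > qlen:
            raise ValueError(
                f"HSP interval {h.q_interval} exceeds query length {qlen} for {h.query_id}"
            )

    covered: list[tuple[int, int]] = []
    total = 0.0
    score_sum = 0.0
    for h in sorted(hsps, key=lambda h: (-h.score, h.q_interval[0])):
        new_len = _uncovered_length(h.q_interval, covered)
        total += 100.0 * new_len / qlen * h.identity_frac
        covered = _merge_interval(covered, h.q_interval)
        score_sum += h.score
    return HomologyScore(
        query_id=qid,
        subject_id=sid,
        pct_blast_identity=min(total, 100.0),
        n_hsps=len(hsps),
        tier=tier,
        total_score=score_sum,
    )


def _uncovered_length(iv: tuple[int, int], covered: list[tuple[int, int]]) -> int:
    s, e = iv
    length = e - s
    for cs, ce in covered:
        lo, hi = max(s, cs), min(e, ce)
        if hi > lo:
            length -= hi - lo
    return max(length, 0)


def _merge_interval(covered: list[tuple[int, int]], iv: tuple[int, int]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    s, e = iv
    for cs, ce in covered:
        if ce < s or cs > e:
            out.append((cs, ce))
        else:
            s, e = min(s, cs), max(e, ce)
    out.append((s, e))
    out.sort()
    return out


def merged_covered_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    total, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# tiered reciprocal-best-hit calling
# ---------------------------------------------------------------------------


def _score_one(
    qrec: GeneRecord, srec: GeneRecord, tier: str, nt: AlignParams, aa: AlignParams
) -> HomologyScore:
    if tier == "cds_nucleotide":
        hsps = local_align(qrec.cds_seq, srec.cds_seq, nt, qrec.gene_id, srec.gene_id)
    else:
        hsps = local_align(qrec.protein_seq, srec.protein_seq, aa, qrec.gene_id, srec.gene_id)
    sc = percent_blast_identity(qrec, hsps, tier)
    sc.subject_id = srec.gene_id
    return sc


def _best_hits(
    queries: Sequence[GeneRecord],
    subjects: Sequence[GeneRecord],
    tier: str,
    nt: AlignParams,
    aa: AlignParams,
) -> dict[str, HomologyScore]:
    """Best subject per query at one tier; queries with no HSPs are absent."""
    best: dict[str, HomologyScore] = {}
    for q in queries:
        cand: HomologyScore | None = None
        for s in subjects:
            sc = _score_one(q, s, tier, nt, aa)
            if sc.n_hsps == 0:
                continue
            if cand is None or (
                (-sc.pct_blast_identity, -sc.total_score, sc.subject_id)
                < (-cand.pct_blast_identity, -cand.total_score, cand.subject_id)
            ):
                cand = sc
        if cand is not None:
            best[q.gene_id] = cand
    return best


def six_frame_translations(scaffold_seq: str) -> list[tuple[str, str]]:
    """Translate a scaffold in all six frames; internal stops are kept as
    ``*`` (seeds never span them, and extension scores across them collapse),
    so each frame is effectively searched as stop-delimited segments."""
    from .io_core import reverse_complement

    frames = []
    for strand, seq in (("+", scaffold_seq), ("-", reverse_complement(scaffold_seq))):
        for off in range(3):
            frames.append((f"{strand}{off}", translate(seq[off:])))
    return frames


def genome_search(
    qrec: GeneRecord, genome: Genome, aa: AlignParams
) -> tuple[str, list[Hsp]] | None:
    """Tier-3: search a protein against six-frame scaffold translations.

    Returns (scaffold_name, HSPs in protein coordinates of the best-scoring
    scaffold/frame) or None.
    """
    best: tuple[float, str, list[Hsp]] | None = None
    for scaffold in genome:
        for frame, prot in six_frame_translations(scaffold.sequence):
            hsps = local_align(
                qrec.protein_seq, prot, aa, qrec.gene_id, f"{scaffold.name}:{frame}"
            )
            if not hsps:
                continue
            total = sum(h.score for h in hsps)
            if best is None or total > best[0]:
                best = (total, scaffold.name, hsps)
    if best is None:
        return None
    return best[1], best[2]


def _tiered_best(
    queries: Sequence[GeneRecord],
    subjects: Sequence[GeneRecord],
    nt: AlignParams,
    aa: AlignParams,
    escalate_below_pct: float,
) -> tuple[dict[str, HomologyScore], dict[str, str], list[GeneRecord]]:
    """Best hit per query with tier escalation.

    A query escalates from the nucleotide to the protein tier when its best
    hit is absent or scores below ``escalate_below_pct`` (the aligner has no
    E-value model, so chance-level fragment hits must not mask a gene as
    'found'); a sub-threshold hit is kept as a fallback if the next tier
    finds nothing. Returns (best hit, tier per gene, genes with no hit at
    any sequence tier).
    """
    best: dict[str, HomologyScore] = {}
    tier_of: dict[str, str] = {}
    weak: dict[str, tuple[HomologyScore, str]] = {}
    pending = list(queries)
    for tier in ("cds_nucleotide", "protein"):
        if not pending:
            break
        found = _best_hits(pending, subjects, tier, nt, aa)
        nxt = []
        for g in pending:
            sc = found.get(g.gene_id)
            if sc is None:
                nxt.append(g)
            elif sc.pct_blast_identity < escalate_below_pct and tier != "protein":
                weak[g.gene_id] = (sc, tier)
                nxt.append(g)
            else:
                best[g.gene_id], tier_of[g.gene_id] = sc, tier
        pending = nxt
    for gid, (sc, tier) in weak.items():
        if gid not in best:
            best[gid], tier_of[gid] = sc, tier
    unmatched = [g for g in pending if g.gene_id not in best]
    return best, tier_of, unmatched


def call_rbh(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    nt_params: AlignParams | None = None,
    aa_params: AlignParams | None = None,
    genome_b: Genome | None = None,
    genome_a: Genome | None = None,
    escalate_below_pct: float = 5.0,
) -> list[HomologCall]:
    """Tiered reciprocal-best-hit calling between two species' gene sets.

    Tier 1 compares CDS nucleotide sequences; genes whose best tier-1 hit is
    absent or below the chance-level floor escalate to protein-vs-protein;
    genes still without a hit are searched against the other species'
    six-frame-translated scaffolds when genomes are supplied (a one-way
    genomic hit, reported against the overlapping annotated gene if there is
    one, else against the scaffold).
    """
    if not genes_a or not genes_b:
        raise ValueError("empty gene set")
    nt = nt_params or AlignParams.nucleotide()
    aa = aa_params or AlignParams.protein()

    best_a, tier_a, remaining_a = _tiered_best(genes_a, genes_b, nt, aa, escalate_below_pct)
    best_b, tier_b, remaining_b = _tiered_best(genes_b, genes_a, nt, aa, escalate_below_pct)
    tier_of = {**tier_a, **tier_b}

    calls: list[HomologCall] = []
    b_by_id = {g.gene_id: g for g in genes_b}
    a_by_id = {g.gene_id: g for g in genes_a}

    seen: set[tuple[str, str]] = set()
    for gid, fwd in best_a.items():
        sid = fwd.subject_id
        rev = best_b.get(sid)
        tier = tier_of[gid]
        if rev is not None and rev.subject_id == gid:
            relation = "rbh_ortholog"
        else:
            relation = "one_way_hit"
            rev = None  # b's best points elsewhere; no b->a score for this pair
        calls.append(HomologCall(gid, sid, relation, tier, fwd, rev))
        seen.add((gid, sid))
    for gid, fwd in best_b.items():
        sid = fwd.subject_id
        if (sid, gid) in seen:
            continue
        rev = best_a.get(sid)
        if rev is not None and rev.subject_id != gid:
            rev = None
        relation = "rbh_ortholog" if rev is not None else "one_way_hit"
        calls.append(HomologCall(sid, gid, relation, tier_of[gid], rev, fwd))

    # tier 3: genomic search for genes with no hit at either sequence tier
    for rec in remaining_a:
        if genome_b is None:
            break
        res = genome_search(rec, genome_b, aa)
        if res is None:
            continue
        scaffold_name, hsps = res
        target = _overlapping_gene(scaffold_name, hsps, genes_b)
        sc = percent_blast_identity(rec, hsps, "translated_genome")
        sc.subject_id = target or scaffold_name
        calls.append(
            HomologCall(rec.gene_id, sc.subject_id, "one_way_hit", "translated_genome", sc, None)
        )
    for rec in remaining_b:
        if genome_a is None:
            break
        res = genome_search(rec, genome_a, aa)
        if res is None:
            continue
        scaffold_name, hsps = res
        target = _overlapping_gene(scaffold_name, hsps, genes_a)
        sc = percent_blast_identity(rec, hsps, "translated_genome")
        sc.subject_id = target or scaffold_name
        calls.append(
            HomologCall(sc.subject_id, rec.gene_id, "one_way_hit", "translated_genome", None, sc)
        )

    calls.sort(key=lambda c: (c.gene_a, c.gene_b))
    return calls


def _overlapping_gene(
    scaffold_name: str, hsps: Sequence[Hsp], genes: Sequence[GeneRecord]
) -> str | None:
    """Map six-frame protein HSPs back to a genomic span and return the id of
    an annotated gene overlapping it, if any."""
    # subject_id carries "scaffold:+0" style frame tags; s_interval is in
    # amino acids of the frame translation — approximate the genomic span.
    spans = []
    for h in hsps:
        frame = h.subject_id.rsplit(":", 1)[-1]
        strand, off = frame[0], int(frame[1:])
        s, e = h.s_interval
        spans.append((strand, off, s * 3 + off, e * 3 + off))
    for g in genes:
        if g.scaffold != scaffold_name:
            continue
        gs, ge = g.span
        for strand, off, s, e in spans:
            # for minus-strand frames coordinates count from the 3' end; an
            # overlap test on the forward strand is close enough for mapping
            if strand == "-":
                continue
            if max(gs, s) < min(ge, e):
                return g.gene_id
    return None


def pairwise_identity_matrix(
    orthologs: dict[str, GeneRecord | None],
    tier: str = "cds_nucleotide",
    nt_params: AlignParams | None = None,
    aa_params: AlignParams | None = None,
) -> pd.DataFrame:
    """Species x species matrix of the homology statistic between one ortholog
    per species. Diagonal is 100; a missing ortholog gives NaN for its row and
    column (absent, not zero); the matrix need not be symmetric because query
    coverage differs by direction."""
    nt = nt_params or AlignParams.nucleotide()
    aa = aa_params or AlignParams.protein()
    species = list(orthologs)
    mat = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    for sp_q in species:
        q = orthologs[sp_q]
        if q is None:
            continue
        for sp_s in species:
            s = orthologs[sp_s]
            if s is None:
                continue
            if sp_q == sp_s:
                mat.loc[sp_q, sp_s] = 100.0
                continue
            mat.loc[sp_q, sp_s] = _score_one(q, s, tier, nt, aa).pct_blast_identity
    return mat


def hsp_table(hsps: Sequence[Hsp], qlen: int, slen: int) -> pd.DataFrame:
    """Tabular HSP output mirroring the classic 12-column blast format plus
    raw score."""
    rows = []
    for h in hsps:
        rows.append(
            dict(
                qseqid=h.query_id,
                sseqid=h.subject_id,
                pident=round(100 * h.identity_frac, 3),
                length=h.aln_len,
                qlen=qlen,
                slen=slen,
                mismatch=h.aln_len - h.matches - h.gaps,
                gapopen=h.gaps,
                qstart=h.q_interval[0] + 1,
                qend=h.q_interval[1],
                sstart=h.s_interval[0] + 1,
                send=h.s_interval[1],
                score=h.score,
            )
        )
    return pd.DataFrame(rows)
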