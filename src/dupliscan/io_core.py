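"""Readers/writers for FASTA, GFF3, Newick and TSV matrices, plus the shared
sequence and coordinate conventions used by every other module.

Conventions
-----------
- Internal coordinates are 0-based half-open everywhere; conversion to/from
  GFF3's 1-based inclusive convention happens only in :func:`read_gff_genes`
  and :func:`write_gff_genes`.
- DNA sequences are upper-case strings over ``{A,C,G,T,N}``; any other
  ambiguity character is rejected at parse time because downstream codon
  counting assumes this alphabet.
- Translation uses the standard genetic code (table 1) throughout.
- One ORF per gene: the longest CDS isoform is kept, ties broken by
  lexicographic mRNA id.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A structural problem in an input file (position reported in message)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS under the standard code; ``X`` for codons with N,
    ``*`` for stops. Trailing partial codon is ignored."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in CODON_TABLE:
            aa.append(CODON_TABLE[codon])
        elif codon in STOP_CODONS:
            aa.append("*")
        else:
            aa.append("X")
    return "".join(aa)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Scaffold:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"scaffold {self.name!r}: empty sequence")


class Genome:
    """A named collection of scaffolds with unique names."""

    def __init__(self, scaffolds: Iterable[Scaffold] | Iterable[tuple[str, str]]):
        self.scaffolds: dict[str, Scaffold] = {}
        for sc in scaffolds:
            if isinstance(sc, tuple):
                sc = Scaffold(*sc)
            if sc.name in self.scaffolds:
                raise ValueError(f"duplicate scaffold name {sc.name!r}")
            self.scaffolds[sc.name] = sc

    def __getitem__(self, name: str) -> Scaffold:
        return self.scaffolds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __iter__(self):
        return iter(self.scaffolds.values())


@dataclass
class GeneRecord:
    """A gene's genomic placement plus its spliced CDS and protein sequence.

    ``cds_intervals`` are 0-based half-open scaffold coordinates sorted by
    start; ``cds_seq`` is spliced in transcription order and strand-corrected
    (5'->3'). A record whose CDS length is not a multiple of three or whose
    translation contains an internal stop is flagged ``pseudogene`` rather
    than rejected.
    """

    gene_id: str
    species: str
    scaffold: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    cds_seq: str
    protein_seq: str = ""
    element_label: str | None = None
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivs
        if len(self.cds_seq) % 3 != 0:
            self.pseudogene = True
        if not self.protein_seq:
            prot = translate(self.cds_seq)
            if prot.endswith("*"):
                prot = prot[:-1]
            if "*" in prot:
                self.pseudogene = True
                prot = prot.split("*")[0]
            self.protein_seq = prot

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (first CDS start, last CDS end)."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with per-sample metadata."""

    counts: "pandas.DataFrame"  # noqa: F821 - imported lazily below
    sample_meta: "pandas.DataFrame"  # columns: species, tissue, replicate

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, alphabet: str | None = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(name, sequence)``.

    Sequences are upper-cased and whitespace-stripped. ``alphabet`` may be
    ``"dna"`` (reject anything outside ACGTN), ``"protein"``, or ``None``
    (no alphabet check).
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    lineno_of_header = 0

    def _flush(lineno: int) -> None:
        nonlocal name, chunks
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(
                f"{path}: record {name!r} (header at line {lineno_of_header}) has an empty sequence"
            )
        _check_alphabet(seq, alphabet, f"{path}: record {name!r}")
        records.append((name, seq))
        name, chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                name = header.split()[0]
                lineno_of_header = lineno
            else:
                if name is None:
                    raise ParseError(f"{path}: sequence before first header at line {lineno}")
                chunks.append(line)
    _flush(lineno_of_header)
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def _check_alphabet(seq: str, alphabet: str | None, context: str) -> None:
    if alphabet is None:
        return
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise ParseError(f"{context}: disallowed characters {sorted(bad)}")


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_attrs(field9: str) -> dict[str, str]:
    return {m.group(1).strip(): m.group(2).strip() for m in _ATTR_RE.finditer(field9)}


def read_gff_genes(
    path: str | Path,
    genome: Genome,
    species: str = "",
    element_labels: dict[str, str] | None = None,
) -> list[GeneRecord]:
    """Extract one :class:`GeneRecord` per gene from a GFF3 annotation.

    GFF 1-based inclusive coordinates become 0-based half-open. Minus-strand
    CDS segments are spliced in transcription order and reverse-complemented.
    When a gene has several mRNAs the longest CDS wins (ties by lexicographic
    mRNA id). A CDS whose length is not a multiple of three is kept but
    flagged pseudogene with a logged warning; a CDS on an unknown scaffold is
    an error.
    """
    # mRNA id -> (gene id, scaffold, strand); mRNA id -> [(start0, end0)]
    mrna_parent: dict[str, tuple[str, str, str]] = {}
    cds_of: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in {"mRNA", "CDS"}:
                continue
            a = _parse_attrs(attrs)
            s0, e0 = int(start) - 1, int(end)  # GFF 1-based inclusive -> half-open
            if ftype == "mRNA":
                mid = a.get("ID", "")
                if not mid:
                    raise ParseError(f"{path}:{lineno}: mRNA without ID")
                gene = a.get("Parent", mid)
                mrna_parent[mid] = (gene, seqid, strand)
                order.append(mid)
            else:  # CDS
                parent = a.get("Parent", "")
                if not parent:
                    raise ParseError(f"{path}:{lineno}: CDS without Parent")
                if seqid not in genome:
                    raise ParseError(f"{path}:{lineno}: CDS references unknown scaffold {seqid!r}")
                for mid in parent.split(","):
                    cds_of.setdefault(mid, []).append((s0, e0))
                    if mid not in mrna_parent:
                        # CDS directly under a gene or orphan mRNA id
                        mrna_parent[mid] = (mid, seqid, strand)
                        order.append(mid)

    element_labels = element_labels or {}
    # choose longest CDS per gene, ties by mRNA id
    best: dict[str, tuple[int, str]] = {}
    for mid in order:
        if mid not in cds_of:
            continue
        total = sum(e - s for s, e in cds_of[mid])
        gene, _, _ = mrna_parent[mid]
        cur = best.get(gene)
        if cur is None or (-total, mid) < (-cur[0], cur[1]):
            best[gene] = (total, mid)

    records: list[GeneRecord] = []
    for gene, (_, mid) in best.items():
        _, seqid, strand = mrna_parent[mid]
        intervals = sorted(cds_of[mid])
        scaff = genome[seqid].sequence
        pieces = [scaff[s:e] for s, e in intervals]
        cds = "".join(pieces)
        if strand == "-":
            cds = reverse_complement(cds)
        rec = GeneRecord(
            gene_id=gene,
            species=species,
            scaffold=seqid,
            strand=strand,
            cds_intervals=intervals,
            cds_seq=cds,
            element_label=element_labels.get(seqid),
        )
        if len(cds) % 3 != 0:
            logger.warning("gene %s: CDS length %d not divisible by 3; flagged pseudogene", gene, len(cds))
        records.append(rec)
    return records


def write_gff_genes(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    """Write gene/mRNA/CDS features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.scaffold}\tdupliscan\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold}\tdupliscan\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for cs, ce in g.cds_intervals:
                fh.write(
                    f"{g.scaffold}\tdupliscan\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\tID={mid}.cds;Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick string into a rooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"Newick parse error: {exc}") from exc
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise ParseError("duplicate tip labels in Newick tree")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    ).strip()


def write_newick(path: str | Path, tree: dendropy.Tree) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def read_count_matrix(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV and its sample metadata TSV.

    The metadata table must have columns ``sample``, ``species``, ``tissue``
    (ovary/testis) and ``replicate``.
    """
    import pandas as pd

    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", comment="#").set_index("sample")
    bad = set(meta["tissue"]) - {"ovary", "testis"}
    if bad:
        raise ParseError(f"{meta_path}: unknown tissues {sorted(bad)}")
    return CountMatrix(counts=counts, sample_meta=meta)


def write_matrix(path: str | Path, df, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def close(a: float, b: float, rel: float = 1e-6) -> bool:
    return math.isclose(a, b, rel_tol=rel, abs_tol=1e-9)
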