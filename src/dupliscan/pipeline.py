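"""Config-driven orchestration of the analysis stages, report generation and
logging.

A run consumes a *cohort directory* (the layout ``simulate.write_cohort``
emits: per-species genome FASTA + GFF3, a species tree, counts + sample
metadata) — either freshly simulated from the config's ``simulate`` block or
pre-existing via ``input_dir`` — and executes the stages in dependency
order: homology -> synteny -> genetree -> selection, with expression
independent after IO. Every output table carries a header comment recording
the package version, the seed, and a hash of the full parameter set; reruns
of the same config are byte-identical. Failure of one gene family is logged
and skipped, not fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .expression import (
    bm_ancestral_states,
    branch_reg_rates,
    counts_to_tpm,
    log_tpm,
    percentile_vs_background,
    tissue_profiles,
)
from .genetree import (
    GeneTree,
    align_codons_from_protein,
    build_nj_tree,
    progressive_align,
    reconcile,
)
from .homology import AlignParams, call_rbh
from .io_core import Genome, read_count_matrix, read_fasta, read_gff_genes, read_newick
from .selection import compare_dup_branches, gene_branch_records
from .simulate import SimConfig, simulate_cohort, write_cohort
from .synteny import classify_duplicate, flanking_homology

logger = logging.getLogger("dupliscan")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HomologyConfig(_Block):
    min_hsp_score: float = 40.0
    min_hsp_len: int = 20
    genome_search: bool = False  # tier-3 six-frame scans are opt-in (slow)
    # a gene escalates to the next tier when its best hit scores below this
    # (the surrogate for an E-value cutoff: chance-level fragment hits must
    # not mask a gene as found)
    escalate_below_pct: float = 5.0
    # an edge joins two genes into one family only above this homology
    # score; chance-level hits between unrelated genes stay in the table
    # but do not define family membership
    family_link_min_pct: float = 10.0


class SyntenyConfig(_Block):
    flank_bp: int = 50_000
    min_aln_len: int = 100
    cutoff: float = 0.05
    tandem_max_gap: int = 100_000
    tandem_max_genes: int = 10


class GenetreeConfig(_Block):
    bootstrap: int = 100
    root_on_species: str | None = None  # outgroup species; midpoint if absent


class SelectionConfig(_Block):
    alpha: float = 0.05
    fdr: float = 0.05


class ExpressionConfig(_Block):
    min_expressed_tpm: float = 1.0
    pseudocount: float = 1.0
    normalize_by_length: bool = False


class SimulateConfig(_Block):
    model_config = ConfigDict(extra="forbid")
    # mirrors simulate.SimConfig; only overrides need to be given
    species_tree: str | None = None
    n_families: int | None = None
    n_background_genes: int | None = None
    dup_rate: float | None = None
    loss_rate: float | None = None
    tandem_fraction: float | None = None
    pseudogenization_prob: float | None = None
    codon_length: int | None = None
    base_omega: float | None = None
    post_dup_omega: float | None = None
    kappa: float | None = None
    bm_sigma2: float | None = None
    testis_shift_prob: float | None = None
    testis_shift_size: float | None = None
    nb_dispersion: float | None = None
    library_size: int | None = None
    n_replicates: int | None = None
    spacer_min: int | None = None
    spacer_max: int | None = None
    codon_indel_rate: float | None = None


class RunConfig(_Block):
    seed: int = 0
    out_dir: str = "dupliscan_out"
    log_level: str = "INFO"
    input_dir: str | None = None
    simulate: SimulateConfig | None = None
    homology: HomologyConfig = HomologyConfig()
    synteny: SyntenyConfig = SyntenyConfig()
    genetree: GenetreeConfig = GenetreeConfig()
    selection: SelectionConfig = SelectionConfig()
    expression: ExpressionConfig = ExpressionConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def param_hash(self) -> str:
        """Hash of the analysis-relevant parameters (where outputs land and
        how much is logged do not change results)."""
        payload = self.model_dump(exclude={"out_dir", "log_level"})
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class Cohort:
    """In-memory view of a cohort directory."""

    def __init__(self, root: Path):
        self.root = Path(root)
        self.species_tree = read_newick(self.root / "species_tree.nwk")
        self.species = sorted(l.taxon.label for l in self.species_tree.leaf_node_iter())
        self.genomes: dict[str, Genome] = {}
        self.gene_records: dict[str, list] = {}
        for sp in self.species:
            fasta = self.root / "genomes" / f"{sp}.fasta"
            gff = self.root / "annotations" / f"{sp}.gff3"
            if not fasta.exists():
                raise FileNotFoundError(fasta)
            genome = Genome(read_fasta(fasta))
            self.genomes[sp] = genome
            self.gene_records[sp] = read_gff_genes(gff, genome, species=sp)
        self.counts = read_count_matrix(self.root / "counts.tsv", self.root / "samples.tsv")
        lengths = pd.read_csv(self.root / "gene_lengths.tsv", sep="\t", index_col=0)
        self.gene_lengths = lengths["length"].to_dict()

    def all_records(self) -> list:
        return [r for sp in self.species for r in self.gene_records[sp]]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_homology(cohort: Cohort, cfg: RunConfig) -> pd.DataFrame:
    """All-species-pairs tiered RBH calling."""
    nt = AlignParams.nucleotide(
        min_hsp_score=cfg.homology.min_hsp_score, min_hsp_len=cfg.homology.min_hsp_len
    )
    aa = AlignParams.protein(min_hsp_score=cfg.homology.min_hsp_score)
    rows = []
    for i, sp1 in enumerate(cohort.species):
        for sp2 in cohort.species[i + 1 :]:
            kw = {"escalate_below_pct": cfg.homology.escalate_below_pct}
            if cfg.homology.genome_search:
                kw.update(genome_a=cohort.genomes[sp1], genome_b=cohort.genomes[sp2])
            calls = call_rbh(cohort.gene_records[sp1], cohort.gene_records[sp2], nt, aa, **kw)
            for c in calls:
                rows.append(
                    dict(
                        species_a=sp1,
                        species_b=sp2,
                        gene_a=c.gene_a,
                        gene_b=c.gene_b,
                        relation=c.relation,
                        tier=c.tier,
                        pct_identity_fwd=(
                            round(c.forward_score.pct_blast_identity, 3) if c.forward_score else np.nan
                        ),
                        pct_identity_rev=(
                            round(c.reverse_score.pct_blast_identity, 3) if c.reverse_score else np.nan
                        ),
                    )
                )
    return pd.DataFrame(rows)


def assemble_families(
    orthologs: pd.DataFrame, cohort: Cohort, link_min_pct: float = 10.0
) -> dict[str, list]:
    """Group genes into families as connected components of the homology
    graph, named by their lexicographically smallest member. RBH edges always
    link; one-way edges link only when their best homology score reaches
    ``link_min_pct`` (chance-level local hits stay in the table but do not
    define membership)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_id = {r.gene_id: r for r in cohort.all_records()}
    for _, row in orthologs.iterrows():
        if row["gene_a"] not in by_id or row["gene_b"] not in by_id:
            continue
        scores = [row.get("pct_identity_fwd", np.nan), row.get("pct_identity_rev", np.nan)]
        best = np.nanmax(scores) if not all(pd.isna(s) for s in scores) else np.nan
        if not (best >= link_min_pct):
            continue  # chance-level hit (even if formally reciprocal)
        union(row["gene_a"], row["gene_b"])
    comps: dict[str, list] = {}
    for gid in by_id:
        comps.setdefault(find(gid), []).append(by_id[gid])
    return {f"family_{root}": sorted(members, key=lambda r: r.gene_id) for root, members in sorted(comps.items())}


def run_synteny(
    cohort: Cohort, cfg: RunConfig, orthologs: pd.DataFrame, families: dict[str, list]
) -> pd.DataFrame:
    """Flanking homology for RBH ortholog pairs and tandem/dispersed
    classification for within-species paralog pairs."""
    sc = cfg.synteny
    by_id = {r.gene_id: r for r in cohort.all_records()}
    rows = []
    rbh = orthologs[orthologs["relation"] == "rbh_ortholog"]
    for _, row in rbh.iterrows():
        a, b = by_id.get(row["gene_a"]), by_id.get(row["gene_b"])
        if a is None or b is None:
            continue
        try:
            rec = flanking_homology(
                a,
                b,
                cohort.genomes[a.species],
                cohort.genomes[b.species],
                flank_bp=sc.flank_bp,
                min_aln_len=sc.min_aln_len,
                cutoff=sc.cutoff,
            )
        except ValueError as exc:
            logger.warning("synteny %s-%s skipped: %s", a.gene_id, b.gene_id, exc)
            continue
        rows.append(
            dict(
                kind="ortholog",
                gene_a=a.gene_id,
                gene_b=b.gene_id,
                flanking_homology=round(rec.flanking_homology, 5),
                syntenic=rec.syntenic,
                mode="",
            )
        )
    for fam, members in families.items():
        per_sp: dict[str, list] = {}
        for r in members:
            per_sp.setdefault(r.species, []).append(r)
        for sp, recs in per_sp.items():
            all_sp = cohort.gene_records[sp]
            for i in range(len(recs)):
                for j in range(i + 1, len(recs)):
                    cls = classify_duplicate(
                        (recs[i], recs[j]),
                        all_sp,
                        tandem_max_gap=sc.tandem_max_gap,
                        tandem_max_genes=sc.tandem_max_genes,
                    )
                    rows.append(
                        dict(
                            kind="paralog",
                            gene_a=recs[i].gene_id,
                            gene_b=recs[j].gene_id,
                            flanking_homology=np.nan,
                            syntenic=cls.same_scaffold,
                            mode=cls.mode,
                        )
                    )
    return pd.DataFrame(rows)


def run_genetree_selection(
    cohort: Cohort, cfg: RunConfig, families: dict[str, list]
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-family alignment, NJ tree, reconciliation, and branch selection
    records. Returns (reconciliation table, branch table, per-family trees)."""
    recon_rows, branch_rows = [], []
    trees: dict[str, GeneTree] = {}
    for fam, members in families.items():
        usable = [r for r in members if not r.pseudogene]
        if len(usable) < 3:
            continue
        try:
            prots = {r.gene_id: r.protein_seq for r in usable}
            aln = progressive_align(prots)
            cds = {r.gene_id: r.cds_seq for r in usable}
            codon_aln = align_codons_from_protein(aln, cds)
            species_map = {r.gene_id: r.species for r in usable}
            root_set = None
            if cfg.genetree.root_on_species:
                root_set = {
                    g for g, s in species_map.items() if s == cfg.genetree.root_on_species
                }
            if not root_set:
                logger.warning("%s: no outgroup tip; midpoint rooting", fam)
            gtree = build_nj_tree(
                aln,
                species_map,
                bootstrap=cfg.genetree.bootstrap,
                root_on_set=root_set or None,
                seed=cfg.seed,
            )
            recon = reconcile(gtree, cohort.species_tree)
            records = gene_branch_records(codon_aln, gtree, recon.post_dup_branches)
        except (ValueError, KeyError) as exc:
            logger.warning("family %s skipped: %s", fam, exc)
            continue
        trees[fam] = gtree
        recon_rows.append(
            dict(
                family=fam,
                n_members=len(members),
                n_duplications=recon.n_duplications,
                implied_losses=recon.implied_losses,
                dup_placements=";".join(sorted(recon.dup_placements.values())),
            )
        )
        for rec in records:
            branch_rows.append(
                dict(
                    family=fam,
                    parent=rec.branch_id[0],
                    child=rec.branch_id[1],
                    N=round(rec.N, 4),
                    S=round(rec.S, 4),
                    N_sites=round(rec.N_sites, 2),
                    S_sites=round(rec.S_sites, 2),
                    omega=round(rec.omega, 4) if not math.isnan(rec.omega) else np.nan,
                    p_value=rec.p_value,
                    fdr_q=rec.fdr_q,
                    post_duplication=rec.post_duplication,
                )
            )
    return pd.DataFrame(recon_rows), pd.DataFrame(branch_rows), trees


def dup_contrast_from_branches(branches: pd.DataFrame) -> dict:
    """Pooled duplicated-vs-unduplicated omega contrast across families."""
    from .selection import BranchSelectionRecord

    records = [
        BranchSelectionRecord(
            branch_id=(r.parent, r.child),
            N=r.N,
            S=r.S,
            N_sites=r.N_sites,
            S_sites=r.S_sites,
            omega=r.omega if not pd.isna(r.omega) else math.nan,
            post_duplication=bool(r.post_duplication),
        )
        for r in branches.itertuples()
    ]
    try:
        med_dup, med_non, p = compare_dup_branches(records)
    except ValueError:
        return dict(median_dup=np.nan, median_nondup=np.nan, p_value=np.nan)
    return dict(median_dup=med_dup, median_nondup=med_non, p_value=p)


def run_expression(cohort: Cohort, cfg: RunConfig) -> pd.DataFrame:
    """TPM, bias calls, BM ancestral states per gene and tissue, branch
    regulatory rates, and percentiles against the background gene set
    (background = genes outside the focal families, here every gene row; the
    focal gene is always excluded from its own background)."""
    ec = cfg.expression
    tpm = counts_to_tpm(cohort.counts, cohort.gene_lengths)
    meta = cohort.counts.sample_meta
    profiles = tissue_profiles(tpm, meta, ec.min_expressed_tpm)
    prof_df = pd.DataFrame([vars(p) for p in profiles])

    rows = []
    rate_sds: dict[tuple[str, str], float] = {}
    for gene in tpm.index:
        sub = prof_df[prof_df["gene_id"] == gene]
        for tissue, col in (("ovary", "ovary_tpm"), ("testis", "testis_tpm")):
            tips = {
                r["species"]: float(log_tpm(r[col], pseudocount=ec.pseudocount))
                for _, r in sub.iterrows()
                if r[col] >= ec.min_expressed_tpm
            }
            if len(tips) < 3:
                continue
            try:
                asr = bm_ancestral_states(cohort.species_tree, tips)
                reg = branch_reg_rates(
                    asr, gene_id=gene, tissue=tissue, normalize_by_length=ec.normalize_by_length
                )
            except ValueError:
                continue
            rate_sds[(gene, tissue)] = reg.rate_sd
    for (gene, tissue), sd in rate_sds.items():
        background = [v for (g, t), v in rate_sds.items() if t == tissue and g != gene]
        if len(background) < 100:
            logger.warning("%s/%s: background has only %d genes", gene, tissue, len(background))
        pct = percentile_vs_background(sd, background) if background else np.nan
        rows.append(dict(gene=gene, tissue=tissue, rate_sd=round(sd, 6), percentile=round(pct, 2)))
    reg_df = pd.DataFrame(rows)

    bias = (
        prof_df.groupby("gene_id")["bias"]
        .agg(lambda s: ";".join(f"{b}:{n}" for b, n in s.value_counts().sort_index().items()))
        .rename("bias_by_species")
    )
    reg_df = reg_df.merge(bias, left_on="gene", right_index=True, how="left")
    return reg_df


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dupliscan {__version__} seed={cfg.seed} params={cfg.param_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages end to end; returns the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    try:
        if cfg.simulate is not None:
            overrides = {k: v for k, v in cfg.simulate.model_dump().items() if v is not None}
            sim_cfg = SimConfig(seed=cfg.seed, **overrides)
            cohort_dir = out / "sim"
            write_cohort(simulate_cohort(sim_cfg), cohort_dir)
        elif cfg.input_dir is not None:
            cohort_dir = Path(cfg.input_dir)
            if not cohort_dir.exists():
                raise FileNotFoundError(f"input_dir {cohort_dir} does not exist")
        else:
            raise ValueError("config needs either a simulate block or input_dir")

        cohort = Cohort(cohort_dir)
        logger.info("cohort: %d species, %d genes", len(cohort.species), len(cohort.all_records()))

        orthologs = run_homology(cohort, cfg)
        _write(orthologs, out / "orthologs.tsv", cfg)
        families = assemble_families(orthologs, cohort, cfg.homology.family_link_min_pct)
        synteny = run_synteny(cohort, cfg, orthologs, families)
        _write(synteny, out / "synteny.tsv", cfg)
        recon, branches, trees = run_genetree_selection(cohort, cfg, families)
        _write(recon, out / "reconciliation.tsv", cfg)
        _write(branches, out / "selection.tsv", cfg)
        from .io_core import newick_string

        with open(out / "gene_trees.nwk", "w") as tfh:
            for fam, gt in sorted(trees.items()):
                tfh.write(f"# {fam}\n{newick_string(gt.tree)}\n")
        contrast = dup_contrast_from_branches(branches) if len(branches) else {}
        expression = run_expression(cohort, cfg)
        _write(expression, out / "expression.tsv", cfg)
        dossier = summarize_genes(cohort, families, synteny, recon, branches, expression)
        _write(dossier, out / "summary.tsv", cfg)

        report = dict(
            version=__version__,
            seed=cfg.seed,
            param_hash=cfg.param_hash(),
            n_species=len(cohort.species),
            n_genes=len(cohort.all_records()),
            n_families=len(families),
            n_rbh=int((orthologs["relation"] == "rbh_ortholog").sum()) if len(orthologs) else 0,
            dup_contrast=contrast,
        )
        with open(out / "report.json", "w") as rfh:
            json.dump(report, rfh, indent=1, sort_keys=True, default=float)
        return report
    finally:
        logger.removeHandler(fh)
        fh.close()


def summarize_genes(
    cohort: Cohort,
    families: dict[str, list],
    synteny: pd.DataFrame,
    recon: pd.DataFrame,
    branches: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(family, species) dossier: copy number, duplication mode, median
    omega, and the family-level regulatory percentile where available."""
    rows = []
    recon_by_fam = recon.set_index("family") if len(recon) else None
    for fam, members in families.items():
        # expression rows are keyed by the counts-table unit id; members map
        # to it when they share the unit prefix of their gene ids
        units = {r.gene_id.split("_")[0] for r in members}
        pct = np.nan
        if len(units) == 1 and len(expression):
            sub = expression[
                (expression["gene"] == next(iter(units))) & (expression["tissue"] == "testis")
            ]
            if len(sub):
                pct = float(sub["percentile"].iloc[0])
        med_omega = np.nan
        if len(branches):
            sub = branches[(branches["family"] == fam) & branches["omega"].notna()]
            if len(sub):
                med_omega = float(sub["omega"].median())
        for sp in cohort.species:
            here = [r for r in members if r.species == sp]
            modes = set()
            if len(synteny):
                ids = {r.gene_id for r in here}
                para = synteny[(synteny["kind"] == "paralog")]
                for _, row in para.iterrows():
                    if row["gene_a"] in ids or row["gene_b"] in ids:
                        modes.add(row["mode"])
            ndup = (
                int(recon_by_fam.loc[fam, "n_duplications"])
                if recon_by_fam is not None and fam in recon_by_fam.index
                else 0
            )
            rows.append(
                dict(
                    family=fam,
                    species=sp,
                    copy_number=len(here),
                    pseudogenes=sum(1 for r in here if r.pseudogene),
                    duplicate_modes=";".join(sorted(modes)),
                    n_duplications=ndup,
                    median_omega=med_omega,
                    testis_rate_percentile=pct,
                )
            )
    return pd.DataFrame(rows)
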