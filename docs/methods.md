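# Methods

This note documents the models behind each stage, the defaults that matter,
what the synthetic cohorts do and do not emulate, and the numerical choices
a maintainer would want to know.

## Homology search and the coverage × identity statistic

The aligner is a deterministic seed-and-extend local aligner: exact k-mer
seeds grouped by diagonal (nucleotide k = 11, protein k = 4), X-drop
ungapped extension, then greedy collinear chaining of nearby segments with
affine gap penalties, which plays the role of banded gapped extension.
Default nucleotide scoring is +2/−3 with gap open −5 / extend −2; protein
scoring uses BLOSUM62. There is no E-value model (Karlin–Altschul
calibration is out of scope); significance is approximated by a raw score
floor (`min_hsp_score` = 40) and a length floor (`min_hsp_len` = 20 nt /
12 aa). Measured on unrelated 500-codon genes, chance-level hits that pass
these floors score below ~4 on the homology statistic; two derived
thresholds build on that floor:

- `escalate_below_pct` = 5: a gene whose best hit at a tier scores below
  chance level escalates to the next tier (nucleotide → protein →
  translated genome), exactly as a real E-value cutoff would have reported
  "no hit". Without this, fragmentary nucleotide hits at genus-scale
  divergence mask true protein-level homology.
- `family_link_min_pct` = 10 (≈ 3× the noise ceiling): graph edges below
  this never join two genes into one family, even when formally reciprocal
  — two species that each lost a family member will otherwise produce
  junk reciprocal pairs.

The homology statistic between two genes is the sum over retained HSPs of
(query coverage %) × (identity fraction), with query coverage intervals
merged greedily in descending HSP score order so no base is counted twice,
capped at 100. It is intentionally asymmetric in query and subject
(coverage is measured on the query), which is why species-by-species
identity matrices are reported with both orientations.

Tier-3 (protein vs six-frame scaffold translation) is opt-in
(`genome_search`): it is the right tool for detecting unannotated homologs
but costs a full genome scan per orphan gene.

## Microsynteny

For a homolog pair, the region spanning each gene ± `flank_bp` (default
50 000, the two flanks pooled into one ratio) is extracted with the focal
gene's own span hard-masked with N; regions are locally aligned, alignments
shorter than 100 bp are discarded, and flanking homology = merged aligned
flank bases / available flank bases. At scaffold edges the denominator is
the sequence actually present, so genes near contig ends are not penalized.
The syntenic/non-syntenic cut is 5% flanking homology.

Tandem vs dispersed classification is an explicit reproducible rule (dot
plots judged by eye are not reproducible): tandem iff same scaffold AND
(gap ≤ 100 kb OR ≤ 10 intervening annotated genes); otherwise dispersed.
Both cutoffs are config keys and are echoed in the output. Two dispersed
copies that happen to land near each other on the same novel scaffold are
genuinely ambiguous under any distance rule and are the one observed error
class in simulation (accuracy ≈ 0.98).

## Gene trees and reconciliation

Protein alignments are progressive: k-mer-distance guide clustering
(average linkage) and profile–profile Needleman–Wunsch with affine gaps
(open −10, extend −1, BLOSUM62), deterministic tie rules. Codon alignments
are produced by back-threading each CDS through its aligned protein (one
codon per residue column, `---` per gap), with an exact translation check.

Trees are distance-based by design: Poisson-corrected protein distances
d = −ln(1 − p) over pairwise-ungapped columns (p ≥ 1 clamped to d = 10),
neighbor joining, negative branch lengths clamped to 0, and classical
nonparametric bootstrap (column resampling, default 100 replicates) written
as percent support on internal nodes. This is a deliberate, testable
stand-in for likelihood tree search: NJ is exact on additive distances
(property-tested), cheap, and adequate at the divergences simulated here.
Rooting: on the outgroup-species clade when its tips are monophyletic in
the unrooted tree, else on a single outgroup tip, else midpoint with a
logged warning. Rooting on the clade rather than an arbitrary outgroup tip
matters when the outgroup itself carries duplicates.

Reconciliation is standard LCA mapping. Each gene-tree node maps to the
species-tree LCA of its descendant species; a node is a duplication iff its
mapping equals a child's mapping; losses accumulate along each gene-tree
branch as the number of skipped species-tree edges (minus one below
speciation nodes). `post_dup_branches` contains every branch of the
subtrees rooted at duplication nodes' children, including their stems; a
config-free alternative (immediate children only) was considered and
rejected as less comparable with downstream branch contrasts. Gene trees
that conflict with synteny evidence are not auto-corrected; the tables
report reconciliation counts and synteny classes side by side and leave the
judgment to the analyst.

## Branch-specific selection

Ancestral codon sequences are reconstructed by unit-cost parsimony
(Sankoff dynamic programming — exact on multifurcating trees, identical to
Fitch on binary trees), with gap/N tip characters treated as missing data;
the top-down pass prefers the parent's base, remaining ties broken by the
fixed order A < C < G < T.

Per branch, substitutions are counted by Nei–Gojobori pathway averaging:
all orderings of the 1–3 differing positions, pathways through stop codons
excluded, equal weights (no transition bias in the weighting; the config
exposes none deliberately — the classic estimator is the defensible
default). Site counts are per codon: of the nine single-base neighbors,
mutations to stops leave the denominator, and syn_sites = 3 × synonymous
fraction of counted neighbors, so syn + nonsyn = 3 per codon. Codon columns
with a gap, N, or stop in either sequence on a branch are skipped for both
substitutions and sites, keeping the ratio commensurate. ω =
(N/N_sites)/(S/S_sites); branches with S = 0 report ω as undefined (NaN),
excluded from medians but counted in branch totals.

The per-branch neutrality test is a one-sided exact binomial test of
observing ≥ N nonsynonymous among N+S substitutions with neutral
probability N_sites/(N_sites+S_sites) (pathway-averaged counts rounded to
integers); Benjamini–Hochberg FDR is applied across the branches of a gene,
and both nominal p and q are reported. This is an honest small-scale
substitute for likelihood branch-site machinery, and its operating
characteristics are themselves measured: under neutral simulation with
transition bias κ = 2 the test is conservative (type-I ≈ 0.1% at α = 0.05,
because transitions are disproportionately synonymous and the site counts
ignore κ), and under ω ∈ {0.2, 1, 2} at 500 codons the rank order of branch
estimates is recovered essentially always, with the ω = 1 class estimated
near 0.96 (parsimony collapses a small fraction of multiple hits, and ω = 2
branches are compressed toward ~1.3 by the same saturation). The
duplicated-vs-unduplicated contrast is a one-tailed Wilcoxon rank-sum test
(duplicated > unduplicated) on defined ω values: exact enumeration when
both groups are ≤ 10 without ties, normal approximation with tie correction
otherwise.

## Regulatory evolution

Counts are TPM-normalized (per sample: count/length-in-kb, scaled to sum to
10⁶). Replicates are averaged on the TPM scale before the log transform
ln(TPM + 1); pseudocount and base are config keys, surfaced because the
choice is conventional. Bias calls: unexpressed if both tissues < 1 TPM;
else the higher tissue, exact ties to ovary with a flag.

Ancestral log-expression is reconstructed under Brownian motion by two-pass
message passing (rootward subtree means/variances, tipward complements),
verified to equal the full GLS solution to 1e-8 on random trees. Species
without data are pruned per gene; zero-length branches are replaced by
ε = 1e-8. The BM rate is reported both as the ML estimate (contrast sum /
n) and the unbiased contrast mean (/ n−1). Branch regulatory rates are raw
differences (child − parent) as reported, with a branch-length-normalized
variant behind a config flag; the per-gene summary is the SD of branch
deltas (ddof = 1), and its percentile against the background gene set
counts strictly-smaller background values plus half of ties, with the focal
gene excluded from its own background. Brown–Forsythe tests use median
centering (the defining choice of that test).

## The synthetic cohorts

Defaults are chosen once to represent a species-dense genus-scale study and
are not tuned per analysis:

- Species tree: 6 species, `((((A:0.10,B:0.10):0.08,C:0.18):0.08,
  (D:0.12,E:0.12):0.14):0.12,F:0.38);` in units of expected neutral
  substitutions/site — pairwise neutral divergence 0.2–0.76, i.e. sister
  species remain alignable at the nucleotide level while the outgroup
  approaches synonymous saturation, which exercises every homology tier.
- Families: 20 per cohort, 500 codons (large multi-exon proteins of the
  kind that motivate this pipeline), birth–death copy-number evolution at
  dup_rate 0.8 and loss_rate 0.2 per lineage per unit length;
  70% of new copies tandem (placed 5–50 kb from the parent, inheriting the
  conserved neighbourhood), the rest intron-less retro copies on a separate
  scaffold with novel random flanks; 10% of duplicates pseudogenized by a
  premature stop.
- Sequence evolution: proposal/acceptance codon model, μ = 1 proposal per
  nt site per unit length, transition bias κ = 2, synonymous proposals
  always accepted, nonsynonymous accepted with probability ω (ω > 1 acts as
  an extra nonsynonymous-only proposal stream), stops rejected; ω = 0.2 on
  background branches and 1.5 on all branches descending from duplication
  nodes; whole-codon indels at 0.005 per codon per unit, tracked in a true
  alignment.
- Intergenic spacers (10–100 kb) and introns evolve from ancestral random
  sequence by Jukes–Cantor substitution down the species tree, so
  orthologous neighbourhoods stay alignable while diverging.
- Expression: per-tissue independent BM of ln(TPM+1) from a root value of
  4.0 at σ² = 0.5 per unit length; at a duplication the new copy's testis
  trait jumps +1.5 with probability 0.5. Background genes (default 1000;
  300 in the acceptance cohort to keep runtime moderate) are single-copy
  with a shared σ², 10% of them at 4× (a heavy tail so percentiles are
  computed against a realistic spread). Counts are negative-binomial
  (dispersion 0.05) around library-size × TPM × length shares, library 10⁶.

What the simulator does **not** emulate: assembly and annotation error,
alignment uncertainty, gene conversion, transposable elements,
recombination-rate variation, pleiotropy between sequence and expression
evolution, and condition-dependent expression. Passing tests therefore
demonstrate the pipeline's correctness and operating characteristics under
its own model assumptions, not robustness to real-data artifacts.

Determinism: every random draw flows from one integer-seeded NumPy
generator; identical config + seed reproduce byte-identical files, and the
analysis stages contain no hidden randomness (bootstrap uses the run seed).

## Problem sizes and experiment designs

The test and acceptance experiments use these sizes, chosen to give stable
Monte-Carlo estimates at desk scale: 200 random tree pairs for the
reconciliation oracle (≤ 6 tips), 100 fixtures each for the parsimony and
GLS oracles, all group-size pairs ≤ 8 for the exact Wilcoxon check, 100
replicates for ω rank recovery, 1000 branches/replicates for the binomial
and Brown–Forsythe calibrations, 500 replicates for BM σ² recovery, and 50
replicates each for the duplication-contrast power and percentile-placement
experiments. The ω-recovery design hangs focal branches between a root
anchored by a low-divergence cherry and cherries of tips, so parsimony
reconstructs both endpoints of each focal branch accurately — on a bare
star, deep-root reconstruction error dominates and the measurement says
nothing about the estimator. The percentile experiment pools both tissue
traits of a gene (both evolve at the gene's σ²), doubling the branch deltas
per gene; with a 6-species tree a single-tissue rate SD has too few degrees
of freedom to separate a 4× gene from the background tail reliably. Its
background sets the heavy-tail fraction to zero because the experiment's
question is placement against a 1× background, not against other 4× genes.

## Known limitations

- ω is systematically compressed at high divergence (no multiple-hit
  correction in counting) and slightly below 1 under neutrality when
  ancestors come from parsimony; rank comparisons and contrasts are the
  supported use, absolute ω near saturation is not.
- The binomial branch test ignores transition bias and is conservative;
  branches with very few substitutions have essentially no power.
- NJ topology error at very low divergence can inflate duplication counts
  via reconciliation; bootstrap support and synteny classes are reported so
  such cases can be inspected.
- The aligner's score floors substitute for E-values; absolute homology
  statistics are comparable within a run, not across scoring configs.
- Six-frame genomic hits are mapped back to annotated genes only on the
  forward strand approximation; reverse-strand overlap resolution reports
  the scaffold instead.
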