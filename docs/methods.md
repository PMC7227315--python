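# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## Family identification

Membership is decided by a position-specific scoring matrix (PSSM) over
the 20-letter amino-acid alphabet, built from gap-free, equal-length
kinase-domain cores taken from trusted reference (anchor) proteins. The
column score for residue *r* is

    log2( ((count_r + p·bg_r) / (n + p)) / bg_r )

with pseudocount weight *p* = 1 and a uniform background. A protein is a
family member when at least one sliding window scores above a threshold
expressed as a fraction of the consensus-path score; the default fraction
is 0.6, which separates planted members from random-sequence decoys by a
wide margin at the generator's default mutation rates (members typically
score ≥ 80% of consensus, random windows score far below zero).
Overlapping above-threshold windows are pruned greedily best-first. `X`
residues score zero per column (background-neutral). Nonredundancy means
byte-identical sequences: duplicates collapse to one record with the
other ids kept as aliases, the only reading of "nonredundant" that needs
no extra assumptions.

Molecular weight uses average (not monoisotopic) residue masses plus one
water; `X` contributes the mean residue mass. The isoelectric point solves
net charge = 0 by bisection on [0, 14] to 1e-6 pH; because the
Henderson–Hasselbalch net charge is strictly decreasing in pH the root is
unique. The pKa set is EMBOSS's (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1). ProtParam uses a different set, so
values differ slightly from ProtParam-derived tables; the ranking and
acid/base classification agree.

## Alignment and phylogeny

Pairwise global alignment is Needleman–Wunsch with affine gaps via
Biopython's `PairwiseAligner` (BLOSUM62, open −10, extend −1 for protein;
match 2 / mismatch −1 for nucleotide). Identity is matches over alignment
columns with terminal-gap columns excluded; coverage is the aligned span
on the longer sequence (terminal gaps excluded) divided by its length.

The multiple aligner is center-star: the center is the sequence with the
highest summed pairwise score, and other sequences are merged against it
under "once a gap, always a gap". This replaces progressive alignment
(ClustalX-style) deliberately: it is deterministic, has no guide-tree
heuristics, and is accurate enough for the distance-based trees built on
top of it. It is a documented method substitution, not an equivalent.

Distances are p-distances over shared non-gap columns; a Poisson
correction −ln(1−p) is available behind a flag but is not the default
(p-distance is the assumption-free base). Neighbor joining is the standard
Saitou–Nei algorithm; ties in the Q criterion break to the lowest index
pair, which makes the tree invariant under taxon order up to relabeling.
Negative branch lengths are clamped to zero and each clamp is recorded on
the tree (never silent). Bootstrap resamples alignment columns with
replacement, rebuilds the NJ tree per replicate, and reports the
percentage of replicates containing each internal bipartition of the
original tree — supports annotate the original topology rather than a
majority-rule consensus, matching how such trees are usually drawn. The
default replicate count is 1000.

Subfamily assignment anchors the tree with labelled references (two per
subfamily by default): a query takes the label of the smallest clade
(either side of any edge) containing it whose anchors carry one label.
When equally small single-label clades disagree — the star-topology
case — or every anchored clade is mixed, the query is `unassigned`.

## Duplication and orthology

A pair of family genes is a duplication pair when the protein-level global
alignment covers more than 70% of the longer gene and the aligned region
shows more than 70% identity. Both inequalities are strict because the
rule is stated as "> 70%". The screen aligns proteins for consistency with
the rest of the pipeline; a nucleotide mode is available via the alphabet
flag (the original procedure used BLASTN on nucleotide sequences).

Pairs on different chromosomes are segmental. Same-chromosome pairs are
tandem when at most `tandem_max_separation` genes (default 1) lie between
them, otherwise they are classified segmental and flagged
"intra-chromosomal distal"; the chromosome-level dichotomy alone does not
bound tandem distance, so the proximity default is conservative and
config-exposed. Pairs involving an unplaced gene stay mode-undetermined
and are excluded from mode counts with a log entry, so
segmental + tandem + undetermined always equals the accepted total.

Orthologs between a subgenome set and an ancestral-genome set are
reciprocal best hits by global alignment score. Score ties drop both
candidates with a warning rather than picking arbitrarily.

## Gene structure and motifs

Exon/intron statistics come straight from the gene models: intronless ⇔
a single exon. Models with no exon records are rejected by name rather
than silently treated as intronless.

Motif discovery is ZOOPS expectation-maximization: each sequence contains
one motif occurrence with probability λ at a uniform position, else is
pure background. The E step computes the posterior over site positions and
absence; the M step re-estimates the PWM with a Dirichlet pseudocount of
0.01 × background per column and λ as the mean posterior occurrence. The
monotone quantity is therefore the log-joint (data log-likelihood plus the
Dirichlet term the M step maximizes); it is asserted non-decreasing at
every iteration, and convergence is a gain below 1e-6 or 200 iterations.
Ten seeded restarts (PWMs seeded from random data windows) are run per
motif and the best kept; a phase-shift refinement then tries moving all
sites one column left or right and re-running EM, which escapes the
off-by-one local optima plain EM is prone to. Motifs are discovered
sequentially with the committed sites of each motif erased (windows
overlapping erased positions are disallowed), so site sets are pairwise
disjoint. Width is fixed per run (default 15) rather than optimized as
MEME does — a documented divergence bounding cost — and motif numbering is
discovery order, which need not match an external tool's output order.

## Promoters and cis-elements

Promoters are the 2000 bp immediately 5' of the transcription start site;
for minus-strand genes the window downstream of the genomic gene end is
reverse-complemented, so promoters always read toward the gene. Windows
truncated by a contig boundary are returned short with a warning; zero
upstream bases give an empty promoter, not an error.

The scanner matches IUPAC degenerate patterns at every position on both
strands by default (cis-elements are orientation-ambiguous in common
practice; a flag disables the reverse strand). All overlapping matches
are reported, making occurrence counts well defined. The bundled
dictionary holds ABRE `ACGTG` and DRE `RCCGAC` and is config-extensible,
replacing a database lookup service with a local algorithm; which exact
database patterns a given published census used is generally not stated,
so the bundled cores are defaults, not a claim of equivalence. In the
family summary, the mean hits per gene is computed over ABRE/DRE-positive
genes only, matching the "average per positive gene" reading.

## Expression and physiology

FPKM is the closed form 10⁹·c/(N·L). Heatmap normalization is log2(x+1)
followed by per-row z-scoring (the pheatmap convention); constant rows map
to zeros and are flagged. qPCR relative expression is 2^−ΔCt against a
housekeeping reference — the ΔCt method, not ΔΔCt, with fold change
between conditions taken as the ratio of relative expressions. Fold change
uses pseudocount 0 by default and raises on a zero control, naming the
gene; a pseudocount can be configured instead. Concordance between qPCR
and RNA-seq fold changes is the sample Pearson correlation.

Drought-response classes from a fold-change series over post-treatment
timepoints (defaults: up 2, down 0.5, both config-exposed since the
verbal classes carry no thresholds): continuously induced ⇔ above the up
threshold at every timepoint; induced ⇔ at ≥ 1; repressed ⇔ below the
down threshold at ≥ 1 and never above; otherwise unchanged. A series both
above and below resolves to induced.

Group comparisons use the equal-variance two-sample Student's t (Welch
behind a flag), two-tailed, with `**` for p < 0.01 and `*` for p < 0.05.
Survival is 100·survived/total; relative water content is
100·(FW−DW)/(TW−DW) with out-of-range fresh weights flagged but still
computed; stomatal summaries warn when n ≤ 50 stomata (strictly more than
50 expected per sample).

## The synthetic-data generator

The generator emulates the statistical structure the survey assumes, not
cotton biology. All family proteins derive from one family-wide template:
subfamily templates diverge from it (20% substitution inside the 60-residue
kinase-domain core — the subfamily signature — and 25% in the flanks), and
each member diverges from its subfamily template (5% in the core, 30% in
the flanks). These rates were chosen once so that (i) every member's core
still scores far above the domain threshold, (ii) non-duplicate pairs sit
well below the 70% identity rule (≈ 55–60% with ≈ 4–6 σ of margin over
all pairwise comparisons), and (iii) within-subfamily distances are
clearly smaller than between-subfamily distances, so the NJ tree separates
subfamilies cleanly. Planted duplication partners are copies of a source
member with flank-only 5% mutation (identity ≈ 92%, coverage ≈ 1). Decoys
are i.i.d. random proteins.

Genes are reverse-translated with a fixed codon table and placed on
chromosomes named A01…/D01… with intergenic gaps of 5000 bp (2500 bp
inside tandem pairs, which are placed immediately adjacent with no
intervening gene and on one strand so both promoters fit). Exon counts
are 2–5 except for the planted intronless genes. Promoters carry exactly
the planted ABRE/DRE occurrence counts: elements are instantiated from
their IUPAC patterns (random strand), placed well separated, and
background windows producing accidental dictionary matches are resampled
until a scan returns exactly the planted hits — counts are exact by
construction, not statistical. Under the defaults roughly 60% of family
genes carry ABREs (2–6 each, mean ≈ 4) and 15% carry one DRE, mirroring
the proportions such surveys report.

The drought time course covers 0, 2, 4, 6, 8 days with three replicates;
planted profiles use fixed multipliers (continuous 2.8/4/6/9, induced
3.5/4.5/1.2/1, repressed 0.35/0.3/0.4/0.35, unchanged ≈ 1) with
log-normal replicate noise of 0.1 log2 units — the generating noise model
is a stand-in, since published tables give no noise model, and is
config-exposed. Counts are derived from FPKM at library size 2×10⁷ and
rounded; the emitted FPKM table is recomputed from those rounded counts so
the two tables are exactly consistent. Ct tables hold the reference gene
constant at 25 cycles. The physiology table has three genotypes
(control and two silenced) × control/drought × three replicates with 4%
noise, silenced-under-drought means shifted in the directions drought
studies report (MDA up; proline, SOD, POD, RWC down; stomatal ratio up),
and planted survival of 12/12, 8/12 and 6/12.

One RNG stream per artifact class (proteins, placement, promoters,
expression, physiology), all derived from the master seed, keeps each
artifact stable when another is added. Identical seeds give byte-identical
files.

What passing on this generator does **not** show: robustness to real
codon usage and splice signals, to length variation and domain
architecture diversity within a family, to alignment ambiguity in
low-complexity regions, to read-level quantification noise, or to
promoter base composition bias. Those require real data.

## Scale choices

Default test and acceptance runs use the 40-member / 60-decoy family, 100
bootstrap replicates where supports are measured (the full default is
1000), 200 random additive trees for NJ verification, and 10–20 EM seeds
for motif recovery. These sizes make the whole verification suite run in
tens of seconds while keeping every statistical margin (identity
separation, domain-score separation, class thresholds) several sigma wide.

## Known limitations

- Center-star MSA and fixed-width ZOOPS EM are simpler than ClustalX/MEME;
  results on real families will differ in detail from tools with width
  optimization and progressive alignment.
- The duplication screen aligns all pairs (O(n²) alignments); for families
  of thousands of members a pre-filter would be needed.
- Ortholog detection is reciprocal-best-hit only; no collinearity/synteny
  (MCScanX-style) evidence is used.
- The subfamily rule depends on anchors being correctly labelled and on
  the family being monophyletic per subfamily in the estimated tree.
- pI/MW constants differ from ProtParam's; absolute values shift by small
  amounts (documented above).
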