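# kinfam

A genome-wide gene-family survey pipeline for plant kinase families, built
around the workflow used to characterize the MAPKKK (mitogen-activated
protein kinase kinase kinase) family in allotetraploid upland cotton:
screen a proteome for kinase-domain proteins, place the members on a
neighbor-joining phylogeny with bootstrap supports and assign them to the
RAF / MEKK / ZIK subfamilies, detect paralogous gene pairs and classify
them as tandem or segmental duplications, characterize exon/intron
structure and conserved protein motifs, census drought-related promoter
cis-elements (ABRE, DRE), and quantify expression response and
drought-physiology statistics.

Every stage is testable end to end on a synthetic allotetraploid genome
with planted ground truth, so the whole survey can be validated without
downloading a real genome.

## Methods at a glance

- **Family identification** — a log-odds PSSM built from trusted aligned
  kinase-domain cores; membership = at least one window with score above a
  fraction (default 60%) of the consensus score. Protein length, molecular
  weight (average residue masses + one water) and isoelectric point
  (Henderson–Hasselbalch net charge, EMBOSS pKa set, bisection) are
  computed per member.
- **Phylogeny** — center-star multiple alignment (BLOSUM62, affine gaps),
  p-distance `d(i,j) = mismatches / shared non-gap columns` (optional
  Poisson correction `−ln(1−p)`), Saitou–Nei neighbor joining with the
  `Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)` criterion, and
  column-bootstrap supports mapped onto the original tree. Subfamilies come
  from the smallest anchored single-label clade containing each query.
- **Duplication** — a gene pair is a duplication pair when the global
  alignment covers > 70% of the longer gene *and* shows > 70% identity
  (both strict). Different chromosomes ⇒ segmental; adjacent on one
  chromosome ⇒ tandem. Orthologs across genomes are reciprocal best hits.
- **Motifs** — ZOOPS (zero-or-one occurrence per sequence)
  expectation-maximization with seeded multi-starts, phase-shift
  refinement, and sequential erasure between motifs.
- **Promoters** — 2 kb upstream of the TSS, strand-aware, scanned against
  an IUPAC dictionary (ABRE core `ACGTG`, DRE core `RCCGAC`) on both
  strands.
- **Expression / physiology** — FPKM `= 10⁹·c/(N·L)`; qPCR relative
  expression `2^−ΔCt` against a housekeeping control; fold change as the
  treated/control ratio; drought-response classes from fold-change series
  (induced / repressed / continuously induced / unchanged); qPCR↔RNA-seq
  concordance as Pearson R; pooled-variance Student's t with `*`/`**`
  stars; survival %, relative water content `100·(FW−DW)/(TW−DW)`, and
  stomatal length/width ratios.

## Worked example

Simulate the default synthetic survey (40 family members split 20/12/8
across subfamilies, 10 segmental + 3 tandem planted duplication pairs,
5 intronless genes, 60 decoy genes) and run every stage over it:

```python
from kinfam.simulate import FamilySimConfig, simulate_all
from kinfam.pipeline import run_survey, validate_report

config = FamilySimConfig(seed=7)
truth = simulate_all(config, "survey_demo")
report = run_survey(truth.files, seed=7, bootstrap_replicates=100)
```

Printing the headline report fields gives:

```
members: 40
subfamilies: {'MEKK': 12, 'RAF': 20, 'ZIK': 8}
subgenomes: {'A': 23, 'D': 17}
duplication pairs: 13 (10 segmental, 3 tandem)
intronless: 5
ABRE-positive genes: 24 mean per positive gene: 3.96
drought classes: {'continuously_induced': 3, 'induced': 8, 'repressed': 4, 'unchanged': 25}
mismatches vs truth: 0
```

Reading the numbers: all 40 planted family members (and none of the 60
decoys) pass the kinase-domain screen; the tree assigns every member to
its planted subfamily; the dual > 70% rule finds exactly the 13 planted
duplication pairs and the chromosome test separates the 10 segmental from
the 3 tandem ones; the 5 planted single-exon (intronless) MEKK-like genes
are recovered; the promoter scan returns exactly the planted ABRE/DRE
occurrences (about 4 ABREs per ABRE-positive gene, mirroring the structure
such surveys report); and the fold-change classifier reproduces every
planted drought-response label. `validate_report` compares the report
against the truth table field by field — an empty list is perfect
recovery.

The same run is available from the shell:

```sh
kinfam run --config survey.yaml --out outdir --seed 7 --bootstrap 100
```

where `survey.yaml` may contain a `simulate:` block (synthetic data) or a
`files:` block pointing at a real genome FASTA, GFF3, proteome and anchor
sequences. Subcommands `kinfam simulate` and `kinfam validate` expose the
generator and the truth-table comparison separately.

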