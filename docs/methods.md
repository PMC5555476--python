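# Methods

## Fold-change normalization

Raw guide readcounts are pseudocounted (+0.5 reads) *before* depth scaling,
then each sample is scaled so its pseudocounted counts sum to the target
depth (default 10⁷ reads).  Fold-change is log2(endpoint/control) per guide
per replicate.  Ordering the pseudocount before scaling makes the per-sample
totals exact and guarantees finite fold-changes; the alternative ordering
differs only at counts comparable to the pseudocount.  Depth scaling is
per-sample (each sample gets its own size factor), which is what
"normalizing each sample to N reads" means literally; it is not a median-of-
ratios estimator and assumes no extreme composition shifts beyond the
dropout signal itself.

Guides with fewer than 30 *raw* reads in the control (T0 or plasmid) sample
are excluded, once per screen, for all replicates and timepoints.  A single
shared control per screen is assumed; screens with per-replicate controls
should be split into separate screens upstream.

## Bayes-factor essentiality classifier

The classifier follows the BAGEL family.  Training data are the retained
guide×replicate fold-changes of the reference essential and nonessential
gene sets.  Each bootstrap iteration resamples reference *genes* (not
guides) with replacement per class, fits a Gaussian KDE (Scott bandwidth) to
each training pool, and scores every gene as the sum over its fold-changes
of log2(f_ess/f_non).  The reported BF is the mean over iterations
(default 1000; tests and the synthetic panel use 5–100, which is enough for
the ~0.1-BF-unit stability those checks need).  Numerical guards: density
evaluation is clamped to the training fold-change range (configurable via
`fc_eval_bounds`) and densities are floored at 1e−12, so a single outlying
guide cannot contribute ±∞.  Gene bootstrap requires at least 20 reference
genes per class with retained guides (`min_ref_genes`); below that the KDE
and the bootstrap variance estimates are unreliable and the classifier
refuses to run.  All randomness flows from one seed (default 1934) through
`numpy.random.default_rng`, making runs bit-reproducible.

Precision-recall is computed over reference genes only, ranked by
descending BF: precision = TP/(TP+FP), FDR = 1 − precision,
recall = TP/(scored essentials).  The FDR attached to a BF threshold is
1 − precision at the smallest cutoff still ≥ the threshold; the estimator is
a design choice, made per screen (not panel-wide).

Posterior conversion is exact arithmetic:
`odds = BF + log2(p/(1−p))`, `prob = 2^odds/(1+2^odds)`, default prior
p = 0.1 (the empirical fraction of essential genes in a typical cell line).

### Core-essential calling

A gene is assayed in a screen when ≥3 of its guides were scored there,
eligible when assayed in ≥7 screens, and core when called essential
(BF ≥ 6 in a screen whose FDR at that threshold is ≤3%) in at least
⌈0.85 × screens_assayed⌉ screens.  The ceiling reproduces the "all but one"
behaviour for panels of 7–12 screens; at 20+ screens it allows
proportionally more misses, which is the intended reading of the 85% rule.

## Positional sequence score

Within each sample (each endpoint replicate of each screen), core genes
with *exactly six* retained guides are split into the three most-depleted
("best") and the remaining three ("worst") guides, ties broken by guide
sequence so the split is deterministic.  Nucleotide frequencies at each of
the 20 protospacer positions (position 20 = PAM-proximal) are pooled over
all qualifying genes, not averaged per gene; Δ = freq_best − freq_worst.
Δ-tables are summed over samples and scaled by the maximum absolute cell,
so the extreme cell is ±1 (the anchor keeps its sign; among tied extremes
the positive one is recorded as anchor).  Cells never observed in either
pool across all samples carry no evidence and are set to −1, generalizing
the special case of libraries that exclude T in the last four positions:
the penalty keeps designed guides away from compositions the training data
cannot vouch for.  A guide's score is the plain sum of its 20 cell weights.

Validation splits essential-targeting guides at the score quartiles and
compares mean-across-replicate fold-changes of top vs bottom quartile by a
two-sided Welch T-test (the test statistic is a choice; the source only
says "T-test").  Degenerate zero-variance inputs yield p = NaN rather than
an exception, so panel sweeps can continue.

## Library design

Candidates are every 20-mer adjacent to an NGG PAM, on either strand, whose
blunt SpCas9 cut (between protospacer positions 17 and 18, 3 bp 5′ of the
PAM) falls inside a coding exon — both bases flanking the cut must be
exonic.  One canonical transcript per gene (longest total CDS, ties by
transcript id) defines the coding exons, numbered ascending from the
transcription start site.  Coordinates are 0-based half-open internally and
1-based in emitted tables.

Filters: GC in [0.40, 0.75] (inclusive); no single-nucleotide run ≥4 in the
protospacer; none of the cloning restriction sites AgeI (ACCGGT), KpnI
(GGTACC), BveI/BspMI (ACCTGC), BsmI (GAATGC), BsmBI (CGTCTC) in
protospacer+PAM on either strand (cloning-context flanks are out of scope);
no supplied variant position overlapping protospacer or PAM.

Off-target search finds all genomic sites with an exact NGG PAM and ≤2
mismatches across the 20-mer (the PAM "N" is free, the GG is required).
Site location is judged by its cut site: inside the target gene's body
(exons+introns) it is a target hit; inside any other gene's body the guide
is excluded outright; otherwise it is an intergenic off-target.  Classes:
1 = ≥2 target hits, no off-targets; 2 = unique clean hit; 3 = 1–2
intergenic off-targets; 4 = exactly 3; more excludes.  Target-gene
multi-hits never count against the off-target budget.  The production
search uses a vectorised site index (all NGG sites encoded as byte
matrices); an independent exhaustive scanner in the synthetic module serves
as its oracle in tests.

Ranks (first tier that admits the candidate):
rank 1 = class 1, score > 0; rank 2 = classes 1–3, score > 0.85;
rank 3 = classes 1–4, score > 0.85; rank 4 = classes 1–3, score in
[0, 0.85]; rank 5 = classes 1–4, score in [−1, 0.85].  Boundary values
(score exactly 0 or 0.85) fall to the inclusive lower tiers.

Selection iterates ranks 1→5; within a rank it runs rounds in which every
gene below its 4-guide quota picks its highest-scoring remaining candidate,
preferring exons without a selected guide and falling back to
already-targeted exons only when the rank offers no fresh-exon candidate.
This reconciles the two published descriptions of the procedure (per-exon
top pick vs. quality-first): exon diversity is a hard per-round preference,
not a hard constraint.  Ties break by lower exon number then lexicographic
protospacer; a protospacer shared between genes goes to the earlier gene
and the conflict is logged.  The procedure is fully deterministic.

## Synthetic data

The genome generator lays out non-overlapping multi-exon genes (default 3
coding exons of 120 bp with 80-bp introns) on uniform-random chromosomes,
then plants mutated copies of real exonic candidate protospacers (with an
AGG PAM) into intergenic gaps or introns, avoiding overlap between plants.
Truth tables list every on-target and planted site.  SNPs are uniform at a
configurable density.

The screen generator draws T0 counts from a negative binomial around
uniform abundance (variance μ + μ²/r, r = 10 by default — standard count
overdispersion; the source experiments imply no specific noise model), then
multiplies essential-gene guide abundance by 2^(−effect·efficiency) and
resamples endpoint counts at the same depth.  Efficiency is
logistic(1.5·score) against a planted score table whose columns are
zero-centred like a real Δ-frequency table, so random guides span
efficiencies ≈0.01–0.99 over a ±4 score range; without a planted table
efficiency is 1.  Defaults: 10% essential genes (matching the prior), 4
guides/gene, 3 replicates, depth 10⁷, effect 3 log2 units.

What the generator does **not** emulate: PCR and infection bottlenecks,
copy-number-driven multi-cut toxicity, chromatin effects on cutting, guide
cross-contamination, or realistic human sequence composition.  Passing
tests therefore demonstrate correctness of the algorithms under a clean
negative-binomial dropout model, not performance on real screens.

## Problem sizes in the test suite

Tests run the classifier at 2–100 bootstrap iterations on screens of
150–300 genes, the off-target oracle comparison on fifty 5-kb genomes, and
the panel study on twelve 300-gene screens — sizes at which every check is
exercised end-to-end while the whole suite stays interactive.  The
acceptance script derives its score table from a 60-gene, 6-guides-per-gene
screen (360 guides).

## Known limitations

* Chemogenomic (drug vs. control) scoring is out of scope; only fitness
  dropout is modelled.
* The fold-change masking rule assumes one shared control per screen.
* Gene symbols are exact case-sensitive strings; no alias resolution.
* The designer evaluates one canonical transcript per gene; guides in
  alternative exons of other isoforms are not considered.
* Genome-scale design on a full mammalian genome is supported by the same
  code paths but the off-target index is held in memory; expect several GB
  for hg-scale genomes.
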