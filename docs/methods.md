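# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the package. It describes what the code computes, in
the package's own terms; every number quoted here is produced by the test
suite or the analysis scripts.

## The workflow and its assumptions

The pipeline treats deep-sequenced small RNA libraries as a random sample
of the cellular small RNA pool. Counts of a mature miRNA are therefore
modelled as Poisson draws, which licenses the Audic–Claverie conditional
test for two-library comparisons without replicates. Four libraries are
analysed (2 genotypes × 2 growth conditions), each a single pooled
library; no replicate-level dispersion is modelled, so the p-values
measure sampling variability only, not biological variability. This is an
intrinsic property of the experimental design the package emulates, not a
fixable implementation detail.

miRNA annotation follows structural plant-miRNA criteria rather than
homology: a genomic window around an abundantly sequenced read must fold
into a stem-loop with low free energy, present the read in a clean
duplex with an inferable passenger strand (miRNA\*), and carry the read
evidence expected from precise Dicer processing (strand bias and
mature/star concentration). Thresholds:

| parameter | default | unit | origin |
| --- | --- | --- | --- |
| anchor redundancy | 10 | copies, summed over libraries | annotation rule |
| window lengths | 100–300, step 20 | nt | annotation rule |
| anchor offset | 10 | bp beyond read | annotation rule |
| ΔG ceiling | −35 | kcal/mol | criterion 1; configurable because absolute energies are backend-dependent |
| duplex mismatches | ≤ 4 | positions | criterion 2 |
| asymmetric bulges | ≤ 1 of size ≤ 2 | per stem | criterion 3 |
| strand bias | ≥ 0.80 | fraction of mapped reads | criterion 4 |
| precise processing | ≥ 0.75 | fraction in mature/star ± 2 nt | criterion 5 |

Interpretation choices where the rules are underdetermined (all
configurable):

- *Window anchoring*: "one end anchored 10 bp from the mapped position" is
  read as 10 bp of flank beyond the read on the anchored side, and both
  left- and right-anchored windows are generated for every length;
  both-sided enumeration dominates any single-sided reading.
- *Anchor scope*: the 10-copy redundancy is summed across all four
  libraries.
- *Mature assignment*: the anchor read's interval is the putative mature;
  other read stacks inside the window are not promoted.
- *Multi-mapped reads* count once per window — attributed to the hairpin
  strand if any of their hits lies there — so a read mapping both arms of
  a near-perfect inverted repeat does not poison the strand-bias
  criterion.
- *Strand bias* uses every read overlapping the window; *precise
  processing* uses reads fully contained in it.
- *Mature expression* (the first key of the best-hairpin choice) is the
  summed count of sense reads processed to exactly the mature interval.
- *Region collapse* happens after criterion filtering; a region is a
  connected set of overlapping passing windows on one reference strand.
- *Gene deduplication* merges genes with identical matures whose
  precursors are identical or mutually contained at >= 90% identity over
  the shorter sequence.

## Folding backends

The bundled backend is a Zuker-style MFE dynamic program over a simplified
Turner-style nearest-neighbour model: a 6×6 stacking table for
Watson–Crick and G:U pairs, tabulated hairpin/bulge/interior loop
penalties with logarithmic extrapolation (1.75·RT at 37 °C), a linear
multiloop model (a = 3.4, b = 0.4 per branch, c = 0.1 per unpaired
nucleotide), interior loops bounded at 12 unpaired nucleotides, no
pseudoknots, and no dangling-end or terminal-mismatch terms. It is
numba-compiled; a 300-nt window folds in tens of milliseconds.

Absolute energies from such a reduced parameter set differ from full
Turner-parameter implementations, which is why the −35 kcal/mol threshold
is configurable and why the contract between backends is *classification
agreement at the threshold*, not numeric equality. The test suite folds 50
synthetic hairpins of varying stem quality with both the bundled model and
ViennaRNA and requires >= 90% pass/fail agreement. The miRNA\* is located
from the pairing table as the positions paired to the mature, shifted to
model the canonical Dicer 2-nt 3' overhang on each duplex strand; a mature
with under 60% of its positions paired (e.g. lying in the terminal loop)
has no star and the candidate fails.

Duplex mismatches are counted by walking consecutive paired mature
positions: each inter-pair gap contributes max(mature-side gap, star-side
gap) — so symmetric internal loops count once per column and bulges count
per their size — plus unpaired mature end positions. Asymmetric bulges are
gaps whose two sides differ; their size is the difference.

## The synthetic experiment

The generator emulates the study conditions at desk scale: four libraries
(2 genotypes × 2 conditions) of 200,000 reads each, 20 planted miRNA
genes, 3 genotype-specific (near-zero counts — 0 to 2 expected reads — in
the off genotype), 5 drought-upregulated and 3 drought-downregulated at
|log2 fold change| = 2 in both genotypes, base abundances log-uniform on
100–1500 expected reads per library (regulated miRNAs >= 200 so the power
property is well defined), star reads at 10% of mature abundance, 10%
imprecise reads (ends shifted ±1–2 nt with decaying probability, keeping
the stack within the ±2-nt precise-processing margin), 25% contaminant
reads drawn from generated rRNA/tRNA/snRNA/snoRNA/repeat sets, 15%
degradation reads (95% from stacked "hotspot" fragments of decoy expressed
loci — these create anchor-worthy read stacks at non-miRNA loci and are
the false-positive challenge — and 5% thinly spread over precursor
bodies, which stress the precise-processing criterion), and the remainder
random unmappable background. Every read carries the 3' adapter before
truncation to the 36-nt read length.

Planted precursors are constructed as
flank – extension stem – mature – loop – star – extension stem – flank:
the star is the reverse complement of the mature with 1–2 genuine
mismatches (at least one, so the mature never maps exactly onto its own
star arm — a perfect inverted repeat would map on both strands and
dilute the strand bias of its own locus), the loop is 8–15 nt of A/C (no
self-pairing), the 12-bp perfect extension stem gives the hairpin a
comfortable energy margin under both folding backends, and flanks are
20–60 nt of GC-0.45 random sequence. Construction is rejection-sampled:
a candidate precursor is accepted only if all five criteria pass under
the bundled backend with a nominal clean read stack. Loci are embedded on
random strands, separated by > 600 nt so 300-nt windows from neighbouring
loci can never merge into one region.

What the generator does **not** emulate: sequencing errors and quality
profiles, genotype SNPs outside the planted matures, multi-locus miRNA
families with near-identical matures, expression-dependent Dicer
imprecision, or replicate structure. Passing the recovery test therefore
shows the pipeline logic is correct under idealized reads, not that it is
robust to base-calling noise.

## Differential expression and PCA

TPTM = count / clean-library-total × 10⁷; clean totals are the post-trim
read counts (contaminants are removed from the unique-read set after the
totals are fixed). The Audic–Claverie conditional probability is evaluated
in log space (gammaln terms); the accumulated probability q sums the lower
tail by log-sum-exp, and when q > ½ the p-value is computed as twice the
*upper* tail, summed directly in log space, rather than as 2(1−q) — the
subtraction would lose all precision for extreme counts. For x + y >
10,000 the algebraically identical negative-binomial form (size x+1,
probability N₁/(N₁+N₂)) takes over via scipy. Both routes are checked
against a brute-force term-recurrence oracle on 1000 random instances
(agreement ~1e−12 relative; instances whose leading term denormalizes in
float64 are outside the oracle's domain and excluded). Bonferroni uses
m = number of unique matures tested per comparison.

Classification: "associated" requires all three criteria; the direction
comes from the sign of the TPTM change in the genotype(s) passing the
p-threshold, and records where the two genotypes' significant changes
disagree are flagged discordant rather than resolved. A log2 ratio with a
zero count on either side is N/A: it fails two-fold checks but does not
veto association established by the other genotype. Two-fold patterns use
|log2| >= 1.

PCA: rows with combined TPTM < 50 are dropped, the matrix is
log2(TPTM + 1) (the pseudocount handles the zeros that genotype-specific
miRNAs produce), libraries are observations, miRNA columns are centered,
and the decomposition is by SVD. With four observations at most three
components exist; variance fractions are reported over those. The ranked
squared PC1 loadings with cumulative fractions are exported so the user
can choose their own cut for "miRNAs dominating PC1" — the cumulation rule
is genuinely ambiguous and is left as a reported table, not a decision.

## Published-table reanalysis

The bundled TPTM tables (genotype-specific miRNAs; two-fold change only in
the tolerant genotype, 12 rows; only in the sensitive genotype, 10 rows)
are re-analysed from their printed TPTM values alone: the two-fold rule
with N/A handling reclassifies all 12 and all 10 rows identically. The
printed log2 columns were evidently computed from raw counts before TPTM
rounding, so recomputation from the rounded TPTM matches the printed value
at 2 decimals only for a subset of rows; five anchor rows (miR1515 in the
tolerant genotype; miR166a, miR2111a, miR393, miR482 in the sensitive one)
are consistent both ways and are the frozen reproduction check.

## Problem sizes and determinism

The default verification runs use 20 planted miRNAs at 200,000 reads per
library (the full pipeline completes in about a minute), a reduced
6-miRNA/30,000-read design for per-stage tests, 1000 random instances for
the statistical oracle and 10,000 for the scoring oracle. All randomness
flows from numpy `default_rng` seeded by the design seed or the
acceptance-script `--seed`; identical seeds give byte-identical simulated
files and tables.

## Known limitations

- The bundled energy model has no dangling ends, coaxial stacking or
  special hairpin loops; its absolute ΔG values are typically a few
  kcal/mol above ViennaRNA's on the same structure.
- Mapping is exact-match (with a k <= 2 substitution mode for control
  analyses); there is no spliced or gapped alignment.
- The site scan enumerates alignments with at most one single-nucleotide
  bulge per site. This is exhaustive for the acceptance rule (a second
  indel or a multi-nucleotide bulge is auto-rejected) but alignments that
  would be rejected anyway are not produced.
- Region collapse assumes loci whose candidate windows overlap are the
  same transcriptional unit; tandem miRNAs within ~300 nt would be merged
  into one gene.
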