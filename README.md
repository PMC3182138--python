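# vunmir

Small RNA-seq miRNA discovery and digital expression analysis for
two-genotype drought experiments, modelled on the cowpea (*Vigna
unguiculata*) comparison of a drought-tolerant (IT93K503-1) and a
drought-sensitive (CB46) genotype under well-watered and drought
conditions.

The package is for people who want a fully testable, self-contained
version of the classic plant miRNA deep-sequencing workflow:

1. **Read preprocessing** — 3' adapter trimming (reads without a clear
   adapter are rejected, inserts must be >= 18 nt), collapsing into unique
   reads with per-library counts, removal of reads matching
   rRNA/tRNA/snRNA/snoRNA/repeat annotations on either strand, and perfect-
   match mapping to reference sequences (bounded-substitution mapping for
   control analyses).
2. **Hairpin discovery** — unique reads with >= 10 copies anchor candidate
   precursor windows of 100–300 nt (20-nt steps, one end 10 bp beyond the
   read); each window is folded (bundled Zuker-style nearest-neighbour MFE
   model; ViennaRNA pluggable) and kept only if it passes five criteria:
   ΔG <= −35 kcal/mol; <= 4 miRNA/miRNA\* duplex mismatches; <= 1
   asymmetric bulge of size <= 2 in the stem; >= 80% of mapped reads on the
   hairpin strand; and >= 75% of precursor reads inside the mature/star
   regions (± 2 nt). Overlapping candidates form a region; the best hairpin
   (highest mature expression, lowest ΔG, shortest window) represents it.
3. **Family annotation** — single-linkage clustering of matures at <= 2
   alignment mismatches; clusters inherit the family number of a
   miRBase-style match within 2 mismatches, otherwise found a new
   `vun_candNNN` family.
4. **Target prediction** — exhaustive site scan and a position-dependent
   penalty: mismatch/bulge/gap = 1, G:U = 0.5, doubled in the core region
   (miRNA positions 2–13); accepted if penalty <= 4 and bulges + gaps < 2.
5. **Expression statistics** — TPTM normalization
   (count / clean reads × 10⁷), the two-tailed Audic–Claverie test

   p(y|x) = (N₂/N₁)^y · (x+y)! / (x! y!) / (1 + N₂/N₁)^(x+y+1),
   p = 2q (or 2(1−q) for q > ½), q = Σ_{y'≤y} p(y'|x)

   with Bonferroni adjustment; drought-associated classification
   (p_adj < 0.01 in a genotype, TPTM >= 100 in a library, |log2
   drought/control| > 1 in a genotype); two-fold-pattern labelling; and
   PCA of log2 TPTM for miRNAs with >= 50 combined TPTM.

Because the original sequencing data and cowpea sequence resources are not
required, a **synthetic-data module** generates the whole experiment:
a reference with planted miRNA hairpins (constructed to pass all five
criteria), decoy expressed loci, contaminant loci, and four seeded read
libraries with designed abundances, genotype-specific miRNAs, drought fold
changes, adapters and contamination. Every pipeline stage is tested
against this ground truth.

## Worked example

```python
from vunmir.pipeline import run_pipeline, evaluate_recovery
from vunmir.synthetic import SyntheticDesign

result = run_pipeline(SyntheticDesign(seed=7))
print(evaluate_recovery(result))
print(result.differential[["mature", "associated", "direction"]].head())
```

The numbered scripts under `analysis/` run the same workflow step by step
and write their tables under `results/`. On the default design
(20 planted miRNAs, 200,000 reads per library, seed 7) they print:

```
predicted genes: 20 in 20 families
recall of planted matures: 1.00; precision: 1.00
drought-associated: 8 (5 up, 3 down)
PCA on 20 miRNAs: PC1 90.7%, PC1+PC2 98.9% of variance
only_IT93K503-1: 12/12 rows reclassified identically
only_CB46: 10/10 rows reclassified identically
```

meaning: every planted hairpin was rediscovered with no false calls at
decoy or contaminant loci; the eight matures simulated with a four-fold
drought change were all classified drought-associated with the designed
directions; genotype dominates the expression variance exactly as designed;
and the bundled published expression tables reclassify identically from
their TPTM values alone.

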