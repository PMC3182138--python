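#!/usr/bin/env python
"""Quantify miRNAs, test drought differential expression, and run PCA.

Counts every predicted mature per library, normalizes to TPTM using the
clean-read totals, runs the two-tailed Audic-Claverie test (drought vs
control within each genotype) with Bonferroni adjustment, classifies
drought-associated miRNAs by the three criteria (adjusted p < 0.01,
TPTM >= 100 somewhere, |log2 ratio| > 1 in a genotype), labels two-fold
patterns, re-checks apparent genotype-specific miRNAs by one-mismatch
re-mapping to their precursors (the SNP control), and performs PCA on
log2 TPTM (combined expression >= 50).  Writes results/ tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from vunmir.preprocess import read_unique_tsv
from vunmir.seqs import read_fasta
from vunmir.stats import (
    classify_drought_associated,
    pc1_contributions,
    pca_expression,
    quantify_mature,
    tptm_matrix,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    results = ROOT / "results"

    reads, lib_ids = read_unique_tsv(ROOT / "scratch" / "unique_reads.tsv")
    totals = (
        pd.read_csv(results / "preprocess_summary.tsv", sep="\t")
        .set_index("library")["clean_reads"]
        .to_dict()
    )
    genes = pd.read_csv(results / "predicted_genes.tsv", sep="\t")
    matures = {
        row.gene: row.mature.replace("U", "T") for row in genes.itertuples()
    }
    # one mature per unique sequence (identical matures from homologous
    # genes are tested once)
    unique_matures: dict[str, str] = {}
    for gid, seq in matures.items():
        if seq not in unique_matures.values():
            unique_matures[gid] = seq

    counts = quantify_mature(reads, unique_matures, lib_ids)
    tm = tptm_matrix(counts, totals)
    table = classify_drought_associated(counts, totals)
    table.insert(0, "mature", [unique_matures[i] for i in table.index])
    table.to_csv(results / "differential_expression.tsv", sep="\t")

    # SNP re-check: one-mismatch re-mapping to precursors must not change
    # the picture for apparently genotype-specific miRNAs
    precursors = read_fasta(results / "predicted_precursors.fa")
    intervals = {}
    for row in genes.itertuples():
        seq = precursors[row.gene]
        m = row.mature.replace("U", "T")
        start = seq.find(m)
        intervals[row.gene] = (start, start + len(m))
    relaxed = quantify_mature(
        reads,
        unique_matures,
        lib_ids,
        mode="one_mismatch_to_precursor",
        precursors={g: precursors[g] for g in unique_matures},
        mature_intervals=intervals,
    )
    drift = (relaxed - counts).abs().to_numpy().sum()

    n_assoc = int(table["associated"].sum())
    n_up = int((table["associated"] & (table["direction"] == "up")).sum())
    n_down = int((table["associated"] & (table["direction"] == "down")).sum())
    print(f"tested matures: {len(table)}")
    print(f"drought-associated: {n_assoc} ({n_up} up, {n_down} down)")
    print("two-fold patterns:", table["two_fold_pattern"].value_counts().to_dict())
    print(f"one-mismatch re-mapping changed counts by {drift} reads in total")

    try:
        pca = pca_expression(tm)
        pca.scores.to_csv(results / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(results / "pca_loadings.tsv", sep="\t")
        pc1_contributions(pca).to_csv(results / "pca_pc1_contributions.tsv", sep="\t")
        fr = pca.variance_fractions
        print(
            f"PCA on {len(pca.retained)} miRNAs: "
            f"PC1 {100 * fr[0]:.1f}%, PC1+PC2 {100 * fr[:2].sum():.1f}% of variance"
        )
    except ValueError as exc:
        print(f"PCA skipped: {exc}")


if __name__ == "__main__":
    main()
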