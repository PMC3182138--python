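#!/usr/bin/env python
"""Predict miRNA genes and annotate families.

Maps the clean unique reads to the synthetic reference, folds candidate
windows around anchor reads (>= 10 copies), applies the five hairpin
criteria, picks the best hairpin per region, deduplicates genes, clusters
the mature sequences into families and compares the predictions with the
planted ground truth.  Writes per-gene and family tables plus precursor /
mature FASTA files under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from vunmir.families import assign_family_names, cluster_families
from vunmir.hairpin import predict_from_reads
from vunmir.preprocess import read_unique_tsv
from vunmir.seqs import read_fasta, to_rna, write_fasta
from vunmir.synthetic import SyntheticDesign, design_truth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)  # matches 01_simulate
    args = ap.parse_args()

    reads, _libs = read_unique_tsv(ROOT / "scratch" / "unique_reads.tsv")
    reference = read_fasta(ROOT / "scratch" / "simulated" / "reference.fa")
    genes, candidates = predict_from_reads(reads, {"genome": reference})

    matures = []
    for g in genes:
        if g.mature_seq not in matures:
            matures.append(g.mature_seq)
    clusters = assign_family_names(cluster_families(matures), {})
    family_of = {m: c.name for c in clusters for m in c.members}

    rows = []
    for g in genes:
        c = g.precursor
        rows.append(
            {
                "gene": g.id,
                "family": family_of[g.mature_seq],
                "reference": c.reference_id,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "mature": to_rna(g.mature_seq),
                "star": to_rna(g.star_seq or ""),
                "delta_g": round(c.fold.delta_g, 2),
                "duplex_mismatches": c.criteria.duplex_mismatches,
                "asym_bulges": c.criteria.n_asym_bulges,
                "strand_bias": round(c.criteria.strand_bias, 3),
                "precise_fraction": round(c.criteria.precise_fraction, 3),
                "mature_expression": c.mature_expression,
            }
        )
    table = pd.DataFrame(rows)
    results = ROOT / "results"
    table.to_csv(results / "predicted_genes.tsv", sep="\t", index=False)
    write_fasta(
        results / "predicted_precursors.fa",
        ((g.id, g.precursor.sequence) for g in genes),
    )
    write_fasta(
        results / "predicted_matures.fa", ((g.id, to_rna(g.mature_seq)) for g in genes)
    )
    with open(results / "predicted_structures.txt", "w") as fh:
        for g in genes:
            fh.write(f">{g.id}\n{g.precursor.sequence}\n{g.precursor.fold.structure}\n")

    truth = design_truth(SyntheticDesign(seed=args.seed))
    planted = {p.mature_seq for p in truth.planted}
    predicted = {g.mature_seq for g in genes}
    recall = len(planted & predicted) / len(planted)
    precision = sum(1 for g in genes if g.mature_seq in planted) / max(len(genes), 1)

    print(f"passing candidate windows: {len(candidates)}")
    print(f"predicted genes: {len(genes)} in {len(clusters)} families")
    print(f"recall of planted matures: {recall:.2f}; precision: {precision:.2f}")


if __name__ == "__main__":
    main()
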