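#!/usr/bin/env python
"""Trim adapters, collapse reads and remove annotated contaminants.

Reads the FASTQ libraries written by 01_simulate.py, trims the 3' adapter
(rejecting reads without a clear adapter or with inserts < 18 nt),
collapses inserts into unique reads with per-library counts, and removes
reads matching rRNA/tRNA/snRNA/snoRNA/repeat annotations on either strand.
Writes the collapsed unique-read table to scratch/ and a per-library
summary to results/preprocess_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from vunmir.preprocess import collapse_unique, filter_annotated, trim_library, write_unique_tsv
from vunmir.seqs import read_fasta, read_fastq_seqs
from vunmir.synthetic import SyntheticDesign

ROOT = Path(__file__).resolve().parents[1]
LIB_IDS = ["IT_C", "IT_D", "CB_C", "CB_D"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)  # matches 01_simulate
    args = ap.parse_args()
    adapter = SyntheticDesign().adapter
    simdir = ROOT / "scratch" / "simulated"

    per_lib, rows = [], []
    for lib in LIB_IDS:
        reads = list(read_fastq_seqs(simdir / f"{lib}.fastq"))
        inserts, rejects = trim_library(reads, adapter)
        per_lib.append(inserts)
        rows.append(
            {
                "library": lib,
                "raw_reads": len(reads),
                "clean_reads": len(inserts),
                **{f"rejected_{k}": v for k, v in rejects.items()},
            }
        )

    unique = collapse_unique(per_lib)
    annotations = {
        f.stem.replace("annotation_", ""): read_fasta(f)
        for f in sorted(simdir.glob("annotation_*.fa"))
    }
    filtered, removed = filter_annotated(unique, annotations)

    write_unique_tsv(ROOT / "scratch" / "unique_reads.tsv", filtered, LIB_IDS)
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "results" / "preprocess_summary.tsv", sep="\t", index=False)

    print(summary.to_string(index=False))
    print(f"unique reads: {len(unique)}; after contaminant removal: {len(filtered)}")
    print("removed unique reads per annotation set:", removed)


if __name__ == "__main__":
    main()
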