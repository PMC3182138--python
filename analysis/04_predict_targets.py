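#!/usr/bin/env python
"""Predict targets for the discovered miRNAs with the penalty scorer.

Builds a small synthetic transcriptome in which some transcripts carry
embedded near-complementary sites (degraded reverse complements of the
predicted matures) and others are unrelated, scans every mature against
every transcript, scores the duplexes with the position-dependent penalty
system (core positions 2-13 doubled) and keeps sites with penalty <= 4 and
fewer than 2 bulges/gaps.  Writes results/predicted_targets.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from vunmir.seqs import read_fasta, revcomp, to_rna
from vunmir.targets import accept_target, scan_sites

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-decoy-transcripts", type=int, default=10)
    args = ap.parse_args()
    rng = np.random.default_rng([args.seed, 4])

    matures = read_fasta(ROOT / "results" / "predicted_matures.fa")
    transcripts: dict[str, str] = {}
    sources: dict[str, str] = {}
    for mid, mseq in matures.items():
        site = list(revcomp(mseq))
        for _ in range(int(rng.integers(0, 3))):  # mild degradation
            site[int(rng.integers(0, len(site)))] = str(rng.choice(list("ACGT")))
        tid = f"tx_{mid}"
        transcripts[tid] = (
            "".join(rng.choice(list("ACGT"), 300))
            + "".join(site)
            + "".join(rng.choice(list("ACGT"), 300))
        )
        sources[tid] = mid
    for d in range(args.n_decoy_transcripts):
        transcripts[f"tx_decoy{d}"] = "".join(rng.choice(list("ACGT"), 600))

    rows = []
    for mid, mseq in matures.items():
        for tid, tseq in transcripts.items():
            for hit in scan_sites(mseq, tseq, tid):
                if accept_target(hit):
                    rows.append(
                        {
                            "mirna": mid,
                            "transcript": tid,
                            "site_start": hit.duplex.site_start,
                            "site_end": hit.duplex.site_end,
                            "penalty": hit.penalty,
                            "n_indels": hit.n_indels,
                            "designed_site": sources.get(tid) == mid,
                            "mature": to_rna(mseq),
                        }
                    )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "results" / "predicted_targets.tsv", sep="\t", index=False)

    designed = int(table["designed_site"].sum()) if len(table) else 0
    print(f"accepted target sites: {len(table)}")
    print(f"of which at designed (planted) sites: {designed} / {len(matures)}")
    if len(table):
        print(f"penalty range: {table['penalty'].min()} .. {table['penalty'].max()}")


if __name__ == "__main__":
    main()
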