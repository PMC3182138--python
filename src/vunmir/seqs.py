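"""Sequence utilities shared across the pipeline.

All internal sequences use the DNA alphabet (U is normalized to T at
ingest); mature miRNAs are converted back to RNA only on output.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Convert an internal DNA-alphabet sequence to RNA for output."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: normalized sequence} dict."""
    return {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_collapsed_fasta(path) -> Iterator[tuple[str, int]]:
    """Yield (sequence, count) from a collapsed FASTA with '<id>-<count>' headers."""
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("-", 1)[1])
        yield normalize(str(rec.seq)), count


def read_fastq_seqs(path) -> Iterator[str]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq).upper()
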