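"""Read preprocessing: adapter trimming, unique-read collapsing, contaminant
filtering, and exact / bounded-mismatch mapping of small RNA reads.

The pipeline keeps one record per distinct insert sequence with a vector of
per-library counts.  Mapping reports every occurrence of a read on either
strand of the reference; minus-strand hits are reported on the plus-strand
interval.  Perfect-match mapping is the default policy; bounded-substitution
mapping (k <= 2, no indels) is used only for the SNP re-check and the scan
against known precursors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqs import normalize, revcomp

MIN_READ_LEN = 18

# reject reason codes for trim_adapter
REJECT_EMPTY = "empty"
REJECT_NO_ADAPTER = "no_adapter"
REJECT_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class Library:
    """One sequencing library (genotype x condition)."""

    id: str
    genotype: str
    condition: str  # "control" | "drought"
    total_clean_reads: int = 0


@dataclass
class UniqueRead:
    """A distinct insert sequence with per-library counts."""

    sequence: str
    counts: np.ndarray  # shape (n_libraries,)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MappingHit:
    read: str
    reference_id: str
    start: int  # 0-based, plus-strand interval
    strand: str  # "+" | "-"
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.read)


def trim_adapter(
    read: str, adapter: str, min_len: int = MIN_READ_LEN, seed_len: int = 8
) -> tuple[str | None, str | None]:
    """Trim the 3' adapter off a raw read.

    The adapter is recognized by an exact match of its first
    ``min(len(adapter), seed_len)`` bases; the insert is the read prefix
    before the leftmost occurrence.  Returns ``(insert, None)`` on success
    or ``(None, reason)`` on rejection.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    read = normalize(read)
    if not read:
        return None, REJECT_EMPTY
    probe = normalize(adapter)[: min(len(adapter), seed_len)]
    pos = read.find(probe)
    if pos < 0:
        return None, REJECT_NO_ADAPTER
    if pos < min_len:
        return None, REJECT_TOO_SHORT
    return read[:pos], None


def trim_library(
    reads: Iterable[str], adapter: str, min_len: int = MIN_READ_LEN
) -> tuple[list[str], Counter]:
    """Trim every read; return kept inserts and a Counter of reject reasons."""
    inserts: list[str] = []
    rejects: Counter = Counter()
    for read in reads:
        insert, reason = trim_adapter(read, adapter, min_len)
        if insert is None:
            rejects[reason] += 1
        else:
            inserts.append(insert)
    return inserts, rejects


def collapse_unique(per_library_inserts: Sequence[Iterable[str]]) -> list[UniqueRead]:
    """Collapse trimmed inserts into unique reads with per-library counts."""
    n_libs = len(per_library_inserts)
    counts: dict[str, np.ndarray] = {}
    for lib_idx, inserts in enumerate(per_library_inserts):
        for seq in inserts:
            row = counts.get(seq)
            if row is None:
                row = counts.setdefault(seq, np.zeros(n_libs, dtype=np.int64))
            row[lib_idx] += 1
    return [UniqueRead(seq, c) for seq, c in counts.items()]


def _substring_set(sequences: Iterable[str], min_len: int, max_len: int) -> set[str]:
    subs: set[str] = set()
    for seq in sequences:
        for strand_seq in (seq, revcomp(seq)):
            n = len(strand_seq)
            for L in range(min_len, max_len + 1):
                for i in range(n - L + 1):
                    subs.add(strand_seq[i : i + L])
    return subs


def filter_annotated(
    reads: Sequence[UniqueRead],
    annotation_sets: Mapping[str, Mapping[str, str]],
) -> tuple[list[UniqueRead], dict[str, int]]:
    """Remove reads occurring exactly (either strand) inside any annotation
    sequence (rRNA/tRNA/snRNA/snoRNA/repeats).

    Returns the kept reads and removed unique-read counts per annotation set.
    A read matching several sets is attributed to the first matching set.
    """
    if not annotation_sets:
        return list(reads), {}
    lens = [len(r.sequence) for r in reads]
    lo, hi = (min(lens), max(lens)) if lens else (MIN_READ_LEN, MIN_READ_LEN)
    indexes = {
        name: _substring_set(seqs.values(), lo, hi)
        for name, seqs in annotation_sets.items()
    }
    kept: list[UniqueRead] = []
    removed = {name: 0 for name in annotation_sets}
    for read in reads:
        hit = None
        for name, subs in indexes.items():
            if read.sequence in subs:
                hit = name
                break
        if hit is None:
            kept.append(read)
        else:
            removed[hit] += 1
    return kept, removed


class ReferenceIndex:
    """Seed-and-verify exact/substitution mapper over a FASTA collection.

    Seeds are ``seed_len``-mers of both strands of every reference; a read is
    verified against each candidate locus by direct comparison (exact) or
    Hamming distance (bounded substitutions).
    """

    def __init__(self, reference: Mapping[str, str], seed_len: int = MIN_READ_LEN):
        self.reference = {rid: normalize(seq) for rid, seq in reference.items()}
        self.seed_len = seed_len
        # seed -> list of (reference id, offset)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.reference.items():
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], []).append((rid, i))

    def _exact_one(self, read: str) -> list[MappingHit]:
        hits: list[MappingHit] = []
        for strand, query in (("+", read), ("-", revcomp(read))):
            seed = query[: self.seed_len]
            for rid, pos in self._index.get(seed, ()):
                ref = self.reference[rid]
                if ref[pos : pos + len(query)] == query:
                    hits.append(MappingHit(read, rid, pos, strand, 0))
        return hits

    def map_exact(self, reads: Iterable[str | UniqueRead]) -> list[MappingHit]:
        """All exact occurrences of each read on either strand."""
        hits: list[MappingHit] = []
        for read in reads:
            seq = read.sequence if isinstance(read, UniqueRead) else normalize(read)
            if len(seq) < self.seed_len:
                continue
            hits.extend(self._exact_one(seq))
        return hits

    def map_mismatch(self, reads: Iterable[str | UniqueRead], k: int) -> list[MappingHit]:
        """All occurrences with Hamming distance <= k (k in {0,1,2}); indels
        are not allowed.  Candidate loci come from exact pigeonhole seeds
        (k+1 read chunks), then each is verified by direct comparison."""
        if k not in (0, 1, 2):
            raise ValueError("k must be 0, 1 or 2")
        if k == 0:
            return self.map_exact(reads)
        hits: list[MappingHit] = []
        seen: set[tuple[str, str, int, str]] = set()
        for read in reads:
            seq = read.sequence if isinstance(read, UniqueRead) else normalize(read)
            n = len(seq)
            if n < MIN_READ_LEN:
                continue
            for strand, query in (("+", seq), ("-", revcomp(seq))):
                for rid, start in self._candidates(query, k):
                    key = (seq, rid, start, strand)
                    if key in seen:
                        continue
                    ref = self.reference[rid]
                    if start < 0 or start + n > len(ref):
                        continue
                    mm = _hamming(ref[start : start + n], query, k)
                    if mm <= k:
                        seen.add(key)
                        hits.append(MappingHit(seq, rid, start, strand, mm))
        return hits

    def _candidates(self, query: str, k: int) -> set[tuple[str, int]]:
        n = len(query)
        parts = k + 1
        bounds = [round(i * n / parts) for i in range(parts + 1)]
        cands: set[tuple[str, int]] = set()
        for i in range(parts):
            a, b = bounds[i], bounds[i + 1]
            chunk = query[a:b]
            for rid, pos in self._chunk_positions(chunk):
                cands.add((rid, pos - a))
        return cands

    def _chunk_positions(self, chunk: str) -> list[tuple[str, int]]:
        # chunks are shorter than the seed length; scan references directly
        out: list[tuple[str, int]] = []
        for rid, seq in self.reference.items():
            pos = seq.find(chunk)
            while pos >= 0:
                out.append((rid, pos))
                pos = seq.find(chunk, pos + 1)
        return out


def _hamming(a: str, b: str, cap: int) -> int:
    if len(a) != len(b):
        return cap + 1
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def write_unique_tsv(path, reads: Sequence[UniqueRead], library_ids: Sequence[str]) -> None:
    """Write unique reads with per-library counts as a TSV table."""
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(library_ids) + "\n")
        for r in reads:
            fh.write(r.sequence + "\t" + "\t".join(map(str, r.counts.tolist())) + "\n")


def read_unique_tsv(path) -> tuple[list[UniqueRead], list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        library_ids = header[1:]
        reads = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            reads.append(UniqueRead(parts[0], np.array([int(x) for x in parts[1:]])))
    return reads, library_ids


def map_exact(reads: Iterable[str | UniqueRead], reference: Mapping[str, str]) -> list[MappingHit]:
    return ReferenceIndex(reference).map_exact(reads)


def map_mismatch(
    reads: Iterable[str | UniqueRead], reference: Mapping[str, str], k: int
) -> list[MappingHit]:
    return ReferenceIndex(reference).map_mismatch(reads, k)
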