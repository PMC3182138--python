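"""miRNA gene prediction from mapped small RNA reads.

Anchor reads (redundancy >= 10 across libraries) seed candidate precursor
windows of 100-300 nt (step 20) with one end 10 bp beyond the read on the
anchored side.  Each window is folded; the miRNA* is inferred from the
pairing table with the canonical Dicer 2-nt 3' overhang; and five
annotation criteria are evaluated:

1. folding free energy <= -35 kcal/mol (threshold configurable, since
   absolute energies are backend-dependent);
2. <= 4 mismatches between the mature and the star in the duplex;
3. <= 1 asymmetric bulge of size <= 2 in the mature/star stem;
4. strand bias: >= 80% of mapped reads on the hairpin's transcribed strand;
5. precise processing: >= 75% of precursor reads fall within the mature or
   star region (each extended by 2 nt on both ends).

Overlapping passing candidates on the same reference strand form a region;
the best hairpin per region is chosen by highest mature expression, then
lowest free energy, then shortest window, then leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import edlib

from .fold import FoldResult, fold
from .preprocess import MappingHit, ReferenceIndex, UniqueRead
from .seqs import revcomp

WINDOW_LENGTHS = tuple(range(100, 301, 20))
ANCHOR_FLANK = 10


@dataclass(frozen=True)
class CriteriaThresholds:
    delta_g_max: float = -35.0
    max_duplex_mismatches: int = 4
    max_asym_bulges: int = 1
    max_asym_bulge_size: int = 2
    min_strand_bias: float = 0.8
    min_precise_fraction: float = 0.75
    precise_margin: int = 2  # "plus 2nt on 5' and 3' ends"


@dataclass(frozen=True)
class CriteriaResult:
    delta_g: float
    duplex_mismatches: int
    n_asym_bulges: int
    max_asym_bulge_size: int
    strand_bias: float
    precise_fraction: float
    delta_g_ok: bool
    duplex_ok: bool
    bulges_ok: bool
    strand_ok: bool
    precise_ok: bool
    star_found: bool

    @property
    def overall(self) -> bool:
        return (
            self.star_found
            and self.delta_g_ok
            and self.duplex_ok
            and self.bulges_ok
            and self.strand_ok
            and self.precise_ok
        )


@dataclass(frozen=True)
class LocalRead:
    """A read stack positioned in hairpin-local coordinates."""

    start: int
    end: int
    sense: bool
    count: int


@dataclass
class HairpinCandidate:
    reference_set: str
    reference_id: str
    start: int  # plus-strand window interval on the reference
    end: int
    strand: str
    sequence: str  # hairpin orientation (revcomp of the interval on '-')
    fold: FoldResult
    mature_interval: tuple[int, int]  # hairpin-local
    star_interval: tuple[int, int] | None
    mature_expression: int
    criteria: CriteriaResult
    reads_local: tuple[LocalRead, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mature_seq(self) -> str:
        a, b = self.mature_interval
        return self.sequence[a:b]

    @property
    def star_seq(self) -> str | None:
        if self.star_interval is None:
            return None
        a, b = self.star_interval
        return self.sequence[a:b]


@dataclass
class MiRNAGene:
    id: str
    precursor: HairpinCandidate

    @property
    def mature_seq(self) -> str:
        return self.precursor.mature_seq

    @property
    def star_seq(self) -> str | None:
        return self.precursor.star_seq


def select_anchors(reads: Sequence[UniqueRead], min_copies: int = 10) -> list[UniqueRead]:
    """Reads whose redundancy summed across all libraries is >= min_copies."""
    return [r for r in reads if r.total >= min_copies]


def enumerate_windows(hit: MappingHit, reference_length: int) -> list[tuple[int, int]]:
    """Candidate precursor intervals (plus-strand, 0-based half-open) for an
    anchored read: for each length in 100..300 step 20, one window whose left
    end sits 10 bp upstream of the read and one whose right end sits 10 bp
    downstream.  Windows are clipped to the reference and dropped when the
    clipped window is shorter than 100 nt or no longer contains the read."""
    windows: list[tuple[int, int]] = []
    for length in WINDOW_LENGTHS:
        for start, end in (
            (hit.start - ANCHOR_FLANK, hit.start - ANCHOR_FLANK + length),
            (hit.end + ANCHOR_FLANK - length, hit.end + ANCHOR_FLANK),
        ):
            start = max(0, start)
            end = min(reference_length, end)
            if end - start < WINDOW_LENGTHS[0]:
                continue
            if start > hit.start or end < hit.end:
                continue
            windows.append((start, end))
    return windows


def infer_star(
    fold_result: FoldResult, mature_interval: tuple[int, int], min_paired: float = 0.6
) -> tuple[int, int] | None:
    """Locate the miRNA* from the pairing table: positions paired to the
    mature, shifted to model the 2-nt 3' overhang on each duplex strand.
    Returns None when the mature is mostly unpaired (e.g. in the loop)."""
    pairs = fold_result.pairs()
    a, b = mature_interval
    paired = [i for i in range(a, b) if pairs[i] >= 0 and not (a <= pairs[i] < b)]
    if len(paired) < min_paired * (b - a):
        return None
    m5 = paired[0]
    inner = [i for i in paired if i <= b - 3]
    m3 = inner[-1] if inner else paired[-1]
    lo, hi = pairs[m3], pairs[m5] + 3
    if lo >= hi:
        return None
    lo = max(0, lo)
    hi = min(len(pairs), hi)
    if lo < b and hi > a:  # overlaps the mature: no opposite arm
        return None
    return lo, hi


def _duplex_walk(
    pairs: Sequence[int], mature_interval: tuple[int, int]
) -> tuple[int, int, int]:
    """Walk the mature/star duplex.  Returns (duplex mismatches,
    number of asymmetric bulges, max asymmetric bulge size).

    A mature position unpaired in the duplex counts as one mismatch; bulged
    positions on either strand count per their size (max of the two gap
    sides between consecutive duplex pairs)."""
    a, b = mature_interval
    kept: list[tuple[int, int]] = []
    prev_partner = None
    for i in range(a, b):
        j = pairs[i]
        if j < 0 or a <= j < b:
            continue
        if prev_partner is not None and j >= prev_partner:
            continue  # pairing outside the main duplex helix
        kept.append((i, j))
        prev_partner = j
    if not kept:
        return b - a, 0, 0
    mismatches = (kept[0][0] - a) + (b - 1 - kept[-1][0])
    n_asym = 0
    max_asym = 0
    for (i1, j1), (i2, j2) in zip(kept, kept[1:]):
        gap_m = i2 - i1 - 1
        gap_s = j1 - j2 - 1
        mismatches += max(gap_m, gap_s)
        if gap_m != gap_s:
            n_asym += 1
            max_asym = max(max_asym, abs(gap_m - gap_s))
    return mismatches, n_asym, max_asym


def evaluate_criteria(
    sequence_fold: FoldResult,
    mature_interval: tuple[int, int],
    reads_local: Sequence[LocalRead],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    star_interval: tuple[int, int] | None = None,
) -> tuple[CriteriaResult, tuple[int, int] | None]:
    """Evaluate the five annotation criteria for one candidate window.

    ``reads_local`` are read stacks in hairpin-local coordinates; ``sense``
    marks reads mapped to the hairpin's transcribed strand.  Strand bias
    uses every read overlapping the window (counted once per window);
    precise processing uses reads fully contained in the window.
    """
    if star_interval is None:
        star_interval = infer_star(sequence_fold, mature_interval)
    star_found = star_interval is not None
    mm, n_asym, max_asym = _duplex_walk(sequence_fold.pairs(), mature_interval)

    total = sum(r.count for r in reads_local)
    sense = sum(r.count for r in reads_local if r.sense)
    strand_bias = sense / total if total else 0.0

    n = len(sequence_fold.structure)
    contained = [r for r in reads_local if 0 <= r.start and r.end <= n]
    denom = sum(r.count for r in contained)
    margin = thresholds.precise_margin
    zones = [
        (
            mature_interval[0] - margin,
            mature_interval[1] + margin,
        )
    ]
    if star_found:
        zones.append((star_interval[0] - margin, star_interval[1] + margin))
    precise = sum(
        r.count
        for r in contained
        if any(r.start >= lo and r.end <= hi for lo, hi in zones)
    )
    precise_fraction = precise / denom if denom else 0.0

    result = CriteriaResult(
        delta_g=sequence_fold.delta_g,
        duplex_mismatches=mm,
        n_asym_bulges=n_asym,
        max_asym_bulge_size=max_asym,
        strand_bias=strand_bias,
        precise_fraction=precise_fraction,
        delta_g_ok=sequence_fold.delta_g <= thresholds.delta_g_max,
        duplex_ok=mm <= thresholds.max_duplex_mismatches,
        bulges_ok=(
            n_asym <= thresholds.max_asym_bulges
            and max_asym <= thresholds.max_asym_bulge_size
        ),
        strand_ok=strand_bias >= thresholds.min_strand_bias,
        precise_ok=precise_fraction >= thresholds.min_precise_fraction,
        star_found=star_found,
    )
    return result, star_interval


def _best_key(c: HairpinCandidate):
    return (-c.mature_expression, c.fold.delta_g, c.length, c.start, c.reference_id)


def choose_best_hairpin(candidates: Sequence[HairpinCandidate]) -> HairpinCandidate:
    """Deterministic lexicographic selection among passing candidates of one
    region: highest mature expression, lowest free energy, shortest window,
    leftmost start."""
    if not candidates:
        raise ValueError("no candidates to choose from")
    return min(candidates, key=_best_key)


def group_regions(
    candidates: Sequence[HairpinCandidate],
) -> list[list[HairpinCandidate]]:
    """Group candidates whose windows overlap on the same reference strand."""
    groups: list[list[HairpinCandidate]] = []
    by_key: dict[tuple[str, str, str], list[HairpinCandidate]] = {}
    for c in candidates:
        by_key.setdefault((c.reference_set, c.reference_id, c.strand), []).append(c)
    for cands in by_key.values():
        cands = sorted(cands, key=lambda c: (c.start, c.end))
        current = [cands[0]]
        reach = cands[0].end
        for c in cands[1:]:
            if c.start < reach:
                current.append(c)
                reach = max(reach, c.end)
            else:
                groups.append(current)
                current = [c]
                reach = c.end
        groups.append(current)
    return groups


def _precursor_similar(a: str, b: str, min_identity: float = 0.9) -> bool:
    if a in b or b in a:
        return True
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="distance")
    return res["editDistance"] <= (1 - min_identity) * len(short)


def deduplicate_genes(candidates: Iterable[HairpinCandidate]) -> list[MiRNAGene]:
    """Merge best-per-region candidates from multiple reference sets: genes
    with identical mature sequence whose precursors are identical or mutually
    contained (>= 90% identity over the shorter) collapse into one, keeping
    the best-ranked candidate.  Distinct loci with the same mature sequence
    remain distinct genes."""
    ordered = sorted(candidates, key=_best_key)
    kept: list[HairpinCandidate] = []
    for cand in ordered:
        merged = False
        for other in kept:
            if cand.mature_seq == other.mature_seq and _precursor_similar(
                cand.sequence, other.sequence
            ):
                merged = True
                break
        if not merged:
            kept.append(cand)
    kept.sort(key=lambda c: (c.reference_set, c.reference_id, c.start))
    return [MiRNAGene(f"cand{i + 1:03d}", c) for i, c in enumerate(kept)]


class _RefHits:
    """Per-reference read stacks for fast window overlap queries."""

    def __init__(self, hits: Sequence[MappingHit], counts: Mapping[str, int]):
        self.items = sorted(
            ((h.start, h.end, h.strand, counts[h.read], h.read) for h in hits),
            key=lambda t: t[0],
        )

    def overlapping(self, start: int, end: int) -> list[tuple[int, int, str, int, str]]:
        return [t for t in self.items if t[0] < end and t[1] > start]


def predict_from_reads(
    reads: Sequence[UniqueRead],
    reference_sets: Mapping[str, Mapping[str, str]],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    min_copies: int = 10,
    backend: str | Callable = "builtin",
) -> tuple[list[MiRNAGene], list[HairpinCandidate]]:
    """Run the full prediction stage over one or more reference sets.

    Returns the deduplicated gene set and every criteria-passing candidate
    (before the per-region choice), for inspection.
    """
    counts = {r.sequence: r.total for r in reads}
    anchors = select_anchors(reads, min_copies)
    fold_cache: dict[str, FoldResult] = {}
    passing: list[HairpinCandidate] = []

    for set_name, reference in reference_sets.items():
        index = ReferenceIndex(reference)
        all_hits = index.map_exact(reads)
        hits_by_ref: dict[str, list[MappingHit]] = {}
        for h in all_hits:
            hits_by_ref.setdefault(h.reference_id, []).append(h)
        stacks = {rid: _RefHits(hs, counts) for rid, hs in hits_by_ref.items()}
        anchor_hits = [h for h in index.map_exact(anchors)]
        seen_eval: set[tuple] = set()
        for hit in anchor_hits:
            ref_seq = reference[hit.reference_id]
            for wstart, wend in enumerate_windows(hit, len(ref_seq)):
                key = (set_name, hit.reference_id, wstart, wend, hit.strand, hit.start)
                if key in seen_eval:
                    continue
                seen_eval.add(key)
                cand = _evaluate_window(
                    set_name,
                    hit,
                    ref_seq,
                    wstart,
                    wend,
                    stacks[hit.reference_id],
                    thresholds,
                    fold_cache,
                    backend,
                )
                if cand is not None and cand.criteria.overall:
                    passing.append(cand)

    best = [choose_best_hairpin(group) for group in group_regions(passing)]
    genes = deduplicate_genes(best)
    return genes, passing


def _evaluate_window(
    set_name: str,
    hit: MappingHit,
    ref_seq: str,
    wstart: int,
    wend: int,
    stacks: "_RefHits",
    thresholds: CriteriaThresholds,
    fold_cache: dict[str, FoldResult],
    backend,
) -> HairpinCandidate | None:
    plus_seq = ref_seq[wstart:wend]
    if hit.strand == "+":
        seq = plus_seq
        to_local = lambda s, e: (s - wstart, e - wstart)
    else:
        seq = revcomp(plus_seq)
        to_local = lambda s, e: (wend - e, wend - s)
    mature = to_local(hit.start, hit.end)

    # a multi-mapped read counts once per window: on the hairpin strand if
    # any of its hits lies there, otherwise as an antisense read
    by_read: dict[str, tuple[int, int, bool, int]] = {}
    for s, e, st, c, rseq in stacks.overlapping(wstart, wend):
        sense = st == hit.strand
        prev = by_read.get(rseq)
        if prev is None or (sense and not prev[2]):
            by_read[rseq] = (s, e, sense, c)
    reads_local = tuple(
        LocalRead(*to_local(s, e), sense, c) for s, e, sense, c in by_read.values()
    )

    fr = fold_cache.get(seq)
    if fr is None:
        fr = fold(seq, backend)
        fold_cache[seq] = fr
    criteria, star = evaluate_criteria(fr, mature, reads_local, thresholds)

    # putative mature expression: reads processed to exactly this interval
    expression = sum(
        r.count
        for r in reads_local
        if r.sense and (r.start, r.end) == mature
    )
    return HairpinCandidate(
        reference_set=set_name,
        reference_id=hit.reference_id,
        start=wstart,
        end=wend,
        strand=hit.strand,
        sequence=seq,
        fold=fr,
        mature_interval=mature,
        star_interval=star,
        mature_expression=expression,
        criteria=criteria,
        reads_local=reads_local,
    )


def reevaluate(cand: HairpinCandidate, thresholds: CriteriaThresholds = CriteriaThresholds()) -> CriteriaResult:
    """Re-run the criteria on a stored candidate (idempotence check)."""
    result, _ = evaluate_criteria(
        cand.fold, cand.mature_interval, cand.reads_local, thresholds, cand.star_interval
    )
    return result
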