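"""miRNA target prediction with a position-dependent mispair penalty.

A miRNA:target duplex is divided into a core region (miRNA positions 2-13
from the 5' end) and a general region (all other positions).  In the
general region a mismatch or a single-nucleotide bulge or gap costs 1 and
a G:U pair costs 0.5; scores are doubled in the core region.  A site is
accepted when the penalty is <= 4 and the total number of bulges and gaps
is < 2.

``scan_sites`` enumerates, exhaustively, every site alignment with zero
indels or one single-nucleotide bulge on either strand whose penalty is
<= 4 — a guaranteed superset of the accepted hits, since a second indel or
a multi-nucleotide bulge already violates the indel rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seqs import normalize, revcomp

CORE_START, CORE_END = 2, 13  # 1-based miRNA positions, inclusive

# alignment states per duplex column
WC = "WC"
GU = "GU"
MISMATCH = "MM"
BULGE_MIRNA = "BM"  # unopposed miRNA base
BULGE_TARGET = "BT"  # unopposed target base


@dataclass(frozen=True)
class DuplexAlignment:
    """States run along the duplex from the miRNA 5' end; each state carries
    the 1-based miRNA position it involves (None for target bulges)."""

    mirna: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    states: tuple[tuple[str, int | None], ...]


@dataclass(frozen=True)
class TargetHit:
    duplex: DuplexAlignment
    penalty: float
    n_indels: int


def _pair_state(mirna_base: str, target_base: str) -> str:
    """Classify one opposed column (DNA alphabet; T stands for U)."""
    if (mirna_base, target_base) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return WC
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return GU
    return MISMATCH


def _in_core(pos: int | None) -> bool:
    return pos is not None and CORE_START <= pos <= CORE_END


def score_duplex(duplex: DuplexAlignment) -> float:
    """Total penalty of a duplex alignment.

    A target-side bulge has no miRNA position of its own; it takes the
    adjacent miRNA position on its 3' side for core/general classification.
    """
    L = len(normalize(duplex.mirna))
    positions = [p for s, p in duplex.states if s != BULGE_TARGET]
    if positions != list(range(1, L + 1)):
        raise ValueError("inconsistent duplex state sequence")
    penalty = 0.0
    for idx, (state, pos) in enumerate(duplex.states):
        if state == WC:
            continue
        base = 0.5 if state == GU else 1.0
        if state == BULGE_TARGET:
            # the next miRNA position toward the miRNA 3' end
            later = [p for s, p in duplex.states[idx + 1 :] if p is not None]
            pos = later[0] if later else L
        penalty += base * (2.0 if _in_core(pos) else 1.0)
    return penalty


def count_indels(duplex: DuplexAlignment) -> int:
    return sum(1 for s, _ in duplex.states if s in (BULGE_MIRNA, BULGE_TARGET))


def accept_target(hit: TargetHit) -> bool:
    """Accept iff penalty <= 4 and total bulges + gaps < 2."""
    return hit.penalty <= 4.0 and hit.n_indels <= 1


def _ungapped(mirna: str, site: str) -> tuple[tuple[str, int | None], ...]:
    L = len(mirna)
    return tuple(
        (_pair_state(mirna[k - 1], site[L - k]), k) for k in range(1, L + 1)
    )


def _with_mirna_bulge(mirna: str, site: str, bulge_pos: int):
    """miRNA position bulge_pos unopposed; site is one shorter."""
    L = len(mirna)
    states: list[tuple[str, int | None]] = []
    t = len(site)  # walk the site from its 3' end (= miRNA 5' side)
    for k in range(1, L + 1):
        if k == bulge_pos:
            states.append((BULGE_MIRNA, k))
        else:
            t -= 1
            states.append((_pair_state(mirna[k - 1], site[t]), k))
    return tuple(states)


def _with_target_bulge(mirna: str, site: str, after_pos: int):
    """One unopposed target base between miRNA positions after_pos and
    after_pos + 1; site is one longer than the miRNA."""
    L = len(mirna)
    states: list[tuple[str, int | None]] = []
    t = len(site)
    for k in range(1, L + 1):
        t -= 1
        states.append((_pair_state(mirna[k - 1], site[t]), k))
        if k == after_pos:
            t -= 1
            states.append((BULGE_TARGET, None))
    return tuple(states)


def scan_sites(
    mature: str,
    transcript: str,
    transcript_id: str = "transcript",
    max_penalty: float = 4.0,
) -> list[TargetHit]:
    """All candidate sites on a transcript whose best duplex alignment
    (zero indels, or exactly one single-nucleotide bulge) has penalty
    <= max_penalty.  One hit — the best-scoring alignment — is reported
    per site interval."""
    mirna = normalize(mature)
    tr = normalize(transcript)
    L, n = len(mirna), len(tr)
    if n < L:
        raise ValueError("transcript shorter than the mature sequence")
    best: dict[tuple[int, int], tuple[float, int, DuplexAlignment]] = {}

    def consider(start: int, end: int, states) -> None:
        d = DuplexAlignment(mirna, transcript_id, start, end, states)
        pen = score_duplex(d)
        if pen > max_penalty:
            return
        ind = count_indels(d)
        key = (start, end)
        if key not in best or (pen, ind) < best[key][:2]:
            best[key] = (pen, ind, d)

    for start in range(0, n - L + 1):
        consider(start, start + L, _ungapped(mirna, tr[start : start + L]))
    for start in range(0, n - (L - 1) + 1):
        site = tr[start : start + L - 1]
        for p in range(1, L + 1):
            consider(start, start + L - 1, _with_mirna_bulge(mirna, site, p))
    for start in range(0, n - (L + 1) + 1):
        site = tr[start : start + L + 1]
        for p in range(1, L):
            consider(start, start + L + 1, _with_target_bulge(mirna, site, p))

    return [
        TargetHit(d, pen, ind)
        for (pen, ind, d) in (best[k] for k in sorted(best))
    ]


def predict_targets(
    matures: Mapping[str, str], transcripts: Mapping[str, str]
) -> list[tuple[str, TargetHit]]:
    """Accepted target sites for each mature against each transcript; every
    accepted site is reported (a miRNA may have several targets)."""
    out: list[tuple[str, TargetHit]] = []
    for mid, mature in matures.items():
        for tid, seq in transcripts.items():
            for hit in scan_sites(mature, seq, tid):
                if accept_target(hit):
                    out.append((mid, hit))
    return out
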