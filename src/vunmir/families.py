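"""miRNA family annotation.

Mature sequences are clustered by single linkage at an alignment distance
of <= 2 (substitutions plus indel columns in the optimal pairwise
alignment), then clusters are named after the closest known family in a
miRBase-style reference when any member matches it within 2 mismatches;
otherwise the cluster founds a new sequentially numbered family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .seqs import normalize

# e.g. "vun-miR156a", "ath-miR396b-5p", "miR2111" -> family "miR156" etc.
_FAMILY_RE = re.compile(r"(mir[0-9]+)", re.IGNORECASE)


@dataclass
class FamilyCluster:
    members: tuple[str, ...]  # mature sequences (internal DNA alphabet)
    name: str


def mature_distance(a: str, b: str) -> int:
    """Alignment distance between two matures: substitutions + indel columns
    in the optimal unit-cost global alignment (symmetric)."""
    a, b = normalize(a), normalize(b)
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_families(matures: Sequence[str], threshold: int = 2) -> list[FamilyCluster]:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever the pairwise distance is <= threshold.  Cluster order and
    member order follow first appearance in the input."""
    seqs = []
    seen = set()
    for m in matures:
        m = normalize(m)
        if m not in seen:
            seen.add(m)
            seqs.append(m)
    uf = _UnionFind(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if mature_distance(seqs[i], seqs[j]) <= threshold:
                uf.union(i, j)
    groups: dict[int, list[str]] = {}
    for i, seq in enumerate(seqs):
        groups.setdefault(uf.find(i), []).append(seq)
    return [
        FamilyCluster(tuple(groups[root]), name="")
        for root in sorted(groups, key=lambda r: r)
    ]


def family_of(reference_id: str) -> str | None:
    """Extract the family label (e.g. miR156) from a reference mature id."""
    m = _FAMILY_RE.search(reference_id)
    return "miR" + m.group(1)[3:] if m else None


def assign_family_names(
    clusters: Iterable[FamilyCluster],
    reference_matures: Mapping[str, str],
    threshold: int = 2,
    new_prefix: str = "vun_cand",
) -> list[FamilyCluster]:
    """Name each cluster by the family of the closest reference match at
    distance <= threshold (ties broken by smallest distance, then
    lexicographically first family name); unmatched clusters receive
    sequential new-family labels in first-discovery order."""
    ref = [
        (family_of(rid) or rid, normalize(seq))
        for rid, seq in reference_matures.items()
    ]
    named: list[FamilyCluster] = []
    n_new = 0
    for cluster in clusters:
        best: tuple[int, str] | None = None
        for member in cluster.members:
            for fam, rseq in ref:
                d = mature_distance(member, rseq)
                if d <= threshold and (best is None or (d, fam) < best):
                    best = (d, fam)
        if best is not None:
            name = best[1]
        else:
            n_new += 1
            name = f"{new_prefix}{n_new:03d}"
        named.append(FamilyCluster(cluster.members, name))
    return named
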