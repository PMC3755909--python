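"""5' EST identity clustering and full-length candidate selection.

ESTs are grouped into contigs by single-linkage closure of a pairwise rule:
two reads link when some local alignment spans at least ``min_span`` aligned
columns with more than ``min_identity`` matching columns (gapped, via
Smith-Waterman; N matches nothing).  Within a contig the clone whose 5' end
reaches furthest upstream is the full-length candidate; singletons are
candidates by themselves.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from ._align import OP_MATCH, encode, sw_align
from .simulate import TranscriptRecord

SW_MATCH = 1.0
SW_MISMATCH = -1.0
SW_GAP = -2.0


@dataclass(frozen=True)
class IdentityRule:
    min_identity: float = 0.95
    min_span: int = 100

    def __post_init__(self):
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_span < 1:
            raise ValueError("min_span must be >= 1")


@dataclass
class EstContig:
    members: List[str]                 # sorted clone ids
    representative: str
    anchor_offset: int                 # bp downstream of the contig 5' start
    offsets: Dict[str, int]            # per-member anchor offsets

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def pairwise_linkage(a: str, b: str, rule: IdentityRule = IdentityRule()) -> Tuple[bool, int]:
    """Link test for two reads, plus the signed 5'-shift of ``a`` vs ``b``.

    Positive offset: ``a``'s 5' end extends upstream of ``b``'s (``a``
    carries extra 5' sequence).  Sequences shorter than ``min_span`` never
    link.
    """
    if min(len(a), len(b)) < rule.min_span:
        return False, 0
    qa, qb = encode(a), encode(b)
    _score, qs, _qe, ts, _te, ops = sw_align(qa, qb, SW_MATCH, SW_MISMATCH, SW_GAP)
    if len(ops) < rule.min_span:
        return False, 0
    is_match = (ops == OP_MATCH).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(is_match)])
    w = rule.min_span
    window_matches = csum[w:] - csum[:-w]
    linked = bool((window_matches > rule.min_identity * w).any())
    offset = int(qs - ts)
    return linked, offset


def _candidate_pairs(seqs: Sequence[str], k: int = 16, max_bucket: int = 64):
    """Indices of read pairs sharing at least one exact k-mer."""
    buckets: Dict[str, List[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        for kmer in {s[j:j + k] for j in range(0, max(0, len(s) - k + 1))}:
            buckets[kmer].append(i)
    pairs = set()
    for members in buckets.values():
        if len(members) > max_bucket:      # repeat-derived k-mer, uninformative
            continue
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                pairs.add((members[x], members[y]))
    return sorted(pairs)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_ests(
    records: Iterable[TranscriptRecord], rule: IdentityRule = IdentityRule()
) -> List[EstContig]:
    """Single-linkage contigs over the pairwise identity graph.

    Output is canonical (sorted member ids, contigs sorted by first member)
    and therefore invariant to input order.
    """
    recs = sorted(records, key=lambda r: r.clone_id)
    ids = [r.clone_id for r in recs]
    seqs = [r.sequence for r in recs]
    n = len(recs)
    uf = _UnionFind(n)
    edges: Dict[Tuple[int, int], int] = {}
    for i, j in _candidate_pairs(seqs):
        linked, offset = pairwise_linkage(seqs[i], seqs[j], rule)
        if linked:
            uf.union(i, j)
            edges[(i, j)] = offset

    groups: Dict[int, List[int]] = defaultdict(list)
    for i in range(n):
        groups[uf.find(i)].append(i)
    adj: Dict[int, List[Tuple[int, int]]] = defaultdict(list)
    for (i, j), off in edges.items():
        # off > 0: i extends upstream of j  =>  pos_i = pos_j - off
        adj[i].append((j, off))
        adj[j].append((i, -off))

    contigs = []
    for root in sorted(groups):
        idxs = groups[root]
        pos = {idxs[0]: 0}
        dq = deque([idxs[0]])
        while dq:
            u = dq.popleft()
            for v, off in adj[u]:
                if v not in pos:
                    # off > 0: u upstream of v by off bp
                    pos[v] = pos[u] + off
                    dq.append(v)
        for i in idxs:                      # disconnected members (shouldn't happen)
            pos.setdefault(i, 0)
        base = min(pos.values())
        offsets = {ids[i]: pos[i] - base for i in idxs}
        members = sorted(ids[i] for i in idxs)
        rep = min(members, key=lambda m: (offsets[m], m))
        contigs.append(EstContig(members=members, representative=rep,
                                 anchor_offset=offsets[rep], offsets=offsets))
    contigs.sort(key=lambda c: c.members[0])
    return contigs


def select_representatives(contigs: Iterable[EstContig]) -> List[str]:
    """Full-length candidate clone per contig (singletons included)."""
    return [c.representative for c in contigs]
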