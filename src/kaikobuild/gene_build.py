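"""Evidence-class gene-set construction and transcript/structure statistics.

All mapped full-length clones, public mRNAs and predicted gene models are
merged into gene loci by transitive same-strand exon overlap (gene set A);
mapped ESTs attach to an overlapping A locus or, failing that, group among
themselves into EST-only loci (set B, ids prefixed ``e``).  Whatever cannot
be placed on the assembly at all clusters by sequence identity into set C.
Chimeric clones are excluded from locus building but kept in the
accounting.  The module also carries the transcript-level feature calls
(forward-strand ORF, terminal poly-A) and the exon/intron summary
statistics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .est_clustering import IdentityRule, cluster_ests
from .simulate import TranscriptRecord
from .spliced_alignment import SplicedAlignment

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneLocus:
    locus_id: str
    chromosome: Optional[str]
    strand: Optional[str]
    exons: List[Tuple[int, int]] = field(default_factory=list)  # merged union
    members: List[str] = field(default_factory=list)
    evidence_class: str = "A"
    isoform_count: int = 0

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class TranscriptFeatures:
    transcript_id: str
    orf: Optional[Tuple[int, int, int, int]]   # (start, end, frame, aa_length)
    has_polya: bool


@dataclass
class ExonIntronStats:
    total_exons: int
    exons_per_transcript_mean: float
    exons_per_transcript_median: float
    exon_len_max: int
    exon_len_mean: float
    exon_len_median: float
    exon_len_min: int
    intron_len_max: Optional[int]
    intron_len_mean: Optional[float]
    intron_len_median: Optional[float]
    intron_len_min: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.__dict__.items()]
        return pd.DataFrame(rows, columns=["statistic", "value"])


# ---------------------------------------------------------------------------
# locus grouping
# ---------------------------------------------------------------------------

def _merge_intervals(blocks: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(blocks):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class _UF:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def _overlap_components(items: Sequence[Tuple[str, str, str, List[Tuple[int, int]]]]):
    """Connected components of >=1 bp exon overlap on the same chrom+strand.

    ``items``: (member_id, chrom, strand, exon_blocks).  Returns a list of
    member-index lists.
    """
    uf = _UF(len(items))
    groups: Dict[Tuple[str, str], List[Tuple[int, int, int]]] = defaultdict(list)
    for idx, (_mid, chrom, strand, blocks) in enumerate(items):
        for s, e in blocks:
            groups[(chrom, strand)].append((s, e, idx))
    for key, blocks in groups.items():
        blocks.sort()
        cur_end = -1
        cur_idx = -1
        for s, e, idx in blocks:
            if s < cur_end:
                uf.union(cur_idx, idx)
                cur_end = max(cur_end, e)
            else:
                cur_end = e
            cur_idx = uf.find(idx)
    comps: Dict[int, List[int]] = defaultdict(list)
    for i in range(len(items)):
        comps[uf.find(i)].append(i)
    return [sorted(v) for _k, v in sorted(comps.items())]


def _exon_chain_key(blocks: List[Tuple[int, int, int, int]]) -> Tuple:
    """Splice-pattern signature of an alignment: the chain of intron
    junctions (single-exon structures collapse to span overlap class)."""
    if len(blocks) == 1:
        return ("single",)
    juncs = tuple((blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1))
    return ("multi",) + juncs


def group_loci(
    alignments: Sequence[SplicedAlignment],
    models: Optional[pd.DataFrame] = None,
    prefix: str = "G",
) -> List[GeneLocus]:
    """Gene set A: merge FLC/mRNA alignments and predicted models into loci.

    ``models`` columns: model_id, chrom, strand, exon_starts, exon_ends
    (comma-joined, 0-based half-open).  Model coordinates outside a known
    range are the caller's concern; alignments must have status mapped.
    """
    items = []
    chains = {}
    kinds = {}
    for a in alignments:
        if a.status != "mapped":
            continue
        blocks = [(s, e) for s, e, _q0, _q1 in a.exon_blocks]
        items.append((a.transcript_id, a.chromosome, a.strand, blocks))
        chains[a.transcript_id] = _exon_chain_key(a.exon_blocks)
        kinds[a.transcript_id] = "transcript"
    if models is not None:
        for row in models.itertuples():
            starts = [int(x) for x in str(row.exon_starts).split(",")]
            ends = [int(x) for x in str(row.exon_ends).split(",")]
            items.append((row.model_id, row.chrom, row.strand, list(zip(starts, ends))))
            kinds[row.model_id] = "model"
    loci = []
    for li, comp in enumerate(_overlap_components(items)):
        members = [items[i][0] for i in comp]
        blocks = [b for i in comp for b in items[i][3]]
        chrom, strand = items[comp[0]][1], items[comp[0]][2]
        iso = len({chains[m] for m in members if m in chains})
        loci.append(GeneLocus(
            locus_id=f"{prefix}{li + 1:05d}", chromosome=chrom, strand=strand,
            exons=_merge_intervals(blocks), members=sorted(members),
            evidence_class="A", isoform_count=iso,
        ))
    loci.sort(key=lambda l: (l.chromosome, l.start))
    for i, l in enumerate(loci):
        l.locus_id = f"{prefix}{i + 1:05d}"
    return loci


def attach_ests(
    loci: Sequence[GeneLocus], est_alignments: Sequence[SplicedAlignment]
) -> Tuple[Dict[str, str], List[SplicedAlignment]]:
    """Assign mapped ESTs to overlapping set-A loci.

    Returns (est_id -> locus_id, leftovers) where leftovers are mapped ESTs
    touching no locus.
    """
    by_key: Dict[Tuple[str, str], List[Tuple[int, int, int]]] = defaultdict(list)
    for li, locus in enumerate(loci):
        for s, e in locus.exons:
            by_key[(locus.chromosome, locus.strand)].append((s, e, li))
    for v in by_key.values():
        v.sort()
    assigned: Dict[str, str] = {}
    leftovers = []
    for a in est_alignments:
        if a.status != "mapped":
            continue
        hit = None
        exons = by_key.get((a.chromosome, a.strand), [])
        for g0, g1, _q0, _q1 in a.exon_blocks:
            for s, e, li in exons:
                if s >= g1:
                    break
                if e > g0:
                    hit = li
                    break
            if hit is not None:
                break
        if hit is None:
            leftovers.append(a)
        else:
            assigned[a.transcript_id] = loci[hit].locus_id
            loci[hit].members.append(a.transcript_id)
    for locus in loci:
        locus.members = sorted(set(locus.members))
    return assigned, leftovers


def build_est_genes(est_alignments: Sequence[SplicedAlignment]) -> List[GeneLocus]:
    """Gene set B: overlap-closure loci from mapped ESTs that touch no set-A
    locus; ids prefixed 'e'."""
    items = [
        (a.transcript_id, a.chromosome, a.strand,
         [(s, e) for s, e, _q0, _q1 in a.exon_blocks])
        for a in est_alignments if a.status == "mapped"
    ]
    loci = []
    for comp in _overlap_components(items):
        members = [items[i][0] for i in comp]
        blocks = [b for i in comp for b in items[i][3]]
        loci.append(GeneLocus(
            locus_id="e", chromosome=items[comp[0]][1], strand=items[comp[0]][2],
            exons=_merge_intervals(blocks), members=sorted(members),
            evidence_class="B", isoform_count=0,
        ))
    loci.sort(key=lambda l: (l.chromosome, l.start))
    for i, l in enumerate(loci):
        l.locus_id = f"e{i + 1:05d}"
    return loci


def cluster_unmapped(
    records: Sequence[TranscriptRecord], rule: IdentityRule = IdentityRule()
) -> List[GeneLocus]:
    """Gene set C: identity-linkage clusters of unmappable transcripts; no
    coordinates."""
    contigs = cluster_ests(records, rule)
    loci = []
    for i, c in enumerate(contigs):
        loci.append(GeneLocus(
            locus_id=f"c{i + 1:05d}", chromosome=None, strand=None, exons=[],
            members=list(c.members), evidence_class="C", isoform_count=0,
        ))
    return loci


# ---------------------------------------------------------------------------
# transcript features
# ---------------------------------------------------------------------------

def detect_orf(sequence: str, min_orf_aa: int = 30) -> Optional[Tuple[int, int, int, int]]:
    """Longest forward-strand ATG..stop reading frame.

    Returns (start, end, frame, aa_length) with ``end`` just past the stop
    codon and ``aa_length`` excluding the stop; None when no frame exceeds
    ``min_orf_aa`` amino acids ("longer than 30 aa" = at least 31 codons).
    """
    seq = sequence.upper()
    best = None
    for frame in range(3):
        i = frame
        open_start = None
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                aa = (i - open_start) // 3
                if aa > min_orf_aa and (best is None or aa > best[3]):
                    best = (open_start, i + 3, frame, aa)
                open_start = None
            i += 3
    return best


def detect_polya(sequence: str) -> bool:
    """True iff the final 15 nt contain a >=10-A run with <=1 interruption."""
    tail = sequence.upper()[-15:]
    n = len(tail)
    for w in (10, 11):
        for i in range(0, n - w + 1):
            window = tail[i:i + w]
            a = window.count("A")
            if a >= 10 and (w - a) <= 1:
                return True
    return False


def transcript_features(transcript_id: str, sequence: str,
                        min_orf_aa: int = 30) -> TranscriptFeatures:
    return TranscriptFeatures(
        transcript_id=transcript_id,
        orf=detect_orf(sequence, min_orf_aa),
        has_polya=detect_polya(sequence),
    )


# ---------------------------------------------------------------------------
# exon/intron statistics
# ---------------------------------------------------------------------------

def exon_intron_stats(structures: Iterable[Sequence[Tuple[int, int]]]) -> ExonIntronStats:
    """Summary statistics over transcript exon-block structures.

    ``structures``: per transcript, genome-ordered (start, end) exon blocks.
    Introns are the gaps between consecutive blocks; single-exon
    transcripts contribute no intron.
    """
    exon_counts, exon_lens, intron_lens = [], [], []
    for blocks in structures:
        blocks = sorted(blocks)
        exon_counts.append(len(blocks))
        exon_lens.extend(e - s for s, e in blocks)
        intron_lens.extend(
            blocks[i + 1][0] - blocks[i][1] for i in range(len(blocks) - 1)
        )
    if not exon_lens:
        raise ValueError("no exon structures supplied")
    il = np.array(intron_lens) if intron_lens else None
    return ExonIntronStats(
        total_exons=len(exon_lens),
        exons_per_transcript_mean=float(np.mean(exon_counts)),
        exons_per_transcript_median=float(np.median(exon_counts)),
        exon_len_max=int(np.max(exon_lens)),
        exon_len_mean=float(np.mean(exon_lens)),
        exon_len_median=float(np.median(exon_lens)),
        exon_len_min=int(np.min(exon_lens)),
        intron_len_max=int(il.max()) if il is not None else None,
        intron_len_mean=float(il.mean()) if il is not None else None,
        intron_len_median=float(np.median(il)) if il is not None else None,
        intron_len_min=int(il.min()) if il is not None else None,
    )
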