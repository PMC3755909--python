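"""Splice-aware transcript-to-genome mapping with prefilters.

Mapping follows the classical two-stage design: an exact k-mer seed search
localizes each transcript to a handful of candidate genomic windows (the
fast BLAST-like stage), then a splice-aware local DP (est2genome-like,
see :mod:`kaikobuild._align`) aligns the transcript inside each window.
A transcript is ``mapped`` when its best placement reaches the identity
and coverage thresholds (defaults 0.95 / 0.5); failing transcripts are
``unmapped_low_homology`` or ``unmapped_low_coverage``.  Chimeric clones
are recognized by failure of any single 100-kb placement to explain the
read while two incompatible placements jointly do.

Internal coordinates are 0-based half-open throughout; GFF3 emission
converts to 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._align import OP_GAP_Q, OP_GAP_T, OP_INTRON, OP_MATCH, OP_MISMATCH, encode, splice_align_kernel
from .io import revcomp

logger = logging.getLogger(__name__)

# splice DP scores: qualitative est2genome behaviour at desk scale.  The
# intron entry must stay expensive enough (net ~30 with canonical GT..AG)
# that chaining chance ~75%-identity patches across a window never pays;
# a cheap intron state lets unrelated sequence "map" by hopping between
# random near-matches.
SCORES = dict(match=2.0, mismatch=-3.0, gap_open=6.0, gap_ext=2.0,
              intron_open=40.0, intron_ext=0.001, splice_bonus=20.0)


@dataclass(frozen=True)
class MappingThresholds:
    min_identity: float = 0.95
    min_coverage: float = 0.5
    min_intron: int = 30
    max_intron: int = 120_000
    chimera_window: int = 100_000
    seed_k: int = 14
    # "perfect alignment within 100 kb" proxy: a single placement covering
    # at least this fraction rules out chimerism
    chimera_full_coverage: float = 0.9
    chimera_min_segment: float = 0.2
    max_windows: int = 8

    def __post_init__(self):
        if not 0 < self.min_identity <= 1 or not 0 < self.min_coverage <= 1:
            raise ValueError("identity/coverage thresholds must be in (0, 1]")
        if self.min_intron >= self.max_intron:
            raise ValueError("min_intron must be < max_intron")


@dataclass
class SplicedAlignment:
    transcript_id: str
    chromosome: Optional[str]
    strand: Optional[str]
    # (genome_start, genome_end, transcript_start, transcript_end), 0-based half-open
    exon_blocks: List[Tuple[int, int, int, int]] = field(default_factory=list)
    percent_identity: float = 0.0
    coverage: float = 0.0
    status: str = "unmapped_low_coverage"
    score: float = 0.0

    @property
    def genome_span(self) -> Tuple[int, int]:
        return self.exon_blocks[0][0], self.exon_blocks[-1][1]

    @property
    def transcript_span(self) -> Tuple[int, int]:
        # minus-strand blocks are genome-ordered, i.e. reversed in
        # transcript coordinates
        return (min(b[2] for b in self.exon_blocks),
                max(b[3] for b in self.exon_blocks))


@dataclass
class GenomicWindow:
    chromosome: str
    strand: str
    start: int
    end: int
    n_seeds: int
    seed_start: int = 0
    seed_end: int = 0
    seed_positions: Optional[np.ndarray] = None   # sorted genomic hit positions


class GenomeIndex:
    """Sorted-array exact k-mer index over a genome (2-bit codes)."""

    def __init__(self, genome: Dict[str, str], k: int = 14):
        self.k = k
        self.genome = genome
        self.chroms = sorted(genome)
        self._enc = {c: encode(genome[c]) for c in self.chroms}
        codes_all, pos_all, chrom_all = [], [], []
        for ci, c in enumerate(self.chroms):
            codes = _kmer_codes(self._enc[c], k)
            valid = codes >= 0
            codes_all.append(codes[valid])
            pos_all.append(np.nonzero(valid)[0])
            chrom_all.append(np.full(int(valid.sum()), ci, dtype=np.int32))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = np.concatenate(pos_all)[order] if pos_all else np.empty(0, dtype=np.int64)
        self._chrom = np.concatenate(chrom_all)[order] if chrom_all else np.empty(0, dtype=np.int32)

    def lookup(self, code: int) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._chrom[lo:hi], self._pos[lo:hi]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Code of every k-mer; -1 where any base is non-ACGT."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    e = enc.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        codes = codes * 4 + np.maximum(e[i:i + n], 0)
        bad |= e[i:i + n] < 0
    codes[bad] = -1
    return codes


def seed_prefilter(
    transcript: str, index: GenomeIndex, thresholds: MappingThresholds = MappingThresholds()
) -> List[GenomicWindow]:
    """Candidate genomic windows from chained exact k-mer seeds.

    Seeds on one chromosome/strand are split where consecutive genomic
    positions differ by more than ``max_intron``; each chain becomes a
    window.  A flank is padded by ``max_intron`` only when the unseeded
    transcript end is long enough (>=30 bp) to hold a missed exon,
    otherwise by a small margin.
    """
    k = thresholds.seed_k
    if len(transcript) < k:
        logger.warning("transcript shorter than seed_k=%d; unmapped", k)
        return []
    windows: List[GenomicWindow] = []
    tlen = len(transcript)
    for strand in "+-":
        query = transcript if strand == "+" else revcomp(transcript)
        codes = _kmer_codes(encode(query), k)
        hits: Dict[int, List[Tuple[int, int]]] = {}
        step = 4 if tlen >= 4 * k else 1
        for tp in range(0, len(codes), step):
            code = codes[tp]
            if code < 0:
                continue
            chroms, poss = index.lookup(code)
            if len(poss) > 50:          # repeat-derived seed
                continue
            for ci, gp in zip(chroms, poss):
                hits.setdefault(int(ci), []).append((int(gp), tp))
        for ci, hp in hits.items():
            hp.sort()
            chrom = index.chroms[ci]
            clen = len(index.genome[chrom])
            chain_start = 0
            for i in range(1, len(hp) + 1):
                if i == len(hp) or hp[i][0] - hp[i - 1][0] > thresholds.max_intron:
                    chain = hp[chain_start:i]
                    chain_start = i
                    gmin = chain[0][0]
                    gmax = chain[-1][0] + k
                    tps = [tp for _g, tp in chain]
                    # unseeded query-end lengths; terminal homopolymer runs
                    # (poly-A tails / their revcomp) cannot hold a missed exon
                    head = min(tps)
                    tail = tlen - (max(tps) + k)
                    head_eff = head - _homopolymer_run(query[:head], reverse=False)
                    tail_eff = tail - _homopolymer_run(query[tlen - tail:], reverse=True)
                    left_q, right_q = (head, tail) if strand == "+" else (tail, head)
                    left_eff, right_eff = (head_eff, tail_eff) if strand == "+" else (tail_eff, head_eff)
                    pad_l = left_q + (thresholds.max_intron if left_eff >= 30 else 60)
                    pad_r = right_q + (thresholds.max_intron if right_eff >= 30 else 60)
                    windows.append(GenomicWindow(
                        chromosome=chrom, strand=strand,
                        start=max(0, gmin - pad_l), end=min(clen, gmax + pad_r),
                        n_seeds=len(chain), seed_start=gmin, seed_end=gmax,
                        seed_positions=np.array([g for g, _tp in chain]),
                    ))
    windows.sort(key=lambda w: (-w.n_seeds, w.chromosome, w.start))
    if windows:
        # chains far weaker than the best are chance k-mer scatter
        floor = max(3 if windows[0].n_seeds >= 12 else 2,
                    int(0.05 * windows[0].n_seeds))
        windows = [w for w in windows if w.n_seeds >= floor]
    windows = [w for w in windows if w.n_seeds >= 2 or len(transcript) < 8 * k]
    return windows[: thresholds.max_windows]


def _homopolymer_run(seq: str, reverse: bool) -> int:
    """Length of the terminal single-base run at the end (reverse=True) or
    start (reverse=False) of ``seq``."""
    if not seq:
        return 0
    it = seq[::-1] if reverse else seq
    base = it[0]
    n = 0
    for ch in it:
        if ch != base:
            break
        n += 1
    return n


# cap on DP cells per window; larger windows get their pads shrunk.  The
# packed traceback costs one byte per cell, so this bounds peak memory at
# ~250 MB and worst-case per-window time at a few seconds.
MAX_DP_CELLS = 250_000_000


def _densest_core(seed_positions: Optional[np.ndarray], k: int, max_len: int):
    """Sub-span of at most ``max_len`` bp covering the most seeds."""
    if seed_positions is None or len(seed_positions) == 0:
        return 0, max_len
    pos = np.sort(seed_positions)
    if pos[-1] + k - pos[0] <= max_len:
        return int(pos[0]), int(pos[-1] + k)
    best_i, best_j = 0, 0
    i = 0
    for j in range(len(pos)):
        while pos[j] + k - pos[i] > max_len:
            i += 1
        if j - i > best_j - best_i:
            best_i, best_j = i, j
    return int(pos[best_i]), int(pos[best_j] + k)


def _path_to_blocks(ops: np.ndarray, qs: int, ts: int):
    """Exon blocks (t0, t1, q0, q1) in window coordinates, plus columns."""
    blocks = []
    q, t = qs, ts
    eq, et = q, t
    bq, bt = q, t
    n_match = n_col = 0
    for op in ops:
        if op == OP_INTRON:
            if et > bt or eq > bq:
                blocks.append((bt, et, bq, eq))
            t += 1
            bq, bt = eq, t
            et = t
            continue
        if op == OP_MATCH or op == OP_MISMATCH:
            n_match += 1 if op == OP_MATCH else 0
            n_col += 1
            q += 1
            t += 1
        elif op == OP_GAP_Q:
            n_col += 1
            t += 1
        elif op == OP_GAP_T:
            n_col += 1
            q += 1
        eq, et = q, t
    if et > bt or eq > bq:
        blocks.append((bt, et, bq, eq))
    return blocks, n_match, n_col


def splice_align(
    transcript: str,
    window_seq: str,
    thresholds: MappingThresholds = MappingThresholds(),
    transcript_id: str = "query",
    chromosome: Optional[str] = None,
    strand: str = "+",
    window_start: int = 0,
) -> SplicedAlignment:
    """Align a transcript inside one genomic window.

    For minus-strand placements the window is reverse-complemented so that
    splice motifs read GT..AG in the DP; emitted blocks are in forward
    genome coordinates either way.
    """
    target = window_seq if strand == "+" else revcomp(window_seq)
    score, qs, qe, ts, te, ops = splice_align_kernel(
        encode(transcript), encode(target),
        SCORES["match"], SCORES["mismatch"], SCORES["gap_open"], SCORES["gap_ext"],
        SCORES["intron_open"], SCORES["intron_ext"], SCORES["splice_bonus"],
        thresholds.min_intron,
    )
    blocks, n_match, n_col = _path_to_blocks(ops, qs, ts)
    wlen = len(window_seq)
    out_blocks = []
    for (t0, t1, q0, q1) in blocks:
        if strand == "+":
            g0, g1 = window_start + t0, window_start + t1
        else:
            g0, g1 = window_start + wlen - t1, window_start + wlen - t0
        out_blocks.append((g0, g1, q0, q1))
    out_blocks.sort()
    identity = n_match / n_col if n_col else 0.0
    coverage = (qe - qs) / len(transcript) if transcript else 0.0
    if identity < thresholds.min_identity:
        status = "unmapped_low_homology"
    elif coverage < thresholds.min_coverage:
        status = "unmapped_low_coverage"
    else:
        status = "mapped"
    return SplicedAlignment(
        transcript_id=transcript_id, chromosome=chromosome, strand=strand,
        exon_blocks=out_blocks, percent_identity=identity, coverage=coverage,
        status=status, score=float(score),
    )


def classify_chimera(
    alignments: Sequence[SplicedAlignment],
    transcript_len: int,
    thresholds: MappingThresholds = MappingThresholds(),
) -> str:
    """Chimera status from all window alignments of one transcript.

    Not chimeric when some single placement (one chromosome, one strand,
    within ``chimera_window``) covers ``chimera_full_coverage`` of the
    read.  Chimeric when no such placement exists but a second,
    incompatible high-identity segment explains a disjoint >=
    ``chimera_min_segment`` share of the read.
    """
    segs = [a for a in alignments if a.exon_blocks]
    if not segs:
        return "unmapped_low_coverage"
    best = max(segs, key=lambda a: a.score)
    if best.coverage >= thresholds.chimera_full_coverage and \
            best.percent_identity >= thresholds.min_identity:
        return best.status
    bq0, bq1 = best.transcript_span
    for a in segs:
        if a is best or a.percent_identity < thresholds.min_identity:
            continue
        if a.coverage < thresholds.chimera_min_segment:
            continue
        compatible = (
            a.chromosome == best.chromosome
            and a.strand == best.strand
            and _span_gap(a.genome_span, best.genome_span) <= thresholds.chimera_window
        )
        if compatible:
            continue
        q0, q1 = a.transcript_span
        overlap = max(0, min(q1, bq1) - max(q0, bq0))
        if overlap < 0.2 * min(q1 - q0, bq1 - bq0):
            return "chimeric"
    return best.status


def _span_gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def align_transcript(
    transcript_id: str,
    sequence: str,
    index: GenomeIndex,
    thresholds: MappingThresholds = MappingThresholds(),
) -> SplicedAlignment:
    """Seed, align in every candidate window, pick the best placement,
    then screen for chimerism.  Ties break toward the forward strand and
    the lexicographically first locus."""
    windows = seed_prefilter(sequence, index, thresholds)
    if not windows:
        return SplicedAlignment(transcript_id, None, None,
                                status="unmapped_low_coverage")
    alns = []
    for w in windows:
        max_len = max(len(sequence) + 1000, MAX_DP_CELLS // (len(sequence) + 1))
        start, end = w.start, w.end
        if end - start > max_len:
            # clamp to the densest seed core: stray same-chromosome hits can
            # stretch the chain far beyond the true locus
            core_s, core_e = _densest_core(w.seed_positions, thresholds.seed_k, max_len)
            spare = max(0, max_len - (core_e - core_s)) // 2
            start = max(w.start, core_s - spare)
            end = min(w.end, core_e + spare)
        a = splice_align(
            sequence, index.genome[w.chromosome][start:end], thresholds,
            transcript_id=transcript_id, chromosome=w.chromosome,
            strand=w.strand, window_start=start,
        )
        if a.exon_blocks:
            alns.append(a)
    if not alns:
        return SplicedAlignment(transcript_id, None, None,
                                status="unmapped_low_coverage")
    alns.sort(key=lambda a: (-a.score, 0 if a.strand == "+" else 1,
                             a.chromosome, a.exon_blocks[0][0]))
    n_best = sum(1 for a in alns if a.score == alns[0].score)
    if n_best > 1:
        logger.info("%s: %d equally-best loci; keeping first", transcript_id, n_best)
    best = alns[0]
    status = classify_chimera(alns, len(sequence), thresholds)
    best.status = status
    return best
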