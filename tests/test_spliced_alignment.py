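"""Seed prefilter, splice-aware DP, and chimera classification."""

import numpy as np
import pytest

from kaikobuild._align import OP_MATCH, encode, splice_align_kernel, sw_align
from kaikobuild.io import revcomp
from kaikobuild.spliced_alignment import (
    SCORES, GenomeIndex, MappingThresholds, SplicedAlignment,
    align_transcript, classify_chimera, seed_prefilter, splice_align,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def toy_locus():
    """One chromosome with a planted two-exon gene (GT..AG intron)."""
    rng = np.random.default_rng(55)
    exon1, exon2 = _random_seq(rng, 180), _random_seq(rng, 240)
    intron = "GT" + _random_seq(rng, 296) + "AG"
    left, right = _random_seq(rng, 900), _random_seq(rng, 900)
    chrom = left + exon1 + intron + exon2 + right
    blocks = [(900, 900 + 180), (900 + 180 + 300, 900 + 180 + 300 + 240)]
    return {"chr1": chrom}, exon1 + exon2, blocks


def test_prefilter_finds_exact_substring(toy_locus, rng):
    genome, transcript, blocks = toy_locus
    index = GenomeIndex(genome, k=14)
    sub = genome["chr1"][920:1050]
    ws = seed_prefilter(sub, index)
    assert any(w.chromosome == "chr1" and w.start <= 920 and w.end >= 1050
               for w in ws)


def test_prefilter_rejects_foreign_sequence(toy_locus, rng):
    genome, _t, _b = toy_locus
    index = GenomeIndex(genome, k=14)
    assert seed_prefilter(_random_seq(rng, 300), index) == []


def test_prefilter_window_spans_both_exons(toy_locus):
    genome, transcript, blocks = toy_locus
    index = GenomeIndex(genome, k=14)
    ws = seed_prefilter(transcript, index)
    assert ws and ws[0].start <= blocks[0][0] and ws[0].end >= blocks[1][1]


def test_error_free_two_exon_transcript_recovers_truth(toy_locus):
    genome, transcript, blocks = toy_locus
    index = GenomeIndex(genome, k=14)
    a = align_transcript("t1", transcript, index)
    assert a.status == "mapped"
    assert a.strand == "+"
    assert [(g0, g1) for g0, g1, _q0, _q1 in a.exon_blocks] == blocks
    assert a.percent_identity == 1.0
    assert a.coverage == 1.0


def test_minus_strand_gene_recovers_exact_blocks():
    # a minus-strand gene: splice sites read CT..AC on the forward genome
    rng = np.random.default_rng(56)
    exon1, exon2 = _random_seq(rng, 180), _random_seq(rng, 240)
    intron = "CT" + _random_seq(rng, 296) + "AC"
    chrom = _random_seq(rng, 900) + exon1 + intron + exon2 + _random_seq(rng, 900)
    blocks = [(900, 1080), (1380, 1620)]
    transcript = revcomp(exon1 + exon2)     # transcription off the minus strand
    a = align_transcript("t1", transcript, GenomeIndex({"chr1": chrom}, k=14))
    assert a.status == "mapped" and a.strand == "-"
    assert [(g0, g1) for g0, g1, _q0, _q1 in a.exon_blocks] == blocks
    assert a.percent_identity == 1.0 and a.coverage == 1.0


def test_low_identity_transcript_filtered(toy_locus, rng):
    genome, transcript, _b = toy_locus
    seq = list(transcript)
    for pos in range(3, len(seq), 16):   # ~6% evenly spread mismatches
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    a = align_transcript("t1", "".join(seq), GenomeIndex(genome, k=14))
    assert a.status == "unmapped_low_homology"
    assert a.percent_identity < 0.95


def test_low_coverage_transcript_filtered(toy_locus, rng):
    genome, transcript, _b = toy_locus
    # 40% genomic, 60% foreign tail
    seq = transcript[:int(0.4 * len(transcript))] + _random_seq(rng, int(0.6 * len(transcript)))
    a = align_transcript("t1", seq, GenomeIndex(genome, k=14))
    assert a.status == "unmapped_low_coverage"
    assert a.coverage < 0.5


def test_identity_and_coverage_bounded(small_result):
    for a in small_result.alignments.values():
        assert 0.0 <= a.percent_identity <= 1.0
        assert 0.0 <= a.coverage <= 1.0
        if a.status == "mapped":
            assert a.percent_identity >= 0.95
            assert a.coverage >= 0.5
            starts = [b[0] for b in a.exon_blocks]
            assert starts == sorted(starts)


def _brute_force_score(q, t, p):
    """Independent exhaustive recursion over the same alignment grammar."""
    import functools

    M, X, Y, I = 0, 1, 2, 3
    NEG = float("-inf")

    @functools.lru_cache(maxsize=None)
    def best_ending(i, j, state):
        # best score of an alignment path ending at (i, j) in `state`
        if state == M:
            if i == 0 or j == 0:
                return NEG
            s = p["match"] if q[i - 1] == t[j - 1] else p["mismatch"]
            prev = [0.0, best_ending(i - 1, j - 1, M), best_ending(i - 1, j - 1, X),
                    best_ending(i - 1, j - 1, Y)]
            acc = p["splice_bonus"] / 2 if (j >= 3 and t[j - 3:j - 1] == "AG") else 0.0
            prev.append(best_ending(i - 1, j - 1, I) + acc)
            return max(prev) + s
        if state == X:
            if j == 0:
                return NEG
            return max(best_ending(i, j - 1, M) - p["gap_open"],
                       best_ending(i, j - 1, X) - p["gap_ext"])
        if state == Y:
            if i == 0:
                return NEG
            return max(best_ending(i - 1, j, M) - p["gap_open"],
                       best_ending(i - 1, j, Y) - p["gap_ext"])
        # intron: extend, or enter with a min_intron jump
        if j == 0:
            return NEG
        out = best_ending(i, j - 1, I) - p["intron_ext"]
        j0 = j - p["min_intron"]
        if j0 >= 1:
            # first intron base is t[j0] (0-based), mirroring the jump entry
            don = p["splice_bonus"] / 2 if (j0 + 1 < len(t) and t[j0:j0 + 2] == "GT") else 0.0
            out = max(out, best_ending(i, j0, M) - p["intron_open"] + don)
        return out

    best = 0.0
    for i in range(1, len(q) + 1):
        for j in range(1, len(t) + 1):
            best = max(best, best_ending(i, j, M))
    return best


@pytest.mark.parametrize("trial", range(6))
def test_dp_score_matches_exhaustive_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    q = _random_seq(rng, int(rng.integers(8, 30)))
    t = _random_seq(rng, int(rng.integers(40, 100)))
    if trial % 2 == 0:
        # embed q with an intron so the intron state is exercised
        cut = len(q) // 2
        t = t[:20] + q[:cut] + "GT" + _random_seq(rng, 36) + "AG" + q[cut:] + t[20:]
        t = t[:100]
    p = dict(match=SCORES["match"], mismatch=SCORES["mismatch"],
             gap_open=SCORES["gap_open"], gap_ext=SCORES["gap_ext"],
             intron_open=SCORES["intron_open"], intron_ext=SCORES["intron_ext"],
             splice_bonus=SCORES["splice_bonus"], min_intron=10)
    score, *_rest = splice_align_kernel(
        encode(q), encode(t), p["match"], p["mismatch"], p["gap_open"],
        p["gap_ext"], p["intron_open"], p["intron_ext"], p["splice_bonus"],
        p["min_intron"],
    )
    assert score == pytest.approx(_brute_force_score(q, t, p), abs=1e-6)


def _seg(tid, chrom, strand, blocks, identity=1.0, coverage=0.5, score=100.0):
    return SplicedAlignment(tid, chrom, strand, exon_blocks=blocks,
                            percent_identity=identity, coverage=coverage,
                            status="mapped", score=score)


def test_compact_placement_is_not_chimeric():
    # all blocks within 40 kb on one chromosome, near-full coverage
    a = _seg("t", "chr2", "+", [(10_000, 11_000, 0, 1000), (50_000, 51_000, 1000, 2000)],
             coverage=0.96, score=500)
    assert classify_chimera([a], 2000) == "mapped"


def test_split_halves_on_two_chromosomes_are_chimeric():
    lhs = _seg("t", "chr2", "+", [(10_000, 11_000, 0, 1000)], coverage=0.5, score=300)
    rhs = _seg("t", "chr5", "+", [(90_000, 91_000, 1000, 2000)], coverage=0.5, score=280)
    assert classify_chimera([lhs, rhs], 2000) == "chimeric"


def test_distant_same_chromosome_halves_are_chimeric():
    lhs = _seg("t", "chr2", "+", [(10_000, 11_000, 0, 1000)], coverage=0.5, score=300)
    rhs = _seg("t", "chr2", "+", [(500_000, 501_000, 1000, 2000)], coverage=0.5, score=280)
    assert classify_chimera([lhs, rhs], 2000) == "chimeric"


def test_planted_chimeras_recovered():
    from kaikobuild.pipeline import chimera_confusion
    from kaikobuild.simulate import simulate_genome, simulate_libraries
    from tests.conftest import small_config

    cfg = small_config(seed=31, n_genes=60, chromosome_length=500_000,
                       chimera_rate=0.25, n_unplaced_genes=0,
                       est_mean_specific=0.0, est_mean_broad=0.0)
    genome, truth = simulate_genome(cfg)
    records = simulate_libraries(genome, truth, cfg)
    index = GenomeIndex(genome, k=14)
    alns = {r.clone_id: align_transcript(r.clone_id, r.sequence, index)
            for r in records if r.rtype == "FLC"}
    tp, fn, fp, tn = chimera_confusion(truth, alns)
    assert tp + fn >= 5
    assert tp / (tp + fn) >= 0.95
    assert fp <= 0.02 * (fp + tn)
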