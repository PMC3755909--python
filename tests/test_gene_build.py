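"""Gene-set construction, ORF/poly-A calls, exon/intron statistics."""

import numpy as np
import pytest

from kaikobuild.gene_build import (
    build_est_genes, cluster_unmapped, detect_orf, detect_polya,
    exon_intron_stats, group_loci,
)
from kaikobuild.simulate import TranscriptRecord
from kaikobuild.spliced_alignment import SplicedAlignment


def _aln(tid, chrom, strand, blocks, status="mapped"):
    return SplicedAlignment(tid, chrom, strand, exon_blocks=blocks,
                            percent_identity=1.0, coverage=1.0, status=status)


# ---------------------------------------------------------------------------
# locus grouping
# ---------------------------------------------------------------------------

def test_flc_matching_model_makes_one_locus():
    import pandas as pd

    flc = _aln("FLC1", "chr1", "+", [(100, 200, 0, 100), (300, 400, 100, 200)])
    models = pd.DataFrame([dict(model_id="m1", chrom="chr1", strand="+",
                                exon_starts="100,300", exon_ends="200,400")])
    loci = group_loci([flc], models)
    assert len(loci) == 1
    assert loci[0].evidence_class == "A"
    assert loci[0].members == ["FLC1", "m1"]


def test_opposite_strands_stay_separate():
    a = _aln("F1", "chr1", "+", [(100, 400, 0, 300)])
    b = _aln("F2", "chr1", "-", [(150, 350, 0, 200)])
    loci = group_loci([a, b])
    assert len(loci) == 2


def test_isoforms_counted_by_exon_chain():
    a = _aln("F1", "chr1", "+", [(100, 200, 0, 100), (300, 400, 100, 200),
                                 (500, 600, 200, 300)])
    b = _aln("F2", "chr1", "+", [(100, 200, 0, 100), (300, 400, 100, 200),
                                 (520, 600, 200, 280)])
    loci = group_loci([a, b])
    assert len(loci) == 1
    assert loci[0].isoform_count == 2


def test_est_only_loci_get_e_prefix():
    ests = [
        _aln("E1", "chr1", "+", [(1000, 1300, 0, 300)]),
        _aln("E2", "chr1", "+", [(1200, 1500, 0, 300)]),
        _aln("E3", "chr1", "+", [(1400, 1700, 0, 300)]),
    ]
    loci = build_est_genes(ests)
    assert len(loci) == 1
    assert loci[0].locus_id.startswith("e")
    assert loci[0].members == ["E1", "E2", "E3"]


def test_cluster_unmapped_handles_singletons_and_empty(rng):
    seq = "".join(rng.choice(list("ACGT"), size=400))
    loci = cluster_unmapped([TranscriptRecord("U1", "L", "EST", seq)])
    assert len(loci) == 1
    assert loci[0].evidence_class == "C"
    assert loci[0].chromosome is None
    assert cluster_unmapped([]) == []


# ---------------------------------------------------------------------------
# ORF / poly-A
# ---------------------------------------------------------------------------

def _orf_oracle(seq, min_aa):
    best = None
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == "ATG":
                for j in range(i + 1, len(codons)):
                    if codons[j] in ("TAA", "TAG", "TGA"):
                        aa = j - i
                        if aa > min_aa and (best is None or aa > best):
                            best = aa
                        i = j
                        break
                else:
                    break
            i += 1
    return best


def test_orf_boundary_just_above_threshold(rng):
    coding = "ATG" + "".join(
        rng.choice(["GCT", "GGA", "TGC", "CAT", "TTC"], size=30)
    ) + "TAA"
    seq = "CCCC" + coding + "CCCC"
    orf = detect_orf(seq, min_orf_aa=30)
    assert orf is not None
    start, end, frame, aa = orf
    assert aa == 31
    assert seq[start:start + 3] == "ATG"
    assert seq[end - 3:end] == "TAA"
    # exactly 30 aa is not "longer than 30"
    shorter = "CCCC" + "ATG" + "GCT" * 29 + "TAA"
    assert detect_orf(shorter, min_orf_aa=30) is None


def test_orf_absent_when_all_frames_blocked():
    assert detect_orf("TAATAATAATAATAA" * 10) is None


@pytest.mark.parametrize("trial", range(5))
def test_orf_agrees_with_exhaustive_scan(trial):
    rng = np.random.default_rng(50 + trial)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    got = detect_orf(seq, min_orf_aa=30)
    want = _orf_oracle(seq, 30)
    assert (got[3] if got else None) == want


def test_polya_detection_rules():
    assert detect_polya("ACGT" * 30 + "AAAAAAAAAAAA")
    assert detect_polya("ACGT" * 30 + "AAAAAG" + "AAAAAA")   # one interruption
    assert not detect_polya("ACGT" * 40)
    assert not detect_polya("ACGT" * 30 + "AAAAAGGAAAAA")    # two interruptions
    assert not detect_polya("AAAAAAAAAAAA" + "ACGTACGTACGTCCC")  # run not terminal


def test_polya_recall_on_planted_tails(small_sim):
    _cfg, _genome, truth, records = small_sim
    flc_ids = set(truth.transcripts.query("type == 'FLC' and not is_chimera").clone_id)
    flcs = [r for r in records if r.clone_id in flc_ids]
    hit = sum(detect_polya(r.sequence) for r in flcs)
    assert hit / len(flcs) >= 0.99


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_exon_intron_stats_direct_case():
    stats = exon_intron_stats([[(0, 100), (600, 800)]])
    assert stats.total_exons == 2
    assert stats.exons_per_transcript_mean == 2
    assert stats.exon_len_mean == 150
    assert stats.intron_len_mean == 500
    assert stats.intron_len_min == stats.intron_len_max == 500


def test_single_exon_contributes_no_intron():
    stats = exon_intron_stats([[(10, 400)]])
    assert stats.intron_len_mean is None
    assert stats.exon_len_min == stats.exon_len_max == 390


def test_stats_invariant_to_order():
    a = [[(0, 100), (300, 500)], [(0, 50)], [(10, 900), (1000, 1200)]]
    s1 = exon_intron_stats(a)
    s2 = exon_intron_stats(a[::-1])
    assert s1 == s2


def test_stats_min_median_max_ordering(small_result):
    structures = [
        [(g0, g1) for g0, g1, _q0, _q1 in a.exon_blocks]
        for a in small_result.alignments.values() if a.status == "mapped"
    ]
    s = exon_intron_stats(structures)
    assert s.exon_len_min <= s.exon_len_median <= s.exon_len_max
    assert s.intron_len_min <= s.intron_len_median <= s.intron_len_max


# ---------------------------------------------------------------------------
# partition accounting
# ---------------------------------------------------------------------------

def test_every_transcript_in_exactly_one_class(small_result):
    assignment = small_result.assignment
    assert set(assignment.klass) <= {"A", "B", "C", "chimeric"}
    assert (assignment.klass != "").all()
    assert len(assignment) == len(small_result.records)
    # class C loci carry no coordinates; A/B do
    for locus in small_result.loci_a + small_result.loci_b:
        assert locus.chromosome is not None and locus.strand in "+-"
    for locus in small_result.loci_c:
        assert locus.chromosome is None and not locus.exons
    # membership is a partition as well
    seen = {}
    for locus in small_result.loci:
        for m in locus.members:
            if not m.startswith("m_"):
                assert m not in seen
                seen[m] = locus.locus_id
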