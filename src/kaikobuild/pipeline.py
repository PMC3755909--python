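"""End-to-end driver: simulate -> map -> build gene sets -> profile -> cluster.

This is the orchestration layer used by the CLI and by recovery
evaluations; every step is a thin call into the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import cluster_analysis, expression, gene_build
from .est_clustering import IdentityRule
from .gene_build import GeneLocus
from .simulate import (
    GroundTruth, SimulationConfig, TranscriptRecord,
    manifest_frame, predicted_models, simulate_genome, simulate_libraries,
)
from .spliced_alignment import GenomeIndex, MappingThresholds, SplicedAlignment, align_transcript


@dataclass
class PipelineResult:
    config: SimulationConfig
    genome: Dict[str, str]
    truth: GroundTruth
    records: List[TranscriptRecord]
    alignments: Dict[str, SplicedAlignment]
    loci_a: List[GeneLocus]
    loci_b: List[GeneLocus]
    loci_c: List[GeneLocus]
    assignment: pd.DataFrame          # clone_id, type, library, class, locus_id
    calls: pd.DataFrame               # locus_id, tissue, chrom, start, end, total
    clusters: List[cluster_analysis.GeneCluster]
    profiles: Dict[str, expression.ExpressionProfile] = field(default_factory=dict)

    @property
    def loci(self) -> List[GeneLocus]:
        return self.loci_a + self.loci_b + self.loci_c


def map_all(
    records: Sequence[TranscriptRecord],
    genome: Dict[str, str],
    thresholds: MappingThresholds = MappingThresholds(),
) -> Dict[str, SplicedAlignment]:
    index = GenomeIndex(genome, k=thresholds.seed_k)
    return {
        r.clone_id: align_transcript(r.clone_id, r.sequence, index, thresholds)
        for r in records
    }


def build_gene_sets(
    records: Sequence[TranscriptRecord],
    alignments: Dict[str, SplicedAlignment],
    models: Optional[pd.DataFrame],
    rule: IdentityRule = IdentityRule(),
) -> Tuple[List[GeneLocus], List[GeneLocus], List[GeneLocus], pd.DataFrame]:
    """Partition every transcript into set A / B / C / excluded-chimeric."""
    by_id = {r.clone_id: r for r in records}
    flc_mrna = [
        alignments[r.clone_id] for r in records
        if r.rtype in ("FLC", "mRNA") and alignments[r.clone_id].status == "mapped"
    ]
    loci_a = gene_build.group_loci(flc_mrna, models)
    est_alns = [
        alignments[r.clone_id] for r in records
        if r.rtype == "EST" and alignments[r.clone_id].status == "mapped"
    ]
    est_assigned, leftovers = gene_build.attach_ests(loci_a, est_alns)
    loci_b = gene_build.build_est_genes(leftovers)
    unmapped = [
        r for r in records
        if alignments[r.clone_id].status in ("unmapped_low_coverage", "unmapped_low_homology")
    ]
    loci_c = gene_build.cluster_unmapped(unmapped, rule)

    locus_of: Dict[str, str] = {}
    for locus in loci_a + loci_b + loci_c:
        for m in locus.members:
            if m in by_id:
                locus_of[m] = locus.locus_id
    rows = []
    for r in records:
        status = alignments[r.clone_id].status
        if status == "chimeric":
            klass, locus = "chimeric", ""
        else:
            locus = locus_of.get(r.clone_id, "")
            klass = {"A": "A", "e": "B", "c": "C"}.get(locus[:1], "") if locus else ""
            if locus.startswith("G"):
                klass = "A"
        rows.append(dict(clone_id=r.clone_id, type=r.rtype, library=r.library,
                         klass=klass, locus_id=locus))
    assignment = pd.DataFrame(rows)
    return loci_a, loci_b, loci_c, assignment


def locus_calls(
    loci: Sequence[GeneLocus],
    assignment: pd.DataFrame,
    manifest: pd.DataFrame,
    min_copies: int = 3,
    min_fraction: float = 0.9,
) -> Tuple[pd.DataFrame, Dict[str, expression.ExpressionProfile]]:
    """Tissue calls with coordinates for all placed (A/B) loci."""
    ests = assignment[(assignment.type == "EST") & (assignment.locus_id != "")]
    profiles = expression.count_est_support(
        ests, manifest, loci=[l.locus_id for l in loci]
    )
    rows = []
    for locus in loci:
        if locus.chromosome is None:
            continue
        call = expression.call_tissue_specific(
            profiles[locus.locus_id], min_copies, min_fraction
        )
        rows.append(dict(
            locus_id=locus.locus_id, tissue=call.specific_tissue or "",
            chrom=locus.chromosome, start=locus.start, end=locus.end,
            total=profiles[locus.locus_id].total,
        ))
    return pd.DataFrame(rows), profiles


def run_pipeline(
    config: SimulationConfig,
    thresholds: MappingThresholds = MappingThresholds(),
    rule: IdentityRule = IdentityRule(),
    cluster_gap: int = 100_000,
) -> PipelineResult:
    genome, truth = simulate_genome(config)
    records = simulate_libraries(genome, truth, config)
    alignments = map_all(records, genome, thresholds)
    models = predicted_models(truth, config)
    loci_a, loci_b, loci_c, assignment = build_gene_sets(records, alignments, models, rule)
    manifest = manifest_frame(config, truth)
    calls, profiles = locus_calls(loci_a + loci_b, assignment, manifest)
    clusters = cluster_analysis.detect_clusters(calls, cluster_gap)
    return PipelineResult(
        config=config, genome=genome, truth=truth, records=records,
        alignments=alignments, loci_a=loci_a, loci_b=loci_b, loci_c=loci_c,
        assignment=assignment, calls=calls, clusters=clusters, profiles=profiles,
    )


# ---------------------------------------------------------------------------
# truth-recovery metrics
# ---------------------------------------------------------------------------

def structure_recovery(truth: GroundTruth,
                       alignments: Dict[str, SplicedAlignment]) -> Tuple[int, int]:
    """(n_exact, n_evaluated): mapped non-chimeric FLC/mRNA whose recovered
    exon blocks equal the planted gene structure exactly.

    The terminal exon is allowed to extend past the annotated 3' end (the
    aligner may absorb poly-A-tail As matching downstream genomic As) and
    the 5' end may start within the first exon for truncated evidence; all
    internal junctions must match exactly.
    """
    tx = truth.transcripts
    n_exact = n_eval = 0
    for row in tx[(tx.type.isin(["FLC", "mRNA"])) & (~tx.is_chimera)].itertuples():
        gene = truth.genes[truth.genes.gene_id == row.gene_id].iloc[0]
        if bool(gene.unplaced):
            continue
        aln = alignments.get(row.clone_id)
        if aln is None or aln.status != "mapped":
            continue
        n_eval += 1
        true_blocks = list(zip(
            (int(x) for x in gene.exon_starts.split(",")),
            (int(x) for x in gene.exon_ends.split(",")),
        ))
        got = [(g0, g1) for g0, g1, _q0, _q1 in aln.exon_blocks]
        if aln.chromosome == gene.chrom and aln.strand == gene.strand and \
                _blocks_match(true_blocks, got, gene.strand):
            n_exact += 1
    return n_exact, n_eval


def _blocks_match(truth_blocks, got, strand) -> bool:
    """Exact agreement of every internal splice junction; the two outer
    ends may shift (5' truncation, poly-A absorption) but must still
    overlap their terminal exon."""
    if len(truth_blocks) != len(got):
        return False
    n = len(got)
    for i in range(n):
        ts, te = truth_blocks[i]
        gs, ge = got[i]
        if i > 0 and gs != ts:
            return False
        if i < n - 1 and ge != te:
            return False
        if ge <= ts or gs >= te:       # outer block must overlap truth exon
            return False
    return True


def chimera_confusion(truth: GroundTruth,
                      alignments: Dict[str, SplicedAlignment]) -> Tuple[int, int, int, int]:
    """(tp, fn, fp, tn) of chimera flags against truth."""
    tx = truth.transcripts
    tp = fn = fp = tn = 0
    for row in tx[tx.type == "FLC"].itertuples():
        called = alignments[row.clone_id].status == "chimeric"
        if row.is_chimera:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return tp, fn, fp, tn


def tissue_call_confusion(
    result: PipelineResult, min_truth_ests: int = 8
) -> Tuple[int, int, int, int]:
    """(tp, fn, fp, n_broad): recall of planted tissue-specific genes with
    >= min_truth_ests simulated ESTs, and false calls among broad genes."""
    truth = result.truth
    est_counts = truth.transcripts.query("type == 'EST'").groupby("gene_id").size()
    locus_tissue = dict(zip(result.calls.locus_id, result.calls.tissue))
    gene_locus = _gene_to_locus(result)
    tp = fn = fp = n_broad = 0
    for gene in truth.genes[~truth.genes.unplaced].itertuples():
        locus = gene_locus.get(gene.gene_id)
        called = locus_tissue.get(locus, "") if locus else ""
        if gene.tissue == "broad":
            n_broad += 1
            fp += bool(called)
        elif est_counts.get(gene.gene_id, 0) >= min_truth_ests:
            if called == gene.tissue:
                tp += 1
            else:
                fn += 1
    return tp, fn, fp, n_broad


def _gene_to_locus(result: PipelineResult) -> Dict[str, str]:
    """Majority-vote mapping of truth genes to built loci via transcripts."""
    tx = result.truth.transcripts
    merged = tx.merge(result.assignment[["clone_id", "locus_id"]], on="clone_id")
    merged = merged[merged.locus_id != ""]
    out: Dict[str, str] = {}
    for gene, sub in merged.groupby("gene_id"):
        out[gene] = sub.locus_id.value_counts().index[0]
    return out
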