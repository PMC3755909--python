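"""Tissue-specific gene clusters, adjacency testing, and density metrics.

Two same-tissue-specific genes belong to one cluster when the gap between
their genomic intervals (end of one to start of the next) is at most
``cluster_gap`` (default 100 kb) on the same chromosome; chains of two or
more form clusters.  Whether tissue-specific genes attract each other along
the chromosome is tested with a Fisher exact test on a 2x2 table built over
ordered adjacent locus pairs.  Density enrichment (e.g. testis-specific
genes on the Z chromosome) is reported as per-bp density over the focal
chromosome divided by the genome-wide per-bp density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._align import OP_MATCH, encode, sw_align


@dataclass
class GeneCluster:
    cluster_id: str
    tissue: str
    chromosome: str
    members: List[str]                  # locus ids ordered by position
    span: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a cluster needs >= 2 members")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def detect_clusters(calls: pd.DataFrame, cluster_gap: int = 100_000) -> List[GeneCluster]:
    """Chain same-tissue specific loci whose interval gap is <= cluster_gap.

    ``calls`` columns: locus_id, tissue (specific tissue, '' or NaN for
    non-specific), chrom, start, end.  Output is ordered and idempotent.
    """
    spec = calls[calls.tissue.fillna("").astype(str) != ""].copy()
    clusters: List[GeneCluster] = []
    for (tissue, chrom), sub in spec.groupby(["tissue", "chrom"], sort=True):
        sub = sub.sort_values(["start", "locus_id"])
        chain: List[Tuple[str, int, int]] = []
        chain_end = None
        for row in sub.itertuples():
            if chain_end is not None and row.start - chain_end <= cluster_gap:
                chain.append((row.locus_id, row.start, row.end))
                chain_end = max(chain_end, row.end)
            else:
                if len(chain) >= 2:
                    clusters.append(_mk_cluster(tissue, chrom, chain, len(clusters)))
                chain = [(row.locus_id, row.start, row.end)]
                chain_end = row.end
        if len(chain) >= 2:
            clusters.append(_mk_cluster(tissue, chrom, chain, len(clusters)))
    return clusters


def _mk_cluster(tissue, chrom, chain, i) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"K{i + 1:04d}", tissue=tissue, chromosome=chrom,
        members=[m for m, _s, _e in chain],
        span=max(e for _m, _s, e in chain) - min(s for _m, s, _e in chain),
    )


def summarize_clusters(
    calls: pd.DataFrame,
    clusters: Sequence[GeneCluster],
    duplicated: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Per-tissue clustering summary plus a Total row.

    Percentages are rounded to integer percent; a tissue with no specific
    genes reports fractions as NA (rendered "-" downstream).
    """
    spec = calls[calls.tissue.fillna("").astype(str) != ""]
    duplicated = duplicated or {}
    rows = []
    tissues = sorted(spec.tissue.unique())
    for tissue in tissues:
        n_specific = int((spec.tissue == tissue).sum())
        cl = [c for c in clusters if c.tissue == tissue]
        clustered = [m for c in cl for m in c.members]
        n_dup = sum(1 for m in clustered if duplicated.get(m, False))
        rows.append(dict(
            tissue=tissue, n_specific=n_specific, n_clustered=len(clustered),
            fraction_clustered_pct=(
                round(100.0 * len(clustered) / n_specific) if n_specific else np.nan
            ),
            n_clusters=len(cl),
            n_duplicated=n_dup,
            fraction_duplicated_in_clusters=(
                round(n_dup / len(clustered), 2) if clustered else np.nan
            ),
        ))
    n_specific = int(len(spec))
    clustered_all = [m for c in clusters for m in c.members]
    n_dup = sum(1 for m in clustered_all if duplicated.get(m, False))
    rows.append(dict(
        tissue="Total", n_specific=n_specific, n_clustered=len(clustered_all),
        fraction_clustered_pct=(
            round(100.0 * len(clustered_all) / n_specific) if n_specific else np.nan
        ),
        n_clusters=len(clusters),
        n_duplicated=n_dup,
        fraction_duplicated_in_clusters=(
            round(n_dup / len(clustered_all), 2) if clustered_all else np.nan
        ),
    ))
    return pd.DataFrame(rows)


def adjacency_table(loci: pd.DataFrame, same_tissue: bool = False) -> ContingencyTable2x2:
    """2x2 adjacency counts over genome-ordered neighbouring locus pairs.

    ``loci`` columns: locus_id, chrom, start, tissue ('' for non-specific).
    Rows: first locus of the pair tissue-specific yes/no.  Columns: second
    locus tissue-specific yes/no.  With ``same_tissue=True`` the column for
    specific-first pairs instead asks whether the second locus is specific
    for the *same* tissue as the first (an alternative, stricter reading;
    its two rows are then not directly comparable, which weakens the
    independence test, so the symmetric construction is the default).
    Chromosomes with fewer than two loci contribute nothing.
    """
    a = b = c = d = 0
    for _chrom, sub in loci.groupby("chrom"):
        sub = sub.sort_values(["start", "locus_id"])
        tissues = sub.tissue.fillna("").astype(str).tolist()
        for t1, t2 in zip(tissues[:-1], tissues[1:]):
            if t1:
                hit = (t2 == t1) if same_tissue else bool(t2)
                if hit:
                    a += 1
                else:
                    b += 1
            else:
                if t2:
                    c += 1
                else:
                    d += 1
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Exact two-sided p: total hypergeometric mass of tables (same margins)
    no more probable than the observed one.  Any zero margin gives p = 1.

    Computed in exact rational arithmetic (ties included exactly), so the
    result carries no floating-point tie ambiguity; no reporting floor is
    applied.
    """
    from fractions import Fraction
    from math import comb

    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return 1.0
    denom = comb(n, c1)
    weights = {
        x: comb(r1, x) * comb(r2, c1 - x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    w_obs = weights[a]
    p = Fraction(sum(w for w in weights.values() if w <= w_obs), denom)
    return float(p)


# ---------------------------------------------------------------------------
# duplication screening
# ---------------------------------------------------------------------------

def _pair_identity(a: str, b: str) -> Tuple[float, float]:
    """(identity over aligned columns, aligned coverage of the shorter seq)
    from a local nucleotide alignment."""
    if not a or not b:
        return 0.0, 0.0
    _s, qs, qe, ts, te, ops = sw_align(encode(a), encode(b), 1.0, -1.0, -2.0)
    if len(ops) == 0:
        return 0.0, 0.0
    ident = float((ops == OP_MATCH).sum()) / len(ops)
    cov = min(qe - qs, te - ts) / min(len(a), len(b))
    return ident, cov


def duplication_fraction(
    member_sequences: Mapping[str, str],
    identity_threshold: float = 0.7,
    coverage_threshold: float = 0.5,
) -> Tuple[float, int]:
    """Fraction of cluster members linked to >=1 other member by sequence
    similarity (identity over >= coverage_threshold of the shorter
    sequence).  Members with missing sequences are excluded."""
    ids = sorted(k for k, v in member_sequences.items() if v)
    if not ids:
        return 0.0, 0
    dup = {k: False for k in ids}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if dup[ids[i]] and dup[ids[j]]:
                continue
            ident, cov = _pair_identity(member_sequences[ids[i]], member_sequences[ids[j]])
            if ident >= identity_threshold and cov >= coverage_threshold:
                dup[ids[i]] = dup[ids[j]] = True
    n_dup = sum(dup.values())
    return n_dup / len(ids), n_dup


def chromosome_density_ratio(
    calls: pd.DataFrame,
    tissue: str,
    chromosome: str,
    chrom_lengths: Mapping[str, int],
) -> float:
    """(specific genes on chromosome / its length) over
    (specific genes genome-wide / genome length)."""
    spec = calls[calls.tissue.fillna("").astype(str) == tissue]
    n_total = len(spec)
    if n_total == 0:
        raise ValueError(f"no {tissue}-specific genes genome-wide")
    genome_len = sum(chrom_lengths.values())
    n_chrom = int((spec.chrom == chromosome).sum())
    return (n_chrom / chrom_lengths[chromosome]) / (n_total / genome_len)
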