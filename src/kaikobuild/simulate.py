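"""Deterministic miniature genome / cDNA-library simulator.

Emulates the statistical structure an FL-cDNA gene-build assumes: a small
multi-chromosome genome whose introns are inflated by transposon-like
repeats, planted multi-exon gene models with canonical GT..AG splice sites,
tissue-biased EST libraries (a Z-like chromosome enriched for
testis-specific genes, compact autosomal ovary-like clusters), 5'-truncated
error-bearing ESTs, full-length clones with poly-A tails, and a small
fraction of chimeric (fused) clones.  A ground-truth table accompanies every
simulation for parameter-recovery tests.

Length distributions are lognormal, parameterized by their median and mean
(the two statistics usually reported for exon/intron sizes) and clipped to
configurable bounds.  Exon counts are 1 + Poisson.  All randomness flows
from ``config.seed``; the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import revcomp, write_fasta, write_gff3, write_tsv

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """A gene could not be placed without overlap."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterSpec:
    """A planted tissue-specific gene cluster.

    ``n_duplicated`` members form one duplication family (shared exon
    structure, ~3% diverged copies) so cluster duplication fractions are
    recoverable against truth.
    """

    tissue: str
    chromosome: str
    span_bp: int
    n_genes: int
    n_duplicated: int = 0


def _default_libraries() -> Dict[str, Tuple[str, int]]:
    # two testis libraries on purpose: tissue pooling across libraries is
    # part of the downstream contract
    return {
        "ftes": ("testis", 400),
        "bmte": ("testis", 200),
        "bmov": ("ovary", 300),
        "fmgV": ("midgut", 400),
        "ffbm": ("fat_body", 300),
        "fwgP": ("wing", 300),
        "fepM": ("epidermis", 200),
        "fner": ("brain", 300),
        "fsgl": ("silk_gland", 200),
    }


def _default_clusters() -> List[ClusterSpec]:
    return [
        ClusterSpec("ovary", "chr2", 100_000, 12, n_duplicated=5),
        ClusterSpec("midgut", "chr3", 150_000, 8, n_duplicated=4),
        ClusterSpec("wing", "chr4", 120_000, 6, n_duplicated=0),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4          # first one is the Z-like chromosome
    chromosome_length: int = 1_000_000
    n_genes: int = 200
    n_unplaced_genes: int = 6       # off-assembly (W-like) genes -> gene set C

    # exon-count distribution: 1 + Poisson(mean - 1)
    exon_count_mean: float = 4.8
    # lognormal length distributions, (median, mean) parameterization
    exon_len_median: float = 179.0
    exon_len_mean: float = 353.0
    exon_len_min: int = 27
    exon_len_max: int = 8000
    intron_len_median: float = 730.0
    intron_len_mean: float = 1904.0
    intron_len_min: int = 34
    intron_len_max: int = 20_000

    gc_content: float = 0.38
    te_fraction: float = 0.35
    min_intergenic: int = 2000

    tissues: List[str] = field(
        default_factory=lambda: [
            "testis", "ovary", "midgut", "fat_body",
            "wing", "epidermis", "brain", "silk_gland",
        ]
    )
    libraries: Dict[str, Tuple[str, int]] = field(default_factory=_default_libraries)
    tissue_specific_fraction: float = 0.35
    specific_tissue_weights: Dict[str, float] = field(
        default_factory=lambda: {"testis": 4.0}
    )
    cluster_plant_spec: List[ClusterSpec] = field(default_factory=_default_clusters)
    testis_z_enrichment: float = 1.6    # target Z density / genome-average density

    # transcript libraries
    model_fraction: float = 0.7         # genes with a predicted gene model
    flc_fraction: float = 0.9           # genes receiving a full-length clone
    n_mrna: int = 8                     # public-mRNA-like records
    est_mean_specific: float = 12.0     # Poisson mean ESTs per specific gene
    est_mean_broad: float = 6.0
    est_error_rate: float = 0.01
    est_truncation_scale: float = 20.0  # exponential 5' truncation offset, bp
    est_read_len_mean: float = 500.0
    est_read_len_sd: float = 60.0
    est_read_len_min: int = 150
    cross_tissue_leakage: float = 0.002
    chimera_rate: float = 0.02
    flc_error_rate: float = 0.0005
    polya_min: int = 10
    polya_max: int = 30

    def chromosome_names(self) -> List[str]:
        return ["chrZ"] + [f"chr{i + 2}" for i in range(self.n_chromosomes - 1)]

    def validate(self) -> None:
        for name, v in [
            ("te_fraction", self.te_fraction),
            ("tissue_specific_fraction", self.tissue_specific_fraction),
            ("est_error_rate", self.est_error_rate),
            ("chimera_rate", self.chimera_rate),
            ("flc_fraction", self.flc_fraction),
            ("cross_tissue_leakage", self.cross_tissue_leakage),
            ("gc_content", self.gc_content),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_chromosomes < 1 or self.chromosome_length < 1000:
            raise ConfigurationError("need >=1 chromosome of >=1 kb")
        names = set(self.chromosome_names())
        for spec in self.cluster_plant_spec:
            if spec.chromosome not in names:
                raise ConfigurationError(f"cluster chromosome {spec.chromosome} unknown")
            if spec.span_bp > self.chromosome_length:
                raise ConfigurationError("planted cluster span exceeds chromosome")
            if spec.tissue not in self.tissues:
                raise ConfigurationError(f"cluster tissue {spec.tissue} unknown")
            if spec.n_duplicated > spec.n_genes:
                raise ConfigurationError("n_duplicated exceeds cluster size")
        n_cluster = sum(s.n_genes for s in self.cluster_plant_spec)
        if self.n_genes and n_cluster > self.n_genes:
            raise ConfigurationError("planted cluster genes exceed n_genes")
        for lib, (tissue, n) in self.libraries.items():
            if tissue not in self.tissues:
                raise ConfigurationError(f"library {lib} names unknown tissue {tissue}")
        w = self.testis_z_enrichment / self.n_chromosomes
        if w > 0.95:
            raise ConfigurationError("testis_z_enrichment infeasible for this genome")


@dataclass
class TranscriptRecord:
    clone_id: str
    library: str            # "" for mRNA-type records
    rtype: str              # EST | FLC | mRNA
    sequence: str

    @property
    def header(self) -> str:
        return f"{self.clone_id}|{self.library}|{self.rtype}"


@dataclass
class GroundTruth:
    genes: pd.DataFrame
    transcripts: Optional[pd.DataFrame] = None
    aux_sequences: Dict[str, str] = field(default_factory=dict)

    def exon_blocks(self, gene_id: str) -> List[Tuple[int, int]]:
        row = self.genes.set_index("gene_id").loc[gene_id]
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# annotation (placement) layer
# ---------------------------------------------------------------------------

def _clipped_lognormal_mean(mu, sigma, lo, hi):
    from scipy.stats import norm

    zlo = (math.log(lo) - mu) / sigma
    zhi = (math.log(hi) - mu) / sigma
    body = math.exp(mu + sigma * sigma / 2.0) * (
        norm.cdf(zhi - sigma) - norm.cdf(zlo - sigma)
    )
    return lo * norm.cdf(zlo) + body + hi * (1.0 - norm.cdf(zhi))


def _lognormal_lengths(rng, n, median, mean, lo, hi):
    """Clipped lognormal draws whose *clipped* expectation equals ``mean``.

    mu/sigma come from the (median, mean) parameterization; clipping to
    [lo, hi] would bias the realized mean low, so the log-scale is shifted
    (bisection on the closed-form clipped mean) to compensate.
    """
    mu, sigma = _corrected_params(float(median), float(mean), float(lo), float(hi))
    vals = rng.lognormal(mu, sigma, n)
    return np.clip(np.round(vals).astype(np.int64), lo, hi)


@lru_cache(maxsize=64)
def _corrected_params(median, mean, lo, hi):
    mu = math.log(median)
    sigma = math.sqrt(max(1e-9, 2.0 * math.log(max(1.0 + 1e-9, mean / median))))
    s_lo, s_hi = 0.5, 4.0
    for _ in range(48):
        s = math.sqrt(s_lo * s_hi)
        if _clipped_lognormal_mean(mu + math.log(s), sigma, lo, hi) < mean:
            s_lo = s
        else:
            s_hi = s
    return mu + math.log(math.sqrt(s_lo * s_hi)), sigma


def _draw_structure(rng, cfg: SimulationConfig, compact: bool = False):
    """Return (exon_lens, intron_lens) for one gene."""
    if compact:
        n_exons = 1 + rng.poisson(1.5)
        exon_lens = _lognormal_lengths(
            rng, n_exons, cfg.exon_len_median, cfg.exon_len_mean, cfg.exon_len_min, 2000
        )
        intron_lens = _lognormal_lengths(
            rng, max(0, n_exons - 1), 300.0, 500.0, cfg.intron_len_min, 2000
        )
    else:
        n_exons = 1 + rng.poisson(max(0.0, cfg.exon_count_mean - 1.0))
        exon_lens = _lognormal_lengths(
            rng, n_exons, cfg.exon_len_median, cfg.exon_len_mean,
            cfg.exon_len_min, cfg.exon_len_max,
        )
        intron_lens = _lognormal_lengths(
            rng, max(0, n_exons - 1), cfg.intron_len_median, cfg.intron_len_mean,
            cfg.intron_len_min, cfg.intron_len_max,
        )
    return exon_lens, intron_lens


def _structure_coords(start, exon_lens, intron_lens):
    starts, ends = [], []
    pos = start
    for i, el in enumerate(exon_lens):
        starts.append(pos)
        pos += int(el)
        ends.append(pos)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    return starts, ends


class _FreeSpace:
    """Per-chromosome free-interval bookkeeping for overlap-free placement."""

    def __init__(self, length: int):
        self.segments: List[Tuple[int, int]] = [(0, length)]

    def place(self, rng, length: int, margin: int) -> Optional[int]:
        need = length + 2 * margin
        fits = [(i, s, e) for i, (s, e) in enumerate(self.segments) if e - s >= need]
        if not fits:
            return None
        weights = np.array([e - s - need + 1 for _, s, e in fits], dtype=float)
        idx = rng.choice(len(fits), p=weights / weights.sum())
        i, s, e = fits[idx]
        offset = int(rng.integers(0, e - s - need + 1))
        start = s + margin + offset
        del self.segments[i]
        if start - margin > s:
            self.segments.insert(i, (s, start - margin))
        if start + length + margin < e:
            self.segments.append((start + length + margin, e))
        self.segments.sort()
        return start


def simulate_annotation(config: SimulationConfig) -> GroundTruth:
    """Place genes (structures, strands, tissue labels) without sequence.

    Cheap enough for replicated null simulations; :func:`simulate_genome`
    builds sequences on top of it.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chroms = config.chromosome_names()
    lengths = {c: config.chromosome_length for c in chroms}
    free = {c: _FreeSpace(lengths[c]) for c in chroms}

    rows = []

    # --- planted clusters ---------------------------------------------------
    for ci, spec in enumerate(config.cluster_plant_spec):
        cluster_id = f"cl{ci:02d}"
        span_start = free[spec.chromosome].place(rng, spec.span_bp, config.min_intergenic)
        if span_start is None:
            raise PlacementError(f"cannot place cluster {cluster_id} on {spec.chromosome}")
        structures = []
        for gi in range(spec.n_genes):
            if 0 < gi < spec.n_duplicated:
                structures.append(structures[0])       # family copies share structure
            else:
                structures.append(_draw_structure(rng, config, compact=True))
        glens = [int(sum(ex) + sum(iv)) for ex, iv in structures]
        slack = spec.span_bp - sum(glens) - 50 * (spec.n_genes + 1)
        if slack < 0:
            raise PlacementError(f"cluster {cluster_id} genes do not fit in span")
        gaps = rng.multinomial(slack, np.ones(spec.n_genes + 1) / (spec.n_genes + 1))
        pos = span_start
        founder_strand = "+" if rng.random() < 0.5 else "-"
        for gi, (ex, iv) in enumerate(structures):
            pos += 50 + int(gaps[gi])
            starts, ends = _structure_coords(pos, ex, iv)
            strand = founder_strand if gi < spec.n_duplicated else (
                "+" if rng.random() < 0.5 else "-"
            )
            rows.append(dict(
                chrom=spec.chromosome, strand=strand,
                exon_starts=starts, exon_ends=ends,
                tissue=spec.tissue, cluster_id=cluster_id,
                family_id=f"{cluster_id}_fam" if gi < spec.n_duplicated else "",
                unplaced=False,
            ))
            pos = ends[-1]

    n_cluster = sum(s.n_genes for s in config.cluster_plant_spec)

    # --- tissue labels for the remaining genes ------------------------------
    n_rest = config.n_genes - n_cluster
    n_specific = max(0, int(round(config.tissue_specific_fraction * config.n_genes)) - n_cluster)
    n_specific = min(n_specific, n_rest)
    weights = np.array(
        [config.specific_tissue_weights.get(t, 1.0) for t in config.tissues], dtype=float
    )
    weights /= weights.sum()
    labels = list(rng.choice(config.tissues, size=n_specific, p=weights))
    labels += ["broad"] * (n_rest - n_specific)
    # placement is sequential and space fills up as it proceeds; shuffle so
    # placement-order artifacts cannot correlate with tissue labels
    labels = [labels[i] for i in rng.permutation(len(labels))]

    total_len = sum(lengths.values())
    len_arr = np.array([lengths[c] for c in chroms], dtype=float)
    base_p = len_arr / len_arr.sum()
    w_z = config.testis_z_enrichment * lengths["chrZ"] / total_len
    testis_p = np.array(
        [w_z] + list((1.0 - w_z) * len_arr[1:] / len_arr[1:].sum()), dtype=float
    )

    for gi, tissue in enumerate(labels):
        p = testis_p if tissue == "testis" else base_p
        start = None
        for _attempt in range(10):       # redraw structure if space is tight
            ex, iv = _draw_structure(rng, config)
            glen = int(sum(ex) + sum(iv))
            for chrom in rng.choice(chroms, size=len(chroms), replace=False, p=p):
                start = free[chrom].place(rng, glen, config.min_intergenic)
                if start is not None:
                    break
            if start is not None:
                break
        if start is None:
            raise PlacementError(f"cannot place gene index {gi} (length {glen})")
        starts, ends = _structure_coords(start, ex, iv)
        rows.append(dict(
            chrom=chrom, strand="+" if rng.random() < 0.5 else "-",
            exon_starts=starts, exon_ends=ends,
            tissue=tissue, cluster_id="", family_id="", unplaced=False,
        ))

    # --- off-assembly genes --------------------------------------------------
    for _ in range(config.n_unplaced_genes):
        ex, _ = _draw_structure(rng, config)
        rows.append(dict(
            chrom="", strand="+",
            exon_starts=[0], exon_ends=[int(sum(ex))],
            tissue="broad", cluster_id="", family_id="", unplaced=True,
        ))

    columns = ["chrom", "strand", "exon_starts", "exon_ends", "tissue",
               "cluster_id", "family_id", "unplaced"]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        df = pd.DataFrame(columns=["gene_id"] + columns + ["start", "end"])
        df["unplaced"] = df.unplaced.astype(bool)
        return GroundTruth(genes=df)
    placed = df[~df.unplaced].copy()
    placed["start"] = placed.exon_starts.map(lambda v: v[0])
    placed = placed.sort_values(["chrom", "start"]).drop(columns="start")
    df = pd.concat([placed, df[df.unplaced]], ignore_index=True)
    df.insert(0, "gene_id", [f"g{i:05d}" for i in range(len(df))])
    df["start"] = df.exon_starts.map(lambda v: int(v[0]))
    df["end"] = df.exon_ends.map(lambda v: int(v[-1]))
    df["exon_starts"] = df.exon_starts.map(lambda v: ",".join(map(str, v)))
    df["exon_ends"] = df.exon_ends.map(lambda v: ",".join(map(str, v)))
    return GroundTruth(genes=df)


# ---------------------------------------------------------------------------
# sequence layer
# ---------------------------------------------------------------------------

def _random_bases(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def _mutate_bytes(rng, arr: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0 or len(arr) == 0:
        return arr
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        arr = arr.copy()
        shift = rng.integers(1, 4, size=n)
        idx = np.searchsorted(np.array([65, 67, 71, 84], dtype=np.uint8), arr[hit])
        arr[hit] = BASES[(idx + shift) % 4]
    return arr


def _mutate_str(rng, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _mutate_bytes(rng, arr, rate).tobytes().decode()


def simulate_genome(config: SimulationConfig) -> Tuple[Dict[str, str], GroundTruth]:
    """Build the genome sequence for a placement and return (assembly, truth).

    Guarantees: GT at every intron 5' end and AG at every 3' end (in the
    gene's reading orientation), transposon-like repeats only in intronic
    and intergenic space, duplicated-family exons ~3% diverged copies of
    their founder.
    """
    truth = simulate_annotation(config)
    rng = np.random.default_rng([config.seed, 2])
    chroms = config.chromosome_names()
    arrays = {c: _random_bases(rng, config.chromosome_length, config.gc_content)
              for c in chroms}

    genes = truth.genes
    placed = genes[~genes.unplaced]

    # transposon-like repeats in non-exonic space
    te_lib = [_random_bases(rng, int(rng.integers(250, 451)), 0.34) for _ in range(4)]
    for chrom in chroms:
        sub = placed[placed.chrom == chrom]
        blocked = []
        for row in sub.itertuples():
            starts = [int(x) for x in row.exon_starts.split(",")]
            ends = [int(x) for x in row.exon_ends.split(",")]
            for s, e in zip(starts, ends):
                blocked.append((s, e))
            for a, b in zip(ends[:-1], starts[1:]):        # protect splice sites
                blocked.append((a, a + 2))
                blocked.append((b - 2, b))
        blocked.sort()
        eligible, prev = [], 0
        for s, e in blocked + [(config.chromosome_length, config.chromosome_length)]:
            if s > prev:
                eligible.append((prev, s))
            prev = max(prev, e)
        lens = np.array([e - s for s, e in eligible], dtype=float)
        if not len(lens):
            continue
        target = config.te_fraction * lens.sum()
        covered, attempts = 0.0, 0
        arr = arrays[chrom]
        while covered < target and attempts < 20000:
            attempts += 1
            i = rng.choice(len(eligible), p=lens / lens.sum())
            s, e = eligible[i]
            te = te_lib[rng.integers(0, len(te_lib))]
            if e - s < 50:
                continue
            pos = int(rng.integers(s, e - min(len(te), e - s) + 1))
            copy = _mutate_bytes(rng, te[: e - pos], 0.02)
            arr[pos:pos + len(copy)] = copy
            covered += len(copy)

    # duplicated families: overwrite member exons with mutated founder copies
    for fam, sub in placed[placed.family_id != ""].groupby("family_id"):
        sub = sub.sort_values("start")
        founder = sub.iloc[0]
        f_starts = [int(x) for x in founder.exon_starts.split(",")]
        f_ends = [int(x) for x in founder.exon_ends.split(",")]
        f_arr = arrays[founder.chrom]
        for _, row in sub.iloc[1:].iterrows():
            starts = [int(x) for x in row.exon_starts.split(",")]
            ends = [int(x) for x in row.exon_ends.split(",")]
            m_arr = arrays[row.chrom]
            for (fs, fe), (ms, me) in zip(zip(f_starts, f_ends), zip(starts, ends)):
                m_arr[ms:me] = _mutate_bytes(rng, f_arr[fs:fe].copy(), 0.03)

    # canonical splice sites, in each gene's orientation
    GT = np.frombuffer(b"GT", dtype=np.uint8)
    AG = np.frombuffer(b"AG", dtype=np.uint8)
    CT = np.frombuffer(b"CT", dtype=np.uint8)
    AC = np.frombuffer(b"AC", dtype=np.uint8)
    for row in placed.itertuples():
        starts = [int(x) for x in row.exon_starts.split(",")]
        ends = [int(x) for x in row.exon_ends.split(",")]
        arr = arrays[row.chrom]
        for a, b in zip(ends[:-1], starts[1:]):            # intron = [a, b)
            if row.strand == "+":
                arr[a:a + 2] = GT
                arr[b - 2:b] = AG
            else:
                arr[a:a + 2] = CT
                arr[b - 2:b] = AC

    genome = {c: arrays[c].tobytes().decode() for c in chroms}

    for row in genes[genes.unplaced].itertuples():
        n = int(row.end)
        truth.aux_sequences[row.gene_id] = (
            _random_bases(rng, n, config.gc_content).tobytes().decode()
        )
    return genome, truth


def mature_transcript(genome: Dict[str, str], truth: GroundTruth, gene_id: str) -> str:
    """Spliced mature transcript (no tail), in transcription orientation."""
    row = truth.genes.set_index("gene_id").loc[gene_id]
    if bool(row.unplaced):
        return truth.aux_sequences[gene_id]
    seq = "".join(
        genome[row.chrom][int(s):int(e)]
        for s, e in zip(
            (int(x) for x in row.exon_starts.split(",")),
            (int(x) for x in row.exon_ends.split(",")),
        )
    )
    return revcomp(seq) if row.strand == "-" else seq


# ---------------------------------------------------------------------------
# transcript libraries
# ---------------------------------------------------------------------------

def simulate_libraries(
    genome: Dict[str, str], truth: GroundTruth, config: SimulationConfig
) -> List[TranscriptRecord]:
    """Simulate FL-cDNA clones, public-mRNA records, and 5' EST reads.

    Fills ``truth.transcripts`` with one row per emitted record (chimeras
    reference their 3' partner gene).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    genes = truth.genes
    matures = {g: mature_transcript(genome, truth, g) for g in genes.gene_id}

    libs = list(config.libraries)
    lib_tissue = {l: config.libraries[l][0] for l in libs}
    lib_w = np.array([config.libraries[l][1] for l in libs], dtype=float)
    lib_w /= lib_w.sum()
    by_tissue: Dict[str, List[int]] = {}
    for i, l in enumerate(libs):
        by_tissue.setdefault(lib_tissue[l], []).append(i)

    def pick_library(tissue: str) -> str:
        if tissue != "broad" and tissue in by_tissue and rng.random() >= config.cross_tissue_leakage:
            idx = by_tissue[tissue]
            w = lib_w[idx] / lib_w[idx].sum()
            return libs[idx[rng.choice(len(idx), p=w)]]
        return libs[rng.choice(len(libs), p=lib_w)]

    records: List[TranscriptRecord] = []
    rows = []

    # ---- full-length clones -------------------------------------------------
    placed_ids = list(genes[~genes.unplaced].gene_id)
    chrom_of = dict(zip(genes.gene_id, genes.chrom))
    flc_genes = [g for g in genes.gene_id
                 if bool(genes.set_index("gene_id").loc[g, "unplaced"]) or
                 rng.random() < config.flc_fraction]
    counter = 0
    for g in flc_genes:
        counter += 1
        cid = f"FLC{counter:05d}"
        tissue = genes.set_index("gene_id").loc[g, "tissue"]
        lib = pick_library(tissue)
        tail = "A" * int(rng.integers(config.polya_min, config.polya_max + 1))
        is_chimera = (
            chrom_of[g] != "" and rng.random() < config.chimera_rate and len(placed_ids) > 1
        )
        partner = ""
        if is_chimera:
            others = [p for p in placed_ids if chrom_of[p] not in ("", chrom_of[g])]
            seq = None
            for _try in range(20):      # both halves must be a detectable share
                if not others:
                    break
                partner = others[int(rng.integers(0, len(others)))]
                a, b = matures[g], matures[partner]
                n_a = max(1, int((0.45 + 0.10 * rng.random()) * len(a)))
                n_b = len(b) - int((0.45 + 0.10 * rng.random()) * len(b))
                share = min(n_a, n_b) / (n_a + n_b)
                if share >= 0.3:
                    seq = a[:n_a] + b[len(b) - n_b:] + tail
                    break
            if seq is None:
                is_chimera = False
                partner = ""
        if not is_chimera:
            seq = matures[g] + tail
        seq = _mutate_str(rng, seq, config.flc_error_rate)
        records.append(TranscriptRecord(cid, lib, "FLC", seq))
        rows.append(dict(clone_id=cid, gene_id=g, library=lib, type="FLC",
                         is_chimera=is_chimera, partner_gene=partner))

    # ---- public-mRNA-like records ------------------------------------------
    n_mrna = min(config.n_mrna, len(placed_ids))
    for i, g in enumerate(rng.choice(placed_ids, size=n_mrna, replace=False)):
        cid = f"MRNA{i + 1:04d}"
        records.append(TranscriptRecord(cid, "", "mRNA", matures[g]))
        rows.append(dict(clone_id=cid, gene_id=g, library="", type="mRNA",
                         is_chimera=False, partner_gene=""))

    # ---- 5' ESTs ------------------------------------------------------------
    counter = 0
    for row in genes.itertuples():
        mean = config.est_mean_broad if row.tissue == "broad" else config.est_mean_specific
        n_est = int(rng.poisson(mean))
        src = matures[row.gene_id] + "A" * int(
            rng.integers(config.polya_min, config.polya_max + 1)
        )
        for _ in range(n_est):
            counter += 1
            cid = f"EST{counter:06d}"
            trunc = min(int(rng.exponential(config.est_truncation_scale)),
                        max(0, len(src) - 60))
            rlen = max(config.est_read_len_min,
                       int(rng.normal(config.est_read_len_mean, config.est_read_len_sd)))
            est = _mutate_str(rng, src[trunc:trunc + rlen], config.est_error_rate)
            lib = pick_library(row.tissue)
            records.append(TranscriptRecord(cid, lib, "EST", est))
            rows.append(dict(clone_id=cid, gene_id=row.gene_id, library=lib,
                             type="EST", is_chimera=False, partner_gene=""))

    truth.transcripts = pd.DataFrame(
        rows, columns=["clone_id", "gene_id", "library", "type", "is_chimera", "partner_gene"]
    )
    return records


def predicted_models(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Ab-initio-predictor stand-in: truth structures for a random subset of
    placed genes (``model_fraction``), emitted as model features."""
    rng = np.random.default_rng([config.seed, 4])
    placed = truth.genes[~truth.genes.unplaced]
    keep = placed[rng.random(len(placed)) < config.model_fraction].copy()
    keep = keep[["gene_id", "chrom", "strand", "exon_starts", "exon_ends"]].copy()
    keep.insert(0, "model_id", ["m_" + g for g in keep.gene_id])
    return keep.drop(columns="gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# output bundle
# ---------------------------------------------------------------------------

def manifest_frame(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    counts = (
        truth.transcripts.query("type == 'EST'").groupby("library").size()
        if truth.transcripts is not None else {}
    )
    rows = [
        dict(library=l, tissue=t, n_ests=int(counts.get(l, 0)))
        for l, (t, _n) in config.libraries.items()
    ]
    return pd.DataFrame(rows)


def write_outputs(outdir: str, genome: Dict[str, str], truth: GroundTruth,
                  records: Sequence[TranscriptRecord], config: SimulationConfig) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_fasta(os.path.join(outdir, "genome.fasta"), genome.items())
    write_fasta(os.path.join(outdir, "transcripts.fasta"),
                [(r.header, r.sequence) for r in records])
    placed = truth.genes[~truth.genes.unplaced]
    write_gff3(os.path.join(outdir, "truth_genes.gff3"), placed)
    write_tsv(os.path.join(outdir, "truth_genes.tsv"), truth.genes)
    if truth.transcripts is not None:
        write_tsv(os.path.join(outdir, "truth_transcripts.tsv"), truth.transcripts)
    write_tsv(os.path.join(outdir, "library_manifest.tsv"), manifest_frame(config, truth))
    models = predicted_models(truth, config)
    write_gff3(
        os.path.join(outdir, "models.gff3"),
        models.rename(columns={"model_id": "gene_id"}),
        source="predictor",
    )
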