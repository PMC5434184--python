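"""Synthetic data generation for the 3'-anchored insertion-detection pipeline.

Produces toy genomes, gene models, element catalogs, planted insertions with
zygosity/mosaicism, pooled amplicon reads and droplet-partition counts. All
operations are deterministic for a fixed seed.

Read layout (100 nt): 10 nt primer surrogate + 64 nt genomic flank taken
immediately 3' of the insertion junction (strand-appropriately) + 26 nt
untemplated tail. Trimming the first 10 and last 26 bases therefore recovers
the flank exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, ReferenceGenome, revcomp
from .reads import AmpliconRead

PRIMER_SURROGATE = "GGGAGATATA"
HEAD_LEN = len(PRIMER_SURROGATE)
TAIL_LEN = 26
FLANK_LEN = 64
READ_LEN = HEAD_LEN + FLANK_LEN + TAIL_LEN

BASES = np.frombuffer(b"ACGT", dtype="S1")

COCAINE = "cocaine"
CONTROL = "control"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class L1CatalogEntry:
    """A cataloged element, positioned at its 3'-end junction."""

    interval: GenomicInterval
    catalog_class: str  # "KR" or "KNR"
    label: str = ""

    def __post_init__(self) -> None:
        if self.catalog_class not in ("KR", "KNR"):
            raise ValueError(f"bad catalog class {self.catalog_class!r}")

    @property
    def junction(self) -> int:
        """Genomic coordinate of the 3' junction the assay reads from."""
        return self.interval.start if self.interval.strand == "-" else self.interval.end - 1


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    span: GenomicInterval
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        prev_end = self.span.start - 1
        for exon in self.exons:
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(f"{self.gene_id}: exon outside span")
            if exon.start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand != "-" else self.span.end - 1

    @property
    def utr3_end(self) -> int:
        return self.span.end - 1 if self.strand != "-" else self.span.start


@dataclass(frozen=True)
class Carrier:
    allele_count: int  # 1 (het) or 2 (hom)
    mosaic_fraction: float  # 1.0 for germline

    def __post_init__(self) -> None:
        if self.allele_count not in (1, 2):
            raise ValueError("allele_count must be 1 or 2")
        if not 0 < self.mosaic_fraction <= 1:
            raise ValueError("mosaic_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TruthInsertion:
    """A planted insertion: junction point, element strand and carriers."""

    contig: str
    site: int  # insertion point between two reference bases
    strand: str  # strand of the inserted element
    carriers: Mapping[str, Carrier]

    @property
    def is_germline(self) -> bool:
        return all(c.mosaic_fraction == 1.0 for c in self.carriers.values())


@dataclass(frozen=True)
class PoolSpec:
    pool_id: str
    population: str  # "cocaine" or "control"
    individual_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.population not in (COCAINE, CONTROL):
            raise ValueError(f"bad population {self.population!r}")


def default_pools(
    n_pools_per_population: int = 3, individuals_per_pool: int = 10
) -> List[PoolSpec]:
    """The study layout: 3 pools of 10 per population."""
    pools = []
    counter = 0
    for population in (COCAINE, CONTROL):
        for p in range(n_pools_per_population):
            ids = tuple(
                f"ind{counter + i:03d}" for i in range(individuals_per_pool)
            )
            counter += individuals_per_pool
            pools.append(
                PoolSpec(f"{population[:3]}_pool{p + 1}", population, ids)
            )
    return pools


@dataclass
class SimulationConfig:
    genome_length: int = 5_000_000
    gc_fraction: float = 0.41
    n_genes: int = 120
    n_KR: int = 5
    n_KNR: int = 5
    n_novel: int = 40
    germline_fraction: float = 1.0
    mosaic_fraction_range: Tuple[float, float] = (0.05, 0.5)
    depth_per_insertion: int = 20
    duplicate_rate: float = 0.2
    base_error_rate: float = 0.002
    noise_read_fraction: float = 0.02
    read_length: int = READ_LEN
    start_jitter: int = 20
    knr_carrier_prob: float = 0.3
    low_q_error_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < HEAD_LEN + TAIL_LEN + 1:
            raise ValueError("read_length leaves no genomic bases after trimming")
        for name in ("duplicate_rate", "noise_read_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")
        lo, hi = self.mosaic_fraction_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("mosaic_fraction_range must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class DropletCounts:
    total_droplets: int
    positives_target: int
    positives_reference: int
    droplet_volume: float  # microlitres

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")
        for n in (self.positives_target, self.positives_reference):
            if not 0 <= n <= self.total_droplets:
                raise ValueError("positive counts must lie in [0, total]")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive")


# ---------------------------------------------------------------------------
# genome and annotations
# ---------------------------------------------------------------------------

def generate_genome(
    length: int,
    gc_fraction: float = 0.41,
    seed: int = 0,
    contig_name: str = "chrS",
) -> ReferenceGenome:
    """Single-contig random genome with the requested GC content."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    seq = rng.choice(BASES, size=length, p=[at, gc, gc, at])
    return ReferenceGenome({contig_name: seq.tobytes().decode("ascii")})


def _place_intervals(
    rng: np.random.Generator,
    contig: str,
    contig_length: int,
    lengths: Sequence[int],
    occupied: List[Tuple[int, int]],
    margin: int,
    gap: int,
    max_tries: int = 2000,
) -> List[Tuple[int, int]]:
    """Rejection-sample non-overlapping placements, respecting `gap` padding."""
    placed = []
    for feat_len in lengths:
        lo, hi = margin, contig_length - margin - feat_len
        if hi <= lo:
            raise ValueError("genome too small for requested features")
        for _ in range(max_tries):
            start = int(rng.integers(lo, hi))
            end = start + feat_len
            if any(start - gap < e and s < end + gap for s, e in occupied):
                continue
            occupied.append((start, end))
            placed.append((start, end))
            break
        else:
            raise ValueError("genome too small for requested features")
    return placed


def make_annotations(
    genome: ReferenceGenome,
    n_genes: int,
    n_KR: int,
    n_KNR: int,
    seed: int = 0,
    gene_length_range: Tuple[int, int] = (2000, 6000),
    margin: int = 200,
    gap: int = 300,
) -> Tuple[List[GeneModel], List[L1CatalogEntry]]:
    """Random non-overlapping gene models and KR/KNR catalog entries.

    Genes have at least two exons; catalog entries are single-base junction
    marks placed outside exons (they may fall in introns or between genes).
    """
    contig = next(iter(genome))
    contig_len = genome.length(contig)
    rng = np.random.default_rng(seed)

    occupied: List[Tuple[int, int]] = []
    gene_lengths = [
        int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        for _ in range(n_genes)
    ]
    gene_spans = _place_intervals(
        rng, contig, contig_len, gene_lengths, occupied, margin, gap
    )

    genes = []
    exon_spans: List[Tuple[int, int]] = []
    for i, (start, end) in enumerate(sorted(gene_spans)):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        length = end - start
        # carve exons from equal slices so they stay sorted and disjoint
        slice_len = length // n_exons
        exons = []
        for e in range(n_exons):
            es = start + e * slice_len
            exon_len = max(50, int(rng.integers(50, max(51, slice_len // 2))))
            ee = min(es + exon_len, end)
            exons.append(GenomicInterval(contig, es, ee, strand))
            exon_spans.append((es, ee))
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                span=GenomicInterval(contig, start, end, strand),
                exons=tuple(exons),
            )
        )

    # catalog junctions: outside exons, padded away from each other
    cat_occupied = [(s - gap, e + gap) for s, e in exon_spans]
    entries: List[L1CatalogEntry] = []
    classes = ["KR"] * n_KR + ["KNR"] * n_KNR
    placed = _place_intervals(
        rng, contig, contig_len, [1] * len(classes), cat_occupied, margin, 2000
    )
    for i, ((start, end), cls) in enumerate(zip(placed, classes)):
        strand = "+" if rng.random() < 0.5 else "-"
        entries.append(
            L1CatalogEntry(
                interval=GenomicInterval(contig, start, end, strand),
                catalog_class=cls,
                label=f"{cls}_{i:03d}",
            )
        )
    return genes, entries


def plant_insertions(
    genome: ReferenceGenome,
    pools: Sequence[PoolSpec],
    n_novel: int,
    germline_fraction: float = 1.0,
    mosaic_fraction_range: Tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    exclude: Sequence[GenomicInterval] = (),
    min_separation: int = 1000,
    margin: int = 200,
    max_carriers: int = 3,
    hom_prob: float = 0.1,
) -> List[TruthInsertion]:
    """Plant novel insertions with random carrier sets.

    Sites avoid `exclude` intervals (typically catalog junctions) by
    `min_separation` and stay `margin` bases from contig edges so a full
    flank read fits on either strand.
    """
    if not pools:
        raise ValueError("at least one pool is required")
    contig = next(iter(genome))
    contig_len = genome.length(contig)
    rng = np.random.default_rng(seed)

    occupied = [(iv.start - min_separation, iv.end + min_separation) for iv in exclude]
    placed = _place_intervals(
        rng, contig, contig_len, [1] * n_novel, occupied, margin, min_separation
    )

    all_individuals = [ind for pool in pools for ind in pool.individual_ids]
    if len(set(all_individuals)) != len(all_individuals):
        raise ValueError("individual ids must be unique across pools")

    insertions = []
    for start, _end in placed:
        strand = "+" if rng.random() < 0.5 else "-"
        germline = rng.random() < germline_fraction
        if germline:
            fraction = 1.0
        else:
            lo, hi = mosaic_fraction_range
            fraction = float(rng.uniform(lo, hi))
        n_carriers = int(rng.integers(1, max_carriers + 1))
        chosen = rng.choice(len(all_individuals), size=n_carriers, replace=False)
        carriers = {}
        for idx in sorted(chosen):
            allele = 2 if (germline and rng.random() < hom_prob) else 1
            carriers[all_individuals[idx]] = Carrier(allele, fraction)
        insertions.append(TruthInsertion(contig, start, strand, carriers))
    insertions.sort(key=lambda t: t.site)
    return insertions


# ---------------------------------------------------------------------------
# amplicon read simulation
# ---------------------------------------------------------------------------

def _flank_interval(contig_len: int, junction: int, strand: str, offset: int) -> Tuple[int, int]:
    """Genomic window of the trimmed 64-mer for a read at jitter `offset`."""
    if strand == "-":
        start, end = junction - FLANK_LEN - offset, junction - offset
    else:
        start, end = junction + offset, junction + offset + FLANK_LEN
    if start < 0 or end > contig_len:
        raise ValueError("insertion site too close to contig edge for a full flank read")
    return start, end


def _pool_dosage(insertion_carriers: Mapping[str, Carrier], pool: PoolSpec) -> float:
    """Read-generating dosage of an event in a pool, relative to one
    germline heterozygous carrier."""
    return sum(
        c.allele_count * c.mosaic_fraction
        for ind, c in insertion_carriers.items()
        if ind in pool.individual_ids
    )


def _assemble_read(
    rng: np.random.Generator,
    read_id: str,
    flank: str,
    config: SimulationConfig,
) -> AmpliconRead:
    tail = rng.choice(BASES, size=TAIL_LEN).tobytes().decode("ascii")
    seq = list(PRIMER_SURROGATE + flank + tail)
    quals = [37] * len(seq)
    if config.base_error_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < config.base_error_rate)
        for pos in hits:
            alternatives = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(3))]
            if rng.random() < config.low_q_error_fraction:
                quals[pos] = 20
    return AmpliconRead(read_id, "".join(seq), tuple(quals))


def simulate_l1seq_reads(
    genome: ReferenceGenome,
    truth: Sequence[TruthInsertion],
    catalog: Sequence[L1CatalogEntry],
    pools: Sequence[PoolSpec],
    config: SimulationConfig,
) -> Dict[str, List[AmpliconRead]]:
    """Per-pool amplicon reads from planted insertions, catalog elements and
    uniform background noise.

    Expected read count per (event, pool) is ``depth_per_insertion`` scaled
    by pool dosage (one germline het carrier = 1). Catalog KR elements are
    carried homozygously by everyone; KNR carriers are drawn per individual.
    """
    contig = next(iter(genome))
    contig_len = genome.length(contig)
    contig_seq = genome[contig]
    rng = np.random.default_rng(config.seed)

    # event list: (junction, strand, carriers, tag)
    events: List[Tuple[int, str, Mapping[str, Carrier], str]] = []
    for i, ins in enumerate(truth):
        events.append((ins.site, ins.strand, ins.carriers, f"novel{i:04d}"))
    all_individuals = [ind for pool in pools for ind in pool.individual_ids]
    for i, entry in enumerate(catalog):
        if entry.catalog_class == "KR":
            carriers = {ind: Carrier(2, 1.0) for ind in all_individuals}
        else:
            chosen = [
                ind for ind in all_individuals
                if rng.random() < config.knr_carrier_prob
            ]
            if not chosen:
                chosen = [all_individuals[int(rng.integers(len(all_individuals)))]]
            carriers = {ind: Carrier(1, 1.0) for ind in chosen}
        events.append((entry.junction, entry.interval.strand, carriers, entry.label))

    reads_by_pool: Dict[str, List[AmpliconRead]] = {p.pool_id: [] for p in pools}
    for pool in pools:
        pool_reads = reads_by_pool[pool.pool_id]
        n_signal = 0
        for junction, strand, carriers, tag in events:
            dosage = _pool_dosage(carriers, pool)
            if dosage == 0:
                continue
            n_reads = int(rng.poisson(config.depth_per_insertion * dosage))
            offsets: List[int] = []
            for r in range(n_reads):
                if offsets and rng.random() < config.duplicate_rate:
                    offset = offsets[int(rng.integers(len(offsets)))]
                else:
                    offset = int(rng.integers(0, config.start_jitter + 1))
                offsets.append(offset)
                start, end = _flank_interval(contig_len, junction, strand, offset)
                flank = contig_seq[start:end]
                if strand == "-":
                    flank = revcomp(flank)
                read_id = f"{pool.pool_id}:{tag}:{r}"
                pool_reads.append(_assemble_read(rng, read_id, flank, config))
                n_signal += 1
        if config.noise_read_fraction > 0 and n_signal:
            n_noise = int(
                round(
                    n_signal
                    * config.noise_read_fraction
                    / (1 - config.noise_read_fraction)
                )
            )
            for r in range(n_noise):
                start = int(rng.integers(0, contig_len - FLANK_LEN))
                flank = contig_seq[start : start + FLANK_LEN]
                if rng.random() < 0.5:
                    flank = revcomp(flank)
                read_id = f"{pool.pool_id}:noise:{r}"
                pool_reads.append(_assemble_read(rng, read_id, flank, config))
    return reads_by_pool


def make_term_map(
    gene_ids: Sequence[str],
    n_terms: int,
    seed: int = 0,
    term_size_range: Tuple[int, int] = (5, 40),
):
    """Random term -> gene annotation over a gene universe, for exercising
    the over-representation tests end to end."""
    from .enrich import TermGeneMap

    rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    terms = {}
    lo, hi = term_size_range
    hi = min(hi, len(genes))
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        terms[f"TERM:{t:04d}"] = {genes[i] for i in members}
    return TermGeneMap(terms, background_size=len(genes))


# ---------------------------------------------------------------------------
# droplet partition model
# ---------------------------------------------------------------------------

def simulate_droplets(
    target_copies_per_ul: float,
    reference_copies_per_ul: float,
    total_droplets: int = 15000,
    droplet_volume: float = 0.00085,
    seed: int = 0,
) -> DropletCounts:
    """Binomial droplet counts under the standard Poisson partition model.

    A droplet is positive iff it receives >= 1 template molecule, so
    P(positive) = 1 - exp(-copies_per_ul * droplet_volume).
    """
    if target_copies_per_ul < 0 or reference_copies_per_ul < 0:
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    counts = []
    for conc in (target_copies_per_ul, reference_copies_per_ul):
        p = 1.0 - math.exp(-conc * droplet_volume)
        counts.append(int(rng.binomial(total_droplets, p)))
    return DropletCounts(total_droplets, counts[0], counts[1], droplet_volume)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_fasta(genome: ReferenceGenome, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> ReferenceGenome:
    from Bio import SeqIO

    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }
    return ReferenceGenome(contigs)


def write_catalog_bed(entries: Sequence[L1CatalogEntry], path: str) -> None:
    """BED6: name column is '<class>|<label>'."""
    with open(path, "w") as fh:
        for e in entries:
            iv = e.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t"
                f"{e.catalog_class}|{e.label}\t0\t{iv.strand}\n"
            )


def read_catalog_bed(path: str) -> List[L1CatalogEntry]:
    entries = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            cls, _, label = name.partition("|")
            entries.append(
                L1CatalogEntry(
                    GenomicInterval(contig, int(start), int(end), strand), cls, label
                )
            )
    return entries


def write_gene_table(genes: Sequence[GeneModel], path: str) -> None:
    """Tab-delimited gene models with an exon block column."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig\tstart\tend\tstrand\texons\n")
        for g in genes:
            blocks = ",".join(f"{e.start}-{e.end}" for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.span.contig}\t{g.span.start}\t{g.span.end}\t"
                f"{g.span.strand}\t{blocks}\n"
            )


def read_gene_table(path: str) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("gene_id")
        for line in fh:
            gene_id, contig, start, end, strand, blocks = line.rstrip("\n").split("\t")
            exons = tuple(
                GenomicInterval(contig, int(b.split("-")[0]), int(b.split("-")[1]), strand)
                for b in blocks.split(",")
            )
            genes.append(
                GeneModel(gene_id, GenomicInterval(contig, int(start), int(end), strand), exons)
            )
    return genes


def write_truth_table(truth: Sequence[TruthInsertion], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tsite\tstrand\tcarriers\n")
        for t in truth:
            carriers = ",".join(
                f"{ind}:{c.allele_count}:{c.mosaic_fraction:g}"
                for ind, c in sorted(t.carriers.items())
            )
            fh.write(f"{t.contig}\t{t.site}\t{t.strand}\t{carriers}\n")


def read_truth_table(path: str) -> List[TruthInsertion]:
    truth = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            contig, site, strand, carriers_s = line.rstrip("\n").split("\t")
            carriers = {}
            for item in carriers_s.split(","):
                ind, allele, frac = item.split(":")
                carriers[ind] = Carrier(int(allele), float(frac))
            truth.append(TruthInsertion(contig, int(site), strand, carriers))
    return truth


def write_pool_manifest(pools: Sequence[PoolSpec], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("pool_id\tpopulation\tindividual_ids\n")
        for p in pools:
            fh.write(f"{p.pool_id}\t{p.population}\t{','.join(p.individual_ids)}\n")


def read_pool_manifest(path: str) -> List[PoolSpec]:
    pools = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            pool_id, population, ids = line.rstrip("\n").split("\t")
            pools.append(PoolSpec(pool_id, population, tuple(ids.split(","))))
    return pools


def write_droplet_csv(counts: Mapping[str, DropletCounts], path: str) -> None:
    import pandas as pd

    rows = [
        {
            "sample_id": sid,
            "total_droplets": c.total_droplets,
            "positives_target": c.positives_target,
            "positives_reference": c.positives_reference,
            "droplet_volume": c.droplet_volume,
        }
        for sid, c in counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_droplet_csv(path: str) -> Dict[str, DropletCounts]:
    import pandas as pd

    df = pd.read_csv(path)
    return {
        str(row.sample_id): DropletCounts(
            int(row.total_droplets),
            int(row.positives_target),
            int(row.positives_reference),
            float(row.droplet_volume),
        )
        for row in df.itertuples()
    }
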