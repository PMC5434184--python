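"""Candidate-insertion peak calling and filtering.

Same-strand aligned reads whose start positions fall within a 64-nt window
are merged into peaks; each peak carries the quality metrics the two filter
profiles test ("original": mapq/mapscore/maxcount/maxuniq; "new": mean
mapq/mappability/mean matchpct/total reads/unique alignments), a catalog
class (KR / KNR / novel) and a genic-context annotation.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, ReferenceGenome, encode_sequence
from .reads import AlignedRead
from .synth import GeneModel, L1CatalogEntry

DEFAULT_WINDOW = 64
DEFAULT_PROXIMITY = 500
DEFAULT_PROMOTER_WINDOW = 500

KR, KNR, NOVEL = "KR", "KNR", "novel"
INTRAGENIC, INTERGENIC = "intragenic", "intergenic"


@dataclass
class Peak:
    """A strand-consistent cluster of read starts marking one candidate
    insertion junction."""

    interval: GenomicInterval
    insertion_point: int
    per_pool_reads: Dict[str, int]
    per_pool_unique: Dict[str, int]
    unique_alignments: int
    mean_mapq: float
    mean_matchpct: float
    mapscore: float
    mappability: Optional[float] = None
    catalog_class: Optional[str] = None
    genic_context: Optional[str] = None
    gene_id: Optional[str] = None
    member_read_ids: Tuple[str, ...] = ()

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def total_reads(self) -> int:
        return sum(self.per_pool_reads.values())

    @property
    def maxcount(self) -> int:
        return max(self.per_pool_reads.values())

    @property
    def maxuniq(self) -> int:
        return max(self.per_pool_unique.values())


_OPS: Dict[str, Callable[[float, float], bool]] = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
}


@dataclass(frozen=True)
class FilterProfile:
    """Named set of threshold comparisons over Peak metrics."""

    name: str
    thresholds: Tuple[Tuple[str, str, float], ...]

    def accepts(self, peak: Peak) -> bool:
        for metric, op, value in self.thresholds:
            if not hasattr(peak, metric):
                raise AttributeError(f"profile {self.name!r}: Peak has no metric {metric!r}")
            observed = getattr(peak, metric)
            if observed is None:
                raise ValueError(
                    f"profile {self.name!r}: metric {metric!r} not populated on peak"
                )
            if not _OPS[op](observed, value):
                return False
        return True


ORIGINAL_PROFILE = FilterProfile(
    "original",
    (
        ("mean_mapq", ">=", 30),
        ("mapscore", ">", 0.5),
        ("maxcount", ">", 5),
        ("maxuniq", ">", 1),
    ),
)

NEW_PROFILE = FilterProfile(
    "new",
    (
        ("mean_mapq", ">=", 30),
        ("mappability", ">", 0.5),
        ("mean_matchpct", ">", 0.98),
        ("total_reads", ">", 5),
        ("unique_alignments", ">", 1),
    ),
)

PROFILES = {p.name: p for p in (ORIGINAL_PROFILE, NEW_PROFILE)}


def build_peaks(
    alignments_by_pool: Mapping[str, Sequence[AlignedRead]],
    window: int = DEFAULT_WINDOW,
) -> List[Peak]:
    """Single-linkage clustering of read starts within `window`, per
    (contig, strand).

    The insertion point is the leftmost read start for "+" peaks and the
    rightmost read end for "-" peaks (the junction the 3' flank extends
    away from). mapscore is the unique-alignment fraction of member reads.
    """
    tagged: List[Tuple[str, AlignedRead]] = []
    for pool_id, alns in alignments_by_pool.items():
        for aln in alns:
            tagged.append((pool_id, aln))
    if not tagged:
        return []
    tagged.sort(key=lambda t: (t[1].interval.contig, t[1].strand, t[1].interval.start))

    peaks: List[Peak] = []
    cluster: List[Tuple[str, AlignedRead]] = []

    def flush() -> None:
        if not cluster:
            return
        alns = [a for _, a in cluster]
        contig = alns[0].interval.contig
        strand = alns[0].strand
        starts = [a.interval.start for a in alns]
        ends = [a.interval.end for a in alns]
        per_pool_reads: Dict[str, int] = {}
        per_pool_starts: Dict[str, set] = {}
        for pool_id, a in cluster:
            per_pool_reads[pool_id] = per_pool_reads.get(pool_id, 0) + 1
            per_pool_starts.setdefault(pool_id, set()).add(a.interval.start)
        peaks.append(
            Peak(
                interval=GenomicInterval(contig, min(starts), max(ends), strand),
                insertion_point=min(starts) if strand != "-" else max(ends),
                per_pool_reads=per_pool_reads,
                per_pool_unique={p: len(s) for p, s in per_pool_starts.items()},
                unique_alignments=len(set(starts)),
                mean_mapq=float(np.mean([a.mapq for a in alns])),
                mean_matchpct=float(np.mean([a.matchpct for a in alns])),
                mapscore=sum(a.is_unique for a in alns) / len(alns),
                member_read_ids=tuple(a.read_id for a in alns),
            )
        )
        cluster.clear()

    prev_key: Optional[Tuple[str, str]] = None
    prev_start: Optional[int] = None
    for pool_id, aln in tagged:
        key = (aln.interval.contig, aln.strand)
        if cluster and (key != prev_key or aln.interval.start - prev_start > window):
            flush()
        cluster.append((pool_id, aln))
        prev_key, prev_start = key, aln.interval.start
    flush()
    peaks.sort(key=lambda p: (p.interval.contig, p.interval.start, p.strand))
    return peaks


# ---------------------------------------------------------------------------
# mappability
# ---------------------------------------------------------------------------

class MappabilityTrack:
    """Per-position k-mer uniqueness: position p scores 1 / (number of
    occurrences of the forward k-mer starting at p across the genome)."""

    def __init__(self, scores: Dict[str, np.ndarray], k: int):
        self.scores = scores
        self.k = k

    def mean_over(self, interval: GenomicInterval) -> float:
        track = self.scores[interval.contig]
        lo = max(0, interval.start)
        hi = min(len(track), interval.end)
        if hi <= lo:
            # interval too close to the contig end for any full k-mer;
            # fall back to the nearest scored position
            idx = min(max(interval.start, 0), len(track) - 1)
            return float(track[idx])
        return float(np.mean(track[lo:hi]))


def compute_mappability(genome: ReferenceGenome, k: int = 64) -> MappabilityTrack:
    """Occurrence-count k-mer uniqueness via a vectorised 64-bit hash."""
    rng = np.random.default_rng(1234567)
    mult = rng.integers(1, 2**63, size=k, dtype=np.uint64) | np.uint64(1)
    hashes: Dict[str, np.ndarray] = {}
    parts = []
    for name, seq in genome.contigs.items():
        if len(seq) < k:
            raise ValueError(f"k={k} exceeds length of contig {name!r}")
        enc = encode_sequence(seq).astype(np.uint64)
        n = len(seq) - k + 1
        h = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            h += enc[j : j + n] * mult[j]
        hashes[name] = h
        parts.append(h)
    allh = np.concatenate(parts)
    uniq, inverse, counts = np.unique(allh, return_inverse=True, return_counts=True)
    per_pos = counts[inverse].astype(np.float64)
    scores: Dict[str, np.ndarray] = {}
    offset = 0
    for name in genome.contigs:
        n = len(hashes[name])
        scores[name] = 1.0 / per_pos[offset : offset + n]
        offset += n
    return MappabilityTrack(scores, k)


def annotate_mappability(peak: Peak, track: MappabilityTrack) -> Peak:
    peak.mappability = track.mean_over(peak.interval)
    return peak


# ---------------------------------------------------------------------------
# classification, filtering, genic context
# ---------------------------------------------------------------------------

def classify_peak(
    peak: Peak,
    catalog: Sequence[L1CatalogEntry],
    proximity_window: int = DEFAULT_PROXIMITY,
) -> str:
    """KR if within `proximity_window` of a KR junction (KR wins ties with
    KNR), else KNR if near a KNR entry, else novel."""
    near = {KR: False, KNR: False}
    for entry in catalog:
        if entry.interval.contig != peak.interval.contig:
            continue
        if entry.interval.distance_to(peak.insertion_point) <= proximity_window:
            near[entry.catalog_class] = True
    label = KR if near[KR] else (KNR if near[KNR] else NOVEL)
    peak.catalog_class = label
    return label


def apply_filter(peaks: Sequence[Peak], profile: FilterProfile) -> List[Peak]:
    return [p for p in peaks if profile.accepts(p)]


def annotate_genic_context(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> str:
    """Intragenic iff the insertion point lies in an exon or intron, or
    within `promoter_window` bases of a TSS or a 3'UTR end."""
    ip = peak.insertion_point
    best: Optional[Tuple[int, str]] = None
    for gene in genes:
        if gene.span.contig != peak.interval.contig:
            continue
        dist = min(
            gene.span.distance_to(ip),
            abs(ip - gene.tss),
            abs(ip - gene.utr3_end),
        )
        if dist <= promoter_window and (best is None or (dist, gene.gene_id) < best):
            best = (dist, gene.gene_id)
    if best is None:
        peak.genic_context = INTERGENIC
        peak.gene_id = None
        return INTERGENIC
    peak.genic_context = INTRAGENIC
    peak.gene_id = best[1]
    return INTRAGENIC


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "contig", "start", "end", "strand", "insertion_point", "catalog_class",
    "genic_context", "gene_id", "total_reads", "unique_alignments",
    "maxcount", "maxuniq", "mean_mapq", "mapscore", "mappability",
    "mean_matchpct",
]


def peaks_to_dataframe(peaks: Sequence[Peak]):
    import pandas as pd

    rows = []
    for p in peaks:
        rows.append(
            {
                "contig": p.interval.contig,
                "start": p.interval.start,
                "end": p.interval.end,
                "strand": p.strand,
                "insertion_point": p.insertion_point,
                "catalog_class": p.catalog_class,
                "genic_context": p.genic_context,
                "gene_id": p.gene_id,
                "total_reads": p.total_reads,
                "unique_alignments": p.unique_alignments,
                "maxcount": p.maxcount,
                "maxuniq": p.maxuniq,
                "mean_mapq": p.mean_mapq,
                "mapscore": p.mapscore,
                "mappability": p.mappability,
                "mean_matchpct": p.mean_matchpct,
            }
        )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_peak_report(peaks: Sequence[Peak], path: str) -> None:
    peaks_to_dataframe(peaks).to_csv(path, sep="\t", index=False)


def read_peak_report(path: str, pool_id: str = "pool") -> List[Peak]:
    """Rebuild peaks from a report TSV. Per-pool maps collapse onto a
    single pool label, which is all the cross-pool comparison needs."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    peaks = []
    for row in df.itertuples():
        peak = Peak(
            interval=GenomicInterval(row.contig, int(row.start), int(row.end), row.strand),
            insertion_point=int(row.insertion_point),
            per_pool_reads={pool_id: int(row.total_reads)},
            per_pool_unique={pool_id: int(row.unique_alignments)},
            unique_alignments=int(row.unique_alignments),
            mean_mapq=float(row.mean_mapq),
            mean_matchpct=float(row.mean_matchpct),
            mapscore=float(row.mapscore),
            mappability=None if pd.isna(row.mappability) else float(row.mappability),
            catalog_class=None if pd.isna(row.catalog_class) else str(row.catalog_class),
            genic_context=None if pd.isna(row.genic_context) else str(row.genic_context),
            gene_id=None if pd.isna(row.gene_id) else str(row.gene_id),
        )
        peaks.append(peak)
    return peaks


def write_peaks_bed(peaks: Sequence[Peak], path: str) -> None:
    """BED6 + metric columns (total_reads, unique_alignments, mean_mapq,
    mapscore, mappability, mean_matchpct, catalog_class)."""
    with open(path, "w") as fh:
        for p in peaks:
            mapp = "" if p.mappability is None else f"{p.mappability:.4f}"
            fh.write(
                f"{p.interval.contig}\t{p.interval.start}\t{p.interval.end}\t"
                f"peak@{p.insertion_point}\t{min(1000, p.total_reads)}\t{p.strand}\t"
                f"{p.total_reads}\t{p.unique_alignments}\t{p.mean_mapq:.2f}\t"
                f"{p.mapscore:.4f}\t{mapp}\t{p.mean_matchpct:.4f}\t"
                f"{p.catalog_class or ''}\n"
            )
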