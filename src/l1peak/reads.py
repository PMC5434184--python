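"""Read preprocessing and alignment.

Implements the assay's fixed trim rule (10 nt off the 5' end, 26 nt off the
3' end of each 100 nt read), the strict per-base Q >= 30 filter, and a small
exact-seed/ungapped-extension aligner sufficient to exercise the downstream
peak caller. Real alignment files can be ingested from SAM instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, ReferenceGenome, encode_sequence, revcomp

logger = logging.getLogger(__name__)

DEFAULT_HEAD_TRIM = 10
DEFAULT_TAIL_TRIM = 26
DEFAULT_MIN_Q = 30


@dataclass(frozen=True)
class AmpliconRead:
    read_id: str
    sequence: str
    qualities: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    interval: GenomicInterval
    mapq: int
    matchpct: float
    n_best_hits: int
    pool_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError("mapq out of range")
        if not 0 <= self.matchpct <= 1:
            raise ValueError("matchpct out of range")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def is_unique(self) -> bool:
        return self.n_best_hits == 1


def trim_read(
    read: AmpliconRead,
    head_trim: int = DEFAULT_HEAD_TRIM,
    tail_trim: int = DEFAULT_TAIL_TRIM,
) -> AmpliconRead:
    """Drop fixed-length primer/tail ends; a 100-nt read yields the 64-nt
    genomic portion (positions 11-74, 1-based)."""
    if len(read) <= head_trim + tail_trim:
        raise ValueError(
            f"{read.read_id}: read of length {len(read)} too short to trim "
            f"{head_trim}+{tail_trim}"
        )
    stop = len(read) - tail_trim
    return AmpliconRead(
        read.read_id, read.sequence[head_trim:stop], read.qualities[head_trim:stop]
    )


def quality_filter(read: AmpliconRead, min_q: int = DEFAULT_MIN_Q) -> bool:
    """Pass iff every base has Phred quality >= min_q."""
    if len(read) == 0:
        raise ValueError("empty read")
    return all(q >= min_q for q in read.qualities)


# ---------------------------------------------------------------------------
# toy aligner
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over forward strands of all contigs.

    k-mers are 2-bit packed into integers (k <= 31), stored sorted for
    binary-search lookup.
    """

    def __init__(self, genome: ReferenceGenome, seed_length: int = 20):
        if seed_length > 31:
            raise ValueError("seed_length must be <= 31")
        if not genome.contigs:
            raise ValueError("empty genome")
        self.genome = genome
        self.k = seed_length
        self._contig_names: List[str] = []
        self._encoded: Dict[str, np.ndarray] = {}
        codes_parts = []
        pos_parts = []
        for cid, (name, seq) in enumerate(genome.contigs.items()):
            self._contig_names.append(name)
            enc = encode_sequence(seq).astype(np.int64)
            self._encoded[name] = enc
            n = len(seq) - seed_length + 1
            if n <= 0:
                continue
            codes = np.zeros(n, dtype=np.int64)
            for j in range(seed_length):
                codes = (codes << 2) | enc[j : j + n]
            codes_parts.append(codes)
            # pack contig id into high bits of the position
            pos_parts.append(np.arange(n, dtype=np.int64) | (cid << 40))
        all_codes = np.concatenate(codes_parts)
        all_pos = np.concatenate(pos_parts)
        order = np.argsort(all_codes, kind="stable")
        self._codes = all_codes[order]
        self._positions = all_pos[order]

    def _kmer_code(self, enc: np.ndarray) -> int:
        code = 0
        for v in enc[: self.k]:
            code = (code << 2) | int(v)
        return code

    def lookup(self, enc_kmer: np.ndarray) -> List[Tuple[str, int]]:
        code = self._kmer_code(enc_kmer)
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        out = []
        for packed in self._positions[lo:hi]:
            cid, pos = int(packed) >> 40, int(packed) & ((1 << 40) - 1)
            out.append((self._contig_names[cid], pos))
        return out


def _mapq_from_mismatches(mismatches: int, max_mismatches: int) -> int:
    # linear scale hitting 60 for a perfect hit and 15 at the mismatch
    # budget, so the downstream mapq >= 30 filter keeps <=2-mismatch hits
    return min(60, 15 * (max_mismatches - mismatches + 1))


def align_reads(
    reads: Iterable[AmpliconRead],
    genome: ReferenceGenome,
    seed_length: int = 20,
    max_mismatches: int = 3,
    index: Optional[GenomeIndex] = None,
    pool_id: str = "",
) -> List[AlignedRead]:
    """Ungapped best-hit alignment of trimmed reads against both strands.

    Exact seeds are tried at several offsets so isolated base errors do not
    kill sensitivity. Equal-best multi-mappers get mapq 0; unique hits get
    mapq = min(60, 6 * (mismatch budget - mismatches + 1)). Unmapped reads
    are dropped (counted in a log message).
    """
    if index is None:
        index = GenomeIndex(genome, seed_length)
    k = index.k
    aligned: List[AlignedRead] = []
    n_unmapped = 0
    for read in reads:
        L = len(read)
        if L < k:
            n_unmapped += 1
            continue
        candidates: Dict[Tuple[str, int, str], int] = {}
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            enc = encode_sequence(seq).astype(np.int64)
            offsets = list(range(0, L - k + 1, k)) or [0]
            seen_starts = set()
            for off in offsets:
                for contig, pos in index.lookup(enc[off : off + k]):
                    start = pos - off
                    key = (contig, start, strand)
                    if key in seen_starts:
                        continue
                    seen_starts.add(key)
                    ref_enc = index._encoded[contig]
                    if start < 0 or start + L > len(ref_enc):
                        continue
                    mismatches = int(
                        np.count_nonzero(ref_enc[start : start + L] != enc)
                    )
                    if mismatches <= max_mismatches:
                        candidates[key] = mismatches
        if not candidates:
            n_unmapped += 1
            continue
        best = min(candidates.values())
        best_keys = sorted(k_ for k_, v in candidates.items() if v == best)
        contig, start, strand = best_keys[0]
        n_best = len(best_keys)
        mapq = 0 if n_best > 1 else _mapq_from_mismatches(best, max_mismatches)
        aligned.append(
            AlignedRead(
                read_id=read.read_id,
                interval=GenomicInterval(contig, start, start + L, strand),
                mapq=mapq,
                matchpct=(L - best) / L,
                n_best_hits=n_best,
                pool_id=pool_id,
            )
        )
    if n_unmapped:
        logger.info("align_reads: %d reads unmapped and dropped", n_unmapped)
    return aligned


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[AmpliconRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str) -> List[AmpliconRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        reads.append(
            AmpliconRead(
                rec.id,
                str(rec.seq),
                tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_sam(
    alignments: Sequence[AlignedRead], genome_lengths: Dict[str, int], path: str
) -> None:
    """Minimal SAM with @SQ lines; NM carries the mismatch count, XH the
    number of equal-best hits, XP the pool id."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in genome_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_name = aln.interval.contig
            seg.reference_start = aln.interval.start
            seg.mapping_quality = aln.mapq
            length = len(aln.interval)
            seg.cigarstring = f"{length}M"
            seg.query_sequence = "N" * length
            nm = round((1 - aln.matchpct) * length)
            seg.set_tag("NM", nm, "i")
            seg.set_tag("XH", aln.n_best_hits, "i")
            if aln.pool_id:
                seg.set_tag("XP", aln.pool_id, "Z")
            out.write(seg)


def read_sam(path: str, default_pool: str = "") -> List[AlignedRead]:
    """Ingest SAM/BAM; matchpct comes from the NM tag over the aligned
    length (1.0 with a warning when NM is absent)."""
    import pysam

    alignments = []
    warned = False
    with pysam.AlignmentFile(path) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            length = seg.query_alignment_length or seg.infer_query_length() or 0
            if length == 0:
                continue
            if seg.has_tag("NM"):
                matchpct = max(0.0, 1 - seg.get_tag("NM") / length)
            else:
                if not warned:
                    logger.warning("NM tag absent; matchpct set to 1.0")
                    warned = True
                matchpct = 1.0
            n_best = seg.get_tag("XH") if seg.has_tag("XH") else (
                1 if seg.mapping_quality > 0 else 2
            )
            pool = seg.get_tag("XP") if seg.has_tag("XP") else default_pool
            alignments.append(
                AlignedRead(
                    read_id=seg.query_name,
                    interval=GenomicInterval(
                        seg.reference_name,
                        seg.reference_start,
                        seg.reference_start + length,
                        "-" if seg.is_reverse else "+",
                    ),
                    mapq=seg.mapping_quality,
                    matchpct=matchpct,
                    n_best_hits=int(n_best),
                    pool_id=str(pool),
                )
            )
    return alignments


def preprocess_reads(
    reads: Iterable[AmpliconRead],
    head_trim: int = DEFAULT_HEAD_TRIM,
    tail_trim: int = DEFAULT_TAIL_TRIM,
    min_q: int = DEFAULT_MIN_Q,
) -> List[AmpliconRead]:
    """Trim then quality-filter (paper order: filter precedes alignment)."""
    kept = []
    n_failed = 0
    for read in reads:
        trimmed = trim_read(read, head_trim, tail_trim)
        if quality_filter(trimmed, min_q):
            kept.append(trimmed)
        else:
            n_failed += 1
    if n_failed:
        logger.info("preprocess_reads: %d reads failed the quality filter", n_failed)
    return kept
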