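"""Cross-pool call merging, population exclusivity, and count statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .calling import INTERGENIC, INTRAGENIC, Peak
from .synth import COCAINE, CONTROL, PoolSpec

DEFAULT_MERGE_WINDOW = 100

COCAINE_ONLY = "cocaine-only"
CONTROL_ONLY = "control-only"
SHARED = "shared"


@dataclass
class PopulationCall:
    """One merged insertion call and the pools it was detected in."""

    contig: str
    strand: str
    insertion_point: int  # representative (median member point)
    pools: Set[str]
    peaks: List[Peak]
    exclusivity: str = ""
    genic_context: Optional[str] = None
    gene_id: Optional[str] = None


@dataclass
class PopulationCallSet:
    calls: List[PopulationCall]

    def by_exclusivity(self, exclusivity: str) -> List[PopulationCall]:
        return [c for c in self.calls if c.exclusivity == exclusivity]

    def exclusivity_counts(self) -> Dict[str, int]:
        counts = {COCAINE_ONLY: 0, CONTROL_ONLY: 0, SHARED: 0}
        for c in self.calls:
            counts[c.exclusivity] += 1
        return counts

    def genic_split(self) -> Dict[str, Dict[str, int]]:
        """exclusivity class -> {intragenic, intergenic} counts."""
        split = {
            cls: {INTRAGENIC: 0, INTERGENIC: 0}
            for cls in (COCAINE_ONLY, CONTROL_ONLY, SHARED)
        }
        for c in self.calls:
            if c.genic_context in (INTRAGENIC, INTERGENIC):
                split[c.exclusivity][c.genic_context] += 1
        return split

    def exclusive_contingency(self) -> "Contingency2x2":
        """2x2 of (cocaine-only, control-only) x (intragenic, intergenic)."""
        split = self.genic_split()
        return Contingency2x2(
            a=split[COCAINE_ONLY][INTRAGENIC],
            b=split[COCAINE_ONLY][INTERGENIC],
            c=split[CONTROL_ONLY][INTRAGENIC],
            d=split[CONTROL_ONLY][INTERGENIC],
            row_labels=(COCAINE_ONLY, CONTROL_ONLY),
            col_labels=(INTRAGENIC, INTERGENIC),
        )


@dataclass(frozen=True)
class Contingency2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: Tuple[str, str] = ("row1", "row2")
    col_labels: Tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def cells(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def compare_pools(
    peaks_by_pool: Mapping[str, Sequence[Peak]],
    pools: Sequence[PoolSpec],
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> PopulationCallSet:
    """Merge per-pool peaks whose insertion points lie within `merge_window`
    on the same strand into single calls, then label each call's
    population exclusivity from the union of its detecting pools."""
    populations = {p.pool_id: p.population for p in pools}
    for pool_id in peaks_by_pool:
        if pool_id not in populations:
            raise KeyError(f"pool {pool_id!r} absent from manifest")

    entries: List[Tuple[str, str, int, str, Peak]] = []
    for pool_id, pool_peaks in peaks_by_pool.items():
        for peak in pool_peaks:
            entries.append(
                (peak.interval.contig, peak.strand, peak.insertion_point, pool_id, peak)
            )
    entries.sort(key=lambda e: (e[0], e[1], e[2], e[3]))

    calls: List[PopulationCall] = []
    cluster: List[Tuple[str, str, int, str, Peak]] = []

    def flush() -> None:
        if not cluster:
            return
        contig, strand = cluster[0][0], cluster[0][1]
        points = [e[2] for e in cluster]
        pool_ids = {e[3] for e in cluster}
        peaks = [e[4] for e in cluster]
        genic = next((p.genic_context for p in peaks if p.genic_context), None)
        gene = next((p.gene_id for p in peaks if p.gene_id), None)
        call = PopulationCall(
            contig=contig,
            strand=strand,
            insertion_point=int(np.median(points)),
            pools=pool_ids,
            peaks=peaks,
            genic_context=genic,
            gene_id=gene,
        )
        pops = {populations[p] for p in pool_ids}
        if pops == {COCAINE}:
            call.exclusivity = COCAINE_ONLY
        elif pops == {CONTROL}:
            call.exclusivity = CONTROL_ONLY
        else:
            call.exclusivity = SHARED
        calls.append(call)
        cluster.clear()

    prev: Optional[Tuple[str, str, int]] = None
    for entry in entries:
        contig, strand, point = entry[0], entry[1], entry[2]
        if cluster and (
            (contig, strand) != prev[:2] or point - prev[2] > merge_window
        ):
            flush()
        cluster.append(entry)
        prev = (contig, strand, point)
    flush()
    calls.sort(key=lambda c: (c.contig, c.insertion_point, c.strand))
    return PopulationCallSet(calls)


def fisher_exact_2x2(table: Contingency2x2, tie_tol: float = 1e-9) -> float:
    """Exact two-sided Fisher p: sum of hypergeometric point probabilities
    not exceeding the observed table's probability (with a relative
    tolerance for floating-point ties)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("fisher_exact_2x2: a margin is zero")
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + tie_tol)].sum())
    return min(1.0, p)


def per_individual_rate(total_novel: int, n_individuals: int) -> float:
    """Mean novel calls per sequenced individual, to one decimal."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return round(total_novel / n_individuals, 1)


def exclusivity_report(callset: PopulationCallSet) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for call in callset.calls:
        rows.append(
            {
                "contig": call.contig,
                "insertion_point": call.insertion_point,
                "strand": call.strand,
                "pools": ",".join(sorted(call.pools)),
                "exclusivity": call.exclusivity,
                "genic_context": call.genic_context,
                "gene_id": call.gene_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "insertion_point", "strand", "pools",
            "exclusivity", "genic_context", "gene_id",
        ],
    )
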