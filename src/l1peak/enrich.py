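"""Gene-set over-representation statistics.

Two flavours: an upper-tail hypergeometric test (DAVID-style) and an
upper-tail binomial test (PANTHER-style), both reported with fold
enrichment over the background rate and Bonferroni-corrected p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TermGeneMap:
    """term id -> background gene set, plus the background universe size."""

    terms: Dict[str, Set[str]]
    background_size: int

    def __post_init__(self) -> None:
        largest = max((len(g) for g in self.terms.values()), default=0)
        if self.background_size < largest:
            raise ValueError("background_size smaller than largest term")

    @classmethod
    def from_gmt(cls, path: str, background_size: Optional[int] = None) -> "TermGeneMap":
        """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
        terms: Dict[str, Set[str]] = {}
        for line in open(path):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            terms[fields[0]] = set(fields[2:])
        if background_size is None:
            background_size = len(set().union(*terms.values())) if terms else 0
        return cls(terms, background_size)

    def to_gmt(self, path: str) -> None:
        with open(path, "w") as fh:
            for term, genes in sorted(self.terms.items()):
                fh.write("\t".join([term, ""] + sorted(genes)) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    observed: int
    expected: float
    percent_of_list: float
    fold_enrichment: float
    p_raw: float
    p_bonferroni: float


def bonferroni(p_values: Sequence[float], m: int) -> List[float]:
    """min(1, m * p) for each raw p-value; order-preserving."""
    if m < len(p_values):
        raise ValueError("m must be >= number of p-values")
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def _prepare_list(gene_list: Iterable[str], background: Set[str]) -> List[str]:
    genes = sorted(set(gene_list))
    if not genes:
        raise ValueError("empty gene list")
    known = [g for g in genes if g in background]
    dropped = len(genes) - len(known)
    if dropped:
        logger.warning("%d query genes absent from background; dropped", dropped)
    if not known:
        raise ValueError("no query genes found in background")
    return known


def _run_enrichment(
    gene_list: Iterable[str],
    term_map: TermGeneMap,
    tail,
    m_terms: Optional[int] = None,
) -> List[EnrichmentResult]:
    if not term_map.terms:
        raise ValueError("empty term map")
    background = set().union(*term_map.terms.values())
    genes = _prepare_list(gene_list, background)
    n = len(genes)
    N = term_map.background_size

    raw: List[tuple] = []
    for term_id, term_genes in sorted(term_map.terms.items()):
        K = len(term_genes)
        observed = len(term_genes.intersection(genes))
        expected = n * K / N
        fold = observed / expected if expected > 0 else 0.0
        p = tail(observed, N, K, n)
        raw.append((term_id, observed, expected, fold, p))

    if m_terms is None:
        m_terms = sum(1 for r in raw if r[1] >= 1) or 1
    results = []
    for term_id, observed, expected, fold, p in raw:
        results.append(
            EnrichmentResult(
                term_id=term_id,
                observed=observed,
                expected=expected,
                percent_of_list=100.0 * observed / n,
                fold_enrichment=fold,
                p_raw=p,
                p_bonferroni=min(1.0, m_terms * p),
            )
        )
    return results


def _hypergeom_tail(observed: int, N: int, K: int, n: int, ease: bool = False) -> float:
    if observed == 0:
        return 1.0
    x = observed - 1 if ease else observed
    if ease and x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def _binom_tail(observed: int, N: int, K: int, n: int) -> float:
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n, K / N))


def hypergeometric_enrichment(
    gene_list: Iterable[str],
    term_map: TermGeneMap,
    m_terms: Optional[int] = None,
    ease: bool = False,
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per term.

    p_raw = P(X >= observed) for X ~ Hypergeom(N=background, K=term size,
    n=list size); fold = (observed/n) / (K/N). `ease=True` switches to the
    EASE-style tail on observed-1.
    """
    return _run_enrichment(
        gene_list,
        term_map,
        lambda o, N, K, n: _hypergeom_tail(o, N, K, n, ease=ease),
        m_terms,
    )


def binomial_enrichment(
    gene_list: Iterable[str],
    term_map: TermGeneMap,
    m_terms: Optional[int] = None,
) -> List[EnrichmentResult]:
    """Upper-tail binomial over-representation per term.

    p_raw = P(X >= observed) for X ~ Binomial(n=list size, p=K/N);
    expected = n*K/N; fold = observed / expected.
    """
    return _run_enrichment(gene_list, term_map, _binom_tail, m_terms)


def binomial_result_from_counts(
    observed: int,
    expected: float,
    list_size: int,
    term_id: str = "term",
    m_terms: int = 1,
) -> EnrichmentResult:
    """Build a binomial-style result directly from an observed/expected
    pair (the shape published enrichment tables report)."""
    if expected <= 0 or list_size <= 0:
        raise ValueError("expected and list_size must be positive")
    p_term = expected / list_size
    p_raw = 1.0 if observed == 0 else float(
        stats.binom.sf(observed - 1, list_size, p_term)
    )
    return EnrichmentResult(
        term_id=term_id,
        observed=observed,
        expected=expected,
        percent_of_list=100.0 * observed / list_size,
        fold_enrichment=observed / expected,
        p_raw=p_raw,
        p_bonferroni=min(1.0, m_terms * p_raw),
    )


def build_gene_lists(
    genes_by_population: Mapping[str, Set[str]],
    include_overlap: bool = True,
) -> Dict[str, Set[str]]:
    """Per-population query lists, optionally excluding genes hit in both
    populations (a list-construction choice, not a statistical one)."""
    pops = list(genes_by_population)
    if include_overlap or len(pops) < 2:
        return {p: set(g) for p, g in genes_by_population.items()}
    overlap = set.intersection(*[set(g) for g in genes_by_population.values()])
    return {p: set(g) - overlap for p, g in genes_by_population.items()}


def results_to_dataframe(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "observed": r.observed,
                "expected": r.expected,
                "percent_of_list": r.percent_of_list,
                "fold_enrichment": r.fold_enrichment,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
            }
            for r in results
        ],
        columns=[
            "term_id", "observed", "expected", "percent_of_list",
            "fold_enrichment", "p_raw", "p_bonferroni",
        ],
    )
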