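"""End-to-end orchestration: simulate -> preprocess/align -> call ->
compare -> enrich, with a JSON-serialisable run report."""

from __future__ import annotations

import json
import logging
import os
from typing import Dict, List, Optional, Sequence, Set

from . import calling, enrich, popcompare, reads, synth
from .config import RunConfig
from .core import ReferenceGenome
from .synth import PoolSpec, TruthInsertion

logger = logging.getLogger(__name__)


def match_calls_to_truth(
    called_points: Sequence[int],
    truth_sites: Sequence[int],
    window: int = 100,
) -> Dict[str, float]:
    """Greedy one-to-one matching of call points to truth sites within
    `window`; returns recall/precision and raw counts."""
    truth_left = sorted(truth_sites)
    matched_truth: Set[int] = set()
    tp = 0
    for point in sorted(called_points):
        best = None
        for i, site in enumerate(truth_left):
            if i in matched_truth:
                continue
            d = abs(site - point)
            if d <= window and (best is None or d < best[0]):
                best = (d, i)
        if best is not None:
            matched_truth.add(best[1])
            tp += 1
    n_calls = len(called_points)
    n_truth = len(truth_sites)
    return {
        "true_positives": tp,
        "n_calls": n_calls,
        "n_truth": n_truth,
        "recall": tp / n_truth if n_truth else 0.0,
        "precision": tp / n_calls if n_calls else 0.0,
    }


def run_pipeline(config: RunConfig, outdir: Optional[str] = None) -> Dict:
    """Execute the full synthetic pipeline and return the run report.

    If `outdir` is given, every intermediate is written in its standard
    plain-text format (FASTA/FASTQ/SAM/BED/TSV/GMT/JSON).
    """
    seeds = config.stage_seeds()

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("simulate")
        genome = synth.generate_genome(
            config.genome_length, config.gc_fraction, seeds["genome"]
        )
        genes, catalog = synth.make_annotations(
            genome, config.n_genes, config.n_KR, config.n_KNR, seeds["annotations"]
        )
        pools = synth.default_pools()
        truth = synth.plant_insertions(
            genome,
            pools,
            config.n_novel,
            config.germline_fraction,
            (config.mosaic_fraction_low, config.mosaic_fraction_high),
            seeds["insertions"],
            exclude=[e.interval for e in catalog],
        )
        sim_config = config.simulation_config()
        reads_by_pool = synth.simulate_l1seq_reads(
            genome, truth, catalog, pools, sim_config
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[simulate] stage failed: {exc}") from exc

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        synth.write_fasta(genome, os.path.join(outdir, "genome.fa"))
        synth.write_gene_table(genes, os.path.join(outdir, "genes.tsv"))
        synth.write_catalog_bed(catalog, os.path.join(outdir, "catalog.bed"))
        synth.write_truth_table(truth, os.path.join(outdir, "truth.tsv"))
        synth.write_pool_manifest(pools, os.path.join(outdir, "pools.tsv"))
        for pool_id, pool_reads in reads_by_pool.items():
            reads.write_fastq(
                pool_reads, os.path.join(outdir, f"{pool_id}.fastq")
            )

    try:
        _stage("align")
        index = reads.GenomeIndex(genome)
        alignments_by_pool = {}
        for pool in pools:
            kept = reads.preprocess_reads(reads_by_pool[pool.pool_id])
            alignments_by_pool[pool.pool_id] = reads.align_reads(
                kept, genome, index=index, pool_id=pool.pool_id
            )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[align] stage failed: {exc}") from exc

    if outdir:
        lengths = {name: genome.length(name) for name in genome}
        for pool_id, alns in alignments_by_pool.items():
            reads.write_sam(alns, lengths, os.path.join(outdir, f"{pool_id}.sam"))

    try:
        _stage("call")
        peaks = calling.build_peaks(alignments_by_pool, window=config.peak_window)
        track = calling.compute_mappability(genome, k=64)
        for peak in peaks:
            calling.annotate_mappability(peak, track)
            calling.classify_peak(peak, catalog, config.proximity_window)
            calling.annotate_genic_context(peak, genes, config.promoter_window)
        profile = calling.PROFILES[config.profile]
        filtered = calling.apply_filter(peaks, profile)
        novel = [p for p in filtered if p.catalog_class == calling.NOVEL]
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[call] stage failed: {exc}") from exc

    if outdir:
        calling.write_peak_report(peaks, os.path.join(outdir, "peaks_all.tsv"))
        calling.write_peaks_bed(filtered, os.path.join(outdir, "peaks_filtered.bed"))

    recovery = match_calls_to_truth(
        [p.insertion_point for p in novel],
        [t.site for t in truth],
        config.truth_match_window,
    )

    try:
        _stage("compare")
        peaks_by_pool: Dict[str, List[calling.Peak]] = {p.pool_id: [] for p in pools}
        for peak in novel:
            for pool_id, count in peak.per_pool_reads.items():
                if count >= config.detect_min_reads:
                    peaks_by_pool[pool_id].append(peak)
        callset = popcompare.compare_pools(
            peaks_by_pool, pools, merge_window=config.merge_window
        )
        table = callset.exclusive_contingency()
        try:
            fisher_p = popcompare.fisher_exact_2x2(table)
        except ValueError:
            fisher_p = None
        n_individuals = sum(len(p.individual_ids) for p in pools)
        rate = popcompare.per_individual_rate(len(callset.calls), n_individuals)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[compare] stage failed: {exc}") from exc

    if outdir:
        popcompare.exclusivity_report(callset).to_csv(
            os.path.join(outdir, "exclusivity.tsv"), sep="\t", index=False
        )

    try:
        _stage("enrich")
        term_map = synth.make_term_map(
            [g.gene_id for g in genes], config.n_terms, seeds["terms"]
        )
        genes_by_population = {
            synth.COCAINE: {
                c.gene_id
                for c in callset.by_exclusivity(popcompare.COCAINE_ONLY)
                if c.gene_id
            },
            synth.CONTROL: {
                c.gene_id
                for c in callset.by_exclusivity(popcompare.CONTROL_ONLY)
                if c.gene_id
            },
        }
        gene_lists = enrich.build_gene_lists(
            genes_by_population, include_overlap=config.include_overlap
        )
        enrichment: Dict[str, List[Dict]] = {}
        for population, gene_list in gene_lists.items():
            if not gene_list:
                enrichment[population] = []
                continue
            results = enrich.binomial_enrichment(sorted(gene_list), term_map)
            results = sorted(results, key=lambda r: (r.p_raw, r.term_id))[:5]
            enrichment[population] = [
                {
                    "term_id": r.term_id,
                    "observed": r.observed,
                    "expected": round(r.expected, 4),
                    "fold_enrichment": round(r.fold_enrichment, 4),
                    "p_raw": r.p_raw,
                    "p_bonferroni": r.p_bonferroni,
                }
                for r in results
            ]
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[enrich] stage failed: {exc}") from exc

    if outdir:
        term_map.to_gmt(os.path.join(outdir, "terms.gmt"))

    split = callset.genic_split()
    report = {
        "seed": config.seed,
        "profile": config.profile,
        "n_peaks_total": len(peaks),
        "n_peaks_filtered": len(filtered),
        "catalog_class_counts": {
            cls: sum(1 for p in peaks if p.catalog_class == cls)
            for cls in (calling.KR, calling.KNR, calling.NOVEL)
        },
        "recovery": recovery,
        "exclusivity_counts": callset.exclusivity_counts(),
        "genic_split": split,
        "fisher_contingency": table.cells,
        "fisher_p": fisher_p,
        "novel_per_individual": rate,
        "enrichment": enrichment,
    }

    if outdir:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
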