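"""Droplet digital PCR models: Poisson concentration estimation, allele
ratio / zygosity interpretation, reference-normalised expression, and the
rank-sum group comparison."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .synth import DropletCounts

HET_BAND = (0.35, 0.65)
HOM_BAND = (0.85, 1.15)
ABSENT_THRESHOLD = 0.02

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
MOSAIC_CANDIDATE = "mosaic-candidate"
ABSENT = "absent"


@dataclass(frozen=True)
class ConcentrationEstimate:
    copies_per_droplet: float  # lambda
    copies_per_ul: float
    ci_low: float  # copies per ul
    ci_high: float

    def __post_init__(self) -> None:
        if self.copies_per_droplet < 0:
            raise ValueError("lambda must be non-negative")
        if not self.ci_low <= self.copies_per_ul <= self.ci_high:
            raise ValueError("interval must contain the point estimate")


@dataclass(frozen=True)
class AlleleRatioResult:
    ratio: float
    zygosity_call: str


@dataclass
class ExpressionRecord:
    sample_id: str
    group: str  # "cocaine" or "control"
    target_conc: float
    reference_concs: Dict[str, float]
    normalized_ratios: Dict[str, float] = field(default_factory=dict)


def poisson_concentration(
    counts: DropletCounts, channel: str = "target", confidence: float = 0.95
) -> ConcentrationEstimate:
    """lambda = -ln(1 - positive fraction); copies/ul = lambda / volume.

    The 95% interval is a Wilson score interval on the positive fraction
    propagated through the (monotone) log transform.
    """
    if channel == "target":
        positives = counts.positives_target
    elif channel == "reference":
        positives = counts.positives_reference
    else:
        raise ValueError(f"unknown channel {channel!r}")
    total = counts.total_droplets
    if positives >= total:
        raise ValueError("all droplets positive: concentration not estimable")

    phat = positives / total
    lam = -math.log(1.0 - phat)
    z = stats.norm.ppf(0.5 + confidence / 2)
    denom = 1 + z * z / total
    centre = (phat + z * z / (2 * total)) / denom
    half = (
        z
        * math.sqrt(phat * (1 - phat) / total + z * z / (4 * total * total))
        / denom
    )
    p_lo = max(0.0, centre - half)
    p_hi = min(1.0 - 1e-12, centre + half)
    vol = counts.droplet_volume
    return ConcentrationEstimate(
        copies_per_droplet=lam,
        copies_per_ul=lam / vol,
        ci_low=-math.log(1.0 - p_lo) / vol,
        ci_high=-math.log(1.0 - p_hi) / vol,
    )


def allele_ratio(
    target: ConcentrationEstimate,
    reference: ConcentrationEstimate,
    het_band: Tuple[float, float] = HET_BAND,
    hom_band: Tuple[float, float] = HOM_BAND,
    absent_threshold: float = ABSENT_THRESHOLD,
) -> AlleleRatioResult:
    """Target/reference copy ratio with a qualitative zygosity call.

    The reference is a two-copy diploid locus, so a germline heterozygous
    insertion sits near 0.5 and a homozygous one near 1.0; markedly lower
    non-zero ratios flag candidate mosaicism.
    """
    if reference.copies_per_ul <= 0:
        raise ValueError("reference concentration must be positive")
    ratio = target.copies_per_ul / reference.copies_per_ul
    if ratio <= absent_threshold:
        call = ABSENT
    elif het_band[0] <= ratio <= het_band[1]:
        call = HETEROZYGOUS
    elif hom_band[0] <= ratio <= hom_band[1]:
        call = HOMOZYGOUS
    else:
        call = MOSAIC_CANDIDATE
    return AlleleRatioResult(ratio=ratio, zygosity_call=call)


def geometric_mean(values: Sequence[float]) -> float:
    if any(v <= 0 for v in values):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(values))))


def normalize_expression(records: Sequence[ExpressionRecord]) -> List[ExpressionRecord]:
    """Add per-reference target ratios plus the ratio to the geometric mean
    of all references ("geomean")."""
    for rec in records:
        if not rec.reference_concs:
            raise ValueError(f"{rec.sample_id}: no reference concentrations")
        if any(v <= 0 for v in rec.reference_concs.values()):
            raise ValueError(f"{rec.sample_id}: non-positive reference concentration")
        ratios = {
            name: rec.target_conc / conc
            for name, conc in rec.reference_concs.items()
        }
        ratios["geomean"] = rec.target_conc / geometric_mean(
            list(rec.reference_concs.values())
        )
        rec.normalized_ratios = ratios
    return list(records)


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 10,
) -> float:
    """Two-sided rank-sum p-value.

    Exact by enumeration of all rank assignments (midranks for ties) when
    both groups have <= `exact_max_n` observations; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = list(map(float, group_a))
    b = list(map(float, group_b))
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.asarray(a + b)
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2

    if n1 <= exact_max_n and n2 <= exact_max_n:
        dev_obs = abs(w_obs - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            w = ranks[list(combo)].sum()
            if abs(w - mean_w) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return count / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w == 0:
        return 1.0
    dev = abs(w_obs - mean_w) - 0.5  # continuity correction
    z = max(0.0, dev) / math.sqrt(var_w)
    return float(min(1.0, 2 * stats.norm.sf(z)))
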