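"""Per-unigene nucleotide diversity and Tajima's D, per population.

Diversity at a site is the fraction of unordered called-allele pairs
that differ; per-gene values are reported both per transcript length
and per SNP site. Tajima's D follows the standard 1989 pipeline with
the sample size taken as the *average* number of alleles genotyped
across the gene's SNPs, so the harmonic-number constants are
generalized to real n via the digamma identity.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import digamma, polygamma

from .model import GeneDiversity, SiteAlleleCounts, SnpRecord
from .divergence import site_allele_counts

logger = logging.getLogger(__name__)

_EULER_GAMMA = float(np.euler_gamma)
_PI2_6 = math.pi**2 / 6.0


def site_pi(counts: Sequence[int]) -> float:
    """Fraction of unordered allele pairs that differ at one site:
    1 - sum_i C(n_i, 2) / C(n, 2) over allele-copy counts ``n_i``."""
    n = int(sum(counts))
    if n < 2:
        raise ValueError("site_pi needs >= 2 called allele copies")
    same = sum(c * (c - 1) for c in counts) / 2
    total = n * (n - 1) / 2
    return 1.0 - same / total


def gene_pi(
    site_pis: Sequence[float], gene_length: int, mode: str = "per-length"
) -> float:
    """Aggregate per-site diversity over a gene.

    ``per-length``: sum over SNP sites divided by transcript length
    (non-SNP positions contribute 0). ``per-snp``: mean over SNP sites.
    """
    if gene_length < 1:
        raise ValueError("gene_length must be >= 1")
    if mode == "per-length":
        return float(sum(site_pis)) / gene_length
    if mode == "per-snp":
        return float(np.mean(site_pis)) if site_pis else 0.0
    raise ValueError(f"unknown gene_pi mode {mode!r}")


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def _harmonic(n: float, power: int = 1) -> float:
    # sum_{i=1}^{n-1} 1/i^power, generalized to real n
    if power == 1:
        return float(digamma(n)) + _EULER_GAMMA
    return _PI2_6 - float(polygamma(1, n))


def tajima_constants(n_bar: float, integer_n: bool = False) -> TajimaConstants:
    """Constants of the Tajima test statistic for (possibly non-integer)
    sample size ``n_bar``. ``integer_n`` rounds n_bar first and uses the
    literal harmonic sums (for oracle comparison)."""
    if n_bar < 2:
        raise ValueError("tajima_constants needs n_bar >= 2")
    n = float(round(n_bar)) if integer_n else float(n_bar)
    if integer_n:
        ints = range(1, int(n))
        a1 = float(sum(1.0 / i for i in ints))
        a2 = float(sum(1.0 / i**2 for i in ints))
    else:
        a1 = _harmonic(n, 1)
        a2 = _harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, k_hat: float, n_bar: float, integer_n: bool = False) -> float:
    """Tajima's D from segregating sites S, mean pairwise differences
    k_hat (= sum of site_pi over the gene's SNPs) and sample size n_bar.

    Returns NaN when the variance term is non-positive.
    """
    if S < 1:
        raise ValueError("tajimas_d needs S >= 1")
    c = tajima_constants(n_bar, integer_n=integer_n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        logger.warning("tajimas_d: non-positive variance (S=%d, n_bar=%.2f)", S, n_bar)
        return math.nan
    return (k_hat - S / c.a1) / math.sqrt(var)


def gene_diversity(
    records: Sequence[SnpRecord],
    pop_masks: Mapping[str, np.ndarray],
    gene_lengths: Mapping[str, int],
    integer_n: bool = False,
) -> list[GeneDiversity]:
    """Per-unigene, per-population diversity and Tajima's D.

    Within each population a SNP contributes if it has >= 2 called allele
    copies there; S counts the contributing SNPs, k_hat sums their
    site diversity, and n_bar averages their called allele copies.
    """
    by_gene: dict[str, list[SnpRecord]] = defaultdict(list)
    for r in records:
        by_gene[r.unigene_id].append(r)

    out: list[GeneDiversity] = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        length = gene_lengths.get(gene)
        if length is None:
            logger.warning("gene_diversity: no length for %s, skipping", gene)
            continue
        for pop, mask in pop_masks.items():
            pis: list[float] = []
            ns: list[int] = []
            for r in recs:
                counts = site_allele_counts(r, {pop: mask})
                n = counts.n_total
                if n < 2:
                    continue
                pis.append(site_pi([counts.ref_counts[0], counts.alt_counts[0]]))
                ns.append(n)
            S = len(pis)
            if S == 0:
                continue
            k_hat = float(sum(pis))
            n_bar = float(np.mean(ns))
            d = tajimas_d(S, k_hat, n_bar, integer_n=integer_n) if n_bar >= 2 else math.nan
            out.append(
                GeneDiversity(
                    unigene_id=gene,
                    population=pop,
                    pi_per_length=gene_pi(pis, length, "per-length"),
                    pi_per_snp=gene_pi(pis, length, "per-snp"),
                    S=S,
                    n_bar=n_bar,
                    tajima_d=d,
                )
            )
    return out


def classify_outliers(
    records: Iterable[GeneDiversity], pct: float = 2.5, min_values: int = 40
) -> None:
    """Flag genes whose Tajima's D falls in the upper or lower ``pct``
    percentile of its population's distribution (inclusive boundaries,
    linear-interpolation percentiles). Sets ``outlier`` in place.

    With fewer than ``min_values`` finite D values in a population, no
    gene is flagged there and a warning is issued.
    """
    by_pop: dict[str, list[GeneDiversity]] = defaultdict(list)
    for r in records:
        by_pop[r.population].append(r)
    for pop, recs in by_pop.items():
        finite = [r for r in recs if math.isfinite(r.tajima_d)]
        if len(finite) < min_values:
            warnings.warn(
                f"population {pop}: only {len(finite)} finite Tajima's D values; "
                "outlier flags suppressed",
                stacklevel=2,
            )
            for r in recs:
                r.outlier = False
            continue
        values = np.array([r.tajima_d for r in finite])
        lo = float(np.percentile(values, pct))
        hi = float(np.percentile(values, 100.0 - pct))
        if lo == hi:  # degenerate distribution: no tails
            for r in recs:
                r.outlier = False
            continue
        for r in recs:
            r.outlier = math.isfinite(r.tajima_d) and (
                r.tajima_d <= lo or r.tajima_d >= hi
            )


def overall_outlier_genes(records: Iterable[GeneDiversity]) -> set[str]:
    """Genes flagged as an outlier in at least one population."""
    return {r.unigene_id for r in records if r.outlier}
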