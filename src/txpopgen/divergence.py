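"""Per-SNP two-population differentiation statistics.

Implements Nei's G_ST (uncorrected and Nei–Chesser bias-corrected
heterozygosities), Hedrick's standardized G'_ST, Jost's D, a
single-locus AMOVA phi_ST on 0/1 allele mismatches, Fisher's exact test
on the 2x2 allele-count table, Bonferroni flagging, and a
transcriptome-wide summary.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .model import (
    MISSING,
    DivergenceSummary,
    SiteAlleleCounts,
    SnpDivergence,
    SnpRecord,
)

logger = logging.getLogger(__name__)


def site_allele_counts(
    record: SnpRecord, pop_masks: Mapping[str, np.ndarray]
) -> SiteAlleleCounts:
    """Called allele-copy, heterozygote and individual counts per population."""
    labels, refs, alts, hets, inds = [], [], [], [], []
    for pop, mask in pop_masks.items():
        g = record.genotypes[mask]
        called = g != MISSING
        n_ind = int(called.sum())
        alt = int(g[called].sum())
        labels.append(pop)
        refs.append(2 * n_ind - alt)
        alts.append(alt)
        hets.append(int((g[called] == 1).sum()))
        inds.append(n_ind)
    return SiteAlleleCounts(
        labels=tuple(labels),
        ref_counts=tuple(refs),
        alt_counts=tuple(alts),
        het_counts=tuple(hets),
        ind_counts=tuple(inds),
    )


def heterozygosities(
    counts: SiteAlleleCounts, corrected: bool = True
) -> tuple[float, float]:
    """Within-population (Hs) and total (Ht) expected heterozygosity.

    Uncorrected: Hs = mean over populations of 1 - sum_a p_a^2;
    Ht = 1 - sum_a pbar_a^2 with pbar the unweighted across-population
    mean frequency.

    Corrected: Nei–Chesser small-sample estimators based on the harmonic
    mean of per-population sample sizes (diploid individuals) and the
    mean observed heterozygosity:

        Hs~ = n~/(n~-1) * (Hs_raw - Ho/(2 n~))
        Ht~ = Ht_raw + Hs~/(n~ k) - Ho/(2 n~ k)
    """
    n_per_pop = counts.n_per_pop
    if any(n == 0 for n in n_per_pop):
        raise ValueError("population with zero called allele copies")
    freqs = np.array(counts.alt_freqs)
    k = len(freqs)
    hs_raw = float(np.mean(1.0 - (freqs**2 + (1.0 - freqs) ** 2)))
    pbar = float(np.mean(freqs))
    ht_raw = 1.0 - (pbar**2 + (1.0 - pbar) ** 2)
    if not corrected:
        return hs_raw, ht_raw
    if counts.het_counts is None or counts.ind_counts is None:
        raise ValueError("corrected estimator needs het/individual counts")
    n_ind = np.array(counts.ind_counts, dtype=float)
    if (n_ind <= 1).any():
        raise ValueError("corrected estimator needs >= 2 individuals per population")
    n_harm = len(n_ind) / np.sum(1.0 / n_ind)
    ho = float(np.mean(np.array(counts.het_counts) / n_ind))
    hs = n_harm / (n_harm - 1.0) * (hs_raw - ho / (2.0 * n_harm))
    ht = ht_raw + hs / (n_harm * k) - ho / (2.0 * n_harm * k)
    return float(hs), float(ht)


def gst(hs: float, ht: float) -> float:
    """Nei's G_ST = (Ht - Hs)/Ht. Undefined (ValueError) for Ht <= 0."""
    if ht <= 0:
        raise ValueError("G_ST undefined for Ht <= 0 (monomorphic site)")
    return (ht - hs) / ht


def gst_hedrick(gst_value: float, hs: float, k: int = 2) -> float:
    """Hedrick's G'_ST = G_ST * (k-1+Hs) / ((k-1)(1-Hs))."""
    if hs >= 1:
        raise ValueError("G'_ST undefined for Hs >= 1")
    return gst_value * (k - 1 + hs) / ((k - 1) * (1.0 - hs))


def jost_d(hs: float, ht: float, k: int = 2) -> float:
    """Jost's D = (k/(k-1)) * (Ht - Hs)/(1 - Hs)."""
    if hs >= 1:
        raise ValueError("Jost's D undefined for Hs >= 1")
    return (k / (k - 1)) * (ht - hs) / (1.0 - hs)


def phi_st(counts: SiteAlleleCounts) -> float:
    """Single-locus AMOVA phi_ST on allele copies with 0/1 mismatch distance.

    SSD are assembled from closed-form pair counts (equivalent to
    enumerating all ordered pairs); variance components use
    n0 = (N - sum n_i^2 / N)/(k-1). Negative estimates are reported
    unclamped.
    """
    n_i = np.array(counts.n_per_pop, dtype=float)
    a_i = np.array(counts.alt_counts, dtype=float)
    r_i = n_i - a_i
    k = len(n_i)
    if (n_i < 2).any():
        raise ValueError("phi_ST needs >= 2 called allele copies per population")
    N = float(n_i.sum())
    A, R = float(a_i.sum()), float(r_i.sum())
    if A == 0 or R == 0:
        raise ValueError("phi_ST undefined: site monomorphic across all samples")
    # sum over unordered pairs of squared distance; d in {0,1} so d^2 = d
    ssd_total = (A * R) / N
    ssd_within = float(np.sum(a_i * r_i / n_i))
    ssd_among = ssd_total - ssd_within
    df_among = k - 1
    df_within = N - k
    ms_among = ssd_among / df_among
    sigma_within = ssd_within / df_within
    n0 = (N - float(np.sum(n_i**2)) / N) / (k - 1)
    sigma_among = (ms_among - sigma_within) / n0
    denom = sigma_among + sigma_within
    if denom == 0:
        raise ValueError("phi_ST undefined: zero total variance")
    return float(sigma_among / denom)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 allele-count table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= observed * (1 + 1e-7) (the
    conventional tie tolerance). An empty margin returns p = 1.
    """
    tbl = np.asarray(table, dtype=np.int64)
    if tbl.shape != (2, 2) or (tbl < 0).any():
        raise ValueError("fisher_exact expects a non-negative 2x2 table")
    if (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
        logger.debug("fisher_exact: empty margin, returning p = 1")
        return 1.0
    _, p = stats.fisher_exact(tbl, alternative="two-sided")
    return float(min(p, 1.0))


def bonferroni_flag(pvalues: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Significance flags under Bonferroni: p < alpha/m, strict."""
    m = len(pvalues)
    if m == 0:
        return []
    cutoff = alpha / m
    return [p < cutoff for p in pvalues]


def snp_divergence(
    records: Sequence[SnpRecord],
    pop_masks: Mapping[str, np.ndarray],
    corrected: bool = True,
    alpha: float = 0.05,
) -> list[SnpDivergence]:
    """Per-SNP differentiation for every testable (polymorphic, fully
    represented) site, with Bonferroni flags over the tested family.

    Sites monomorphic after masking, or with an uncalled population,
    carry no test and are skipped with a log message.
    """
    results: list[SnpDivergence] = []
    skipped = 0
    for r in records:
        counts = site_allele_counts(r, pop_masks)
        try:
            hs, ht = heterozygosities(counts, corrected=corrected)
            g = gst(hs, ht) if ht > 0 else math.nan
            if not math.isfinite(g):
                raise ValueError("monomorphic")
            gh = gst_hedrick(g, hs, k=len(counts.labels))
            d = jost_d(hs, ht, k=len(counts.labels))
            phi = phi_st(counts)
        except ValueError:
            skipped += 1
            continue
        table = [
            [counts.ref_counts[0], counts.alt_counts[0]],
            [counts.ref_counts[1], counts.alt_counts[1]],
        ]
        p = fisher_exact(table)
        results.append(
            SnpDivergence(
                unigene_id=r.unigene_id,
                pos=r.pos,
                hs=hs,
                ht=ht,
                gst=g,
                gst_hedrick=gh,
                jost_d=d,
                phi_st=phi,
                fisher_p=p,
            )
        )
    if skipped:
        logger.info("divergence: skipped %d untestable sites", skipped)
    flags = bonferroni_flag([r.fisher_p for r in results], alpha=alpha)
    for rec, flag in zip(results, flags):
        rec.significant = flag
    return results


def summarize(divergences: Iterable[SnpDivergence]) -> DivergenceSummary:
    """Transcriptome-wide summary: arithmetic-mean and ratio-of-means
    G_ST, significant SNP/gene counts, and the significant G_ST range."""
    divs = list(divergences)
    if not divs:
        return DivergenceSummary(
            mean_gst=math.nan,
            global_gst=math.nan,
            n_snps=0,
            n_significant_snps=0,
            n_significant_genes=0,
            gst_range_significant=None,
        )
    gsts = np.array([d.gst for d in divs])
    mean_hs = float(np.mean([d.hs for d in divs]))
    mean_ht = float(np.mean([d.ht for d in divs]))
    sig = [d for d in divs if d.significant]
    sig_genes = {d.unigene_id for d in sig}
    sig_range = None
    if sig:
        sig_gst = [d.gst for d in sig]
        sig_range = (min(sig_gst), max(sig_gst))
    return DivergenceSummary(
        mean_gst=float(np.mean(gsts)),
        global_gst=(mean_ht - mean_hs) / mean_ht,
        n_snps=len(divs),
        n_significant_snps=len(sig),
        n_significant_genes=len(sig_genes),
        gst_range_significant=sig_range,
    )
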