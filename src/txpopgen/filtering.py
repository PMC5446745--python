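"""Hard-filter cascade for biallelic transcriptome SNPs.

The cascade mirrors GATK-style hard filtering: genotype-level masking
first, then site-level rules applied in a fixed attribution order so
per-rule removal counts are deterministic:

1. ``fs``                  — FisherStrand > fs_max
2. ``qd``                  — quality-by-depth < qd_min
3. ``snp_cluster``         — > cluster_max_snps SNPs in any cluster_window
4. ``depth``               — site depth < depth_min
5. ``min_called_per_pop``  — called individuals < threshold in either population
6. ``maf``                 — pooled minor allele frequency < maf_min
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    MISSING,
    FILTER_RULES,
    FilterOutcome,
    FilterThresholds,
    SnpRecord,
)

logger = logging.getLogger(__name__)


def mask_low_quality_genotypes(
    records: Iterable[SnpRecord], gq_min: int
) -> tuple[list[SnpRecord], int]:
    """Mark calls with GQ < gq_min as missing.

    Returns the new records and the number of genotypes masked.
    Site-level annotations are untouched.
    """
    out: list[SnpRecord] = []
    n_masked = 0
    for r in records:
        low = (r.genotype_quals < gq_min) & (r.genotypes != MISSING)
        if low.any():
            gts = r.genotypes.copy()
            gts[low] = MISSING
            n_masked += int(low.sum())
            out.append(r.with_genotypes(gts))
        else:
            out.append(r)
    return out, n_masked


def flag_snp_clusters(
    records: Sequence[SnpRecord], window: int = 35, max_snps: int = 3
) -> set[tuple[str, int]]:
    """Positions removed by the SNP-cluster rule.

    A SNP is removed if it lies in *any* window of ``window`` bp (on its
    own unigene) that contains more than ``max_snps`` SNPs. Windows
    starting at each SNP position are sufficient: any offending window
    can be slid right until its left edge hits its leftmost SNP without
    losing members.
    """
    by_gene: dict[str, list[int]] = defaultdict(list)
    for r in records:
        by_gene[r.unigene_id].append(r.pos)
    removed: set[tuple[str, int]] = set()
    for gene, positions in by_gene.items():
        pos = np.array(sorted(set(positions)))
        right = np.searchsorted(pos, pos + window - 1, side="right")
        for i in range(len(pos)):
            if right[i] - i > max_snps:
                for p in pos[i : right[i]]:
                    removed.add((gene, int(p)))
    return removed


def _pooled_maf(record: SnpRecord) -> float | None:
    called = record.genotypes != MISSING
    n_copies = 2 * int(called.sum())
    if n_copies == 0:
        return None
    alt = int(record.genotypes[called].sum())
    p = alt / n_copies
    return min(p, 1.0 - p)


def apply_site_filters(
    records: Sequence[SnpRecord],
    thresholds: FilterThresholds,
    pop_masks: Mapping[str, np.ndarray],
    *,
    genotypes_masked: int = 0,
) -> FilterOutcome:
    """Apply the site-level cascade (genotype masking must already have
    happened). A record is attributed to the first rule it violates."""
    t = thresholds
    cluster_removed = flag_snp_clusters(records, t.cluster_window, t.cluster_max_snps)
    kept: list[SnpRecord] = []
    removed = {rule: 0 for rule in FILTER_RULES}
    for r in records:
        rule = _first_violated_rule(r, t, pop_masks, cluster_removed)
        if rule is None:
            kept.append(r)
        else:
            removed[rule] += 1
    logger.info(
        "site filters: kept %d of %d (%s)",
        len(kept),
        len(records),
        ", ".join(f"{k}={v}" for k, v in removed.items() if v),
    )
    return FilterOutcome(kept=kept, removed_by_rule=removed, genotypes_masked=genotypes_masked)


def _first_violated_rule(
    r: SnpRecord,
    t: FilterThresholds,
    pop_masks: Mapping[str, np.ndarray],
    cluster_removed: set[tuple[str, int]],
) -> str | None:
    # 1. strand bias: "greater than" is strict, FS == fs_max passes
    if r.fs is None:
        if t.strict_info:
            return "fs"
    elif r.fs > t.fs_max:
        return "fs"
    # 2. quality by depth
    if r.qd is None:
        if t.strict_info:
            return "qd"
    elif r.qd < t.qd_min:
        return "qd"
    # 3. SNP cluster
    if (r.unigene_id, r.pos) in cluster_removed:
        return "snp_cluster"
    # 4. depth ("at least depth_min" inclusive)
    if t.depth_per_sample:
        # alternative semantics: site fails if no called sample could have
        # depth_min reads; without per-sample AD we approximate with
        # mean depth per called sample
        n_called = max(int((r.genotypes != MISSING).sum()), 1)
        if r.depth is None:
            if t.strict_info:
                return "depth"
        elif r.depth / n_called < t.depth_min:
            return "depth"
    else:
        if r.depth is None:
            if t.strict_info:
                return "depth"
        elif r.depth < t.depth_min:
            return "depth"
    # 5. presence: "at least min_called_per_pop individuals" in each population
    called = r.genotypes != MISSING
    for mask in pop_masks.values():
        if int((called & mask).sum()) < t.min_called_per_pop:
            return "min_called_per_pop"
    # 6. pooled minor allele frequency
    maf = _pooled_maf(r)
    if maf is None or maf < t.maf_min:
        return "maf"
    return None


def run_filters(
    records: Sequence[SnpRecord],
    thresholds: FilterThresholds,
    pop_masks: Mapping[str, np.ndarray],
) -> FilterOutcome:
    """Convenience wrapper: genotype masking followed by the site cascade."""
    masked, n_masked = mask_low_quality_genotypes(records, thresholds.gq_min)
    return apply_site_filters(
        masked, thresholds, pop_masks, genotypes_masked=n_masked
    )
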