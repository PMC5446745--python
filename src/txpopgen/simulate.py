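"""Synthetic fixture generator for the whole pipeline.

Two-population Balding–Nichols genotypes on random unigene transcripts,
with optional hidden substructure ("standing_variation": the derived
population ND samples only one of two ancestral MN subclusters), planted
hard-filter violations, and text-format fixture output (VCF 4.2 + FASTA
+ TSV + JSON manifest). All randomness flows from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .model import (
    MISSING,
    SampleSheet,
    SimulationConfig,
    SnpRecord,
    TranscriptAnnotation,
)

POP_ANCESTRAL = "MN"  # admixed ancestral-type population (2 subclusters)
POP_DERIVED = "ND"  # derived population, drawn from subcluster 1 only

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def balding_nichols(
    p: np.ndarray, F: float, size: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Per-population allele frequencies around ancestral ``p`` with
    divergence F: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale, size=size)


@dataclass
class LocusFrequencies:
    """Per-locus ancestral and per-cluster alternate-allele frequencies."""

    ancestral: np.ndarray  # (n_loci,)
    clusters: np.ndarray  # (n_loci, 2): subclusters C1, C2


def simulate_frequencies(
    config: SimulationConfig,
    n_loci: int | None = None,
    rng: np.random.Generator | None = None,
) -> LocusFrequencies:
    """Draw ancestral frequencies Uniform(0.05, 0.95) and two independent
    Balding–Nichols cluster frequencies per locus.

    In scenario ``two_pop`` the two clusters ARE the two populations; in
    ``standing_variation`` they are the hidden subclusters of the
    ancestral population, and the derived population uses cluster 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_loci is None:
        n_loci = max(1, round(config.n_genes * config.snps_per_gene))
    p = rng.uniform(0.05, 0.95, size=n_loci)
    clusters = balding_nichols(p, config.F, (2, n_loci), rng).T
    return LocusFrequencies(ancestral=p, clusters=clusters)


def cluster_memberships(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-individual subcluster index (0 or 1) for each population.

    ``two_pop``: population i is cluster i wholesale. ``standing_variation``:
    ancestral individuals come from cluster 2 with probability mix_weight;
    derived individuals always from cluster 1.
    """
    n = config.n_per_pop
    if config.scenario == "two_pop":
        return {
            POP_ANCESTRAL: np.zeros(n, dtype=int),
            POP_DERIVED: np.ones(n, dtype=int),
        }
    return {
        POP_ANCESTRAL: (rng.random(n) < config.mix_weight).astype(int),
        POP_DERIVED: np.zeros(n, dtype=int),
    }


@dataclass
class SimulatedData:
    config: SimulationConfig
    records: list[SnpRecord]
    sequences: dict[str, str]
    annotations: dict[str, TranscriptAnnotation]
    sheet: SampleSheet
    truth: dict = field(default_factory=dict)


def simulate_transcripts(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, TranscriptAnnotation], list[tuple[str, int]]]:
    """Random transcripts with planted ORFs and unique SNP positions.

    Returns sequences, annotations and the flat (unigene, pos) SNP
    layout. The last ``n_cluster_genes`` genes get exactly four SNPs
    inside one 35-bp window (a planted cluster-rule violation).
    """
    sequences: dict[str, str] = {}
    annotations: dict[str, TranscriptAnnotation] = {}
    layout: list[tuple[str, int]] = []
    n_cluster = min(config.n_cluster_genes, config.n_genes)
    for g in range(config.n_genes):
        gene = f"g{g + 1:05d}"
        length = int(max(300, rng.normal(config.gene_length_mean, config.gene_length_mean / 4)))
        seq = rng.choice(_BASES, size=length)
        has_orf = rng.random() < config.orf_fraction
        orf_start = orf_end = None
        if has_orf:
            max_codons = (length - 60) // 3
            n_codons = int(rng.integers(20, max(21, max_codons)))
            orf_start = int(rng.integers(1, length - 3 * n_codons))
            orf_end = orf_start + 3 * n_codons - 1
            codons = ["ATG"]
            codons += [
                _NONSTOP_CODONS[i]
                for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
            ]
            codons.append(_STOPS[rng.integers(0, 3)])
            seq[orf_start - 1 : orf_end] = list("".join(codons))
        sequences[gene] = "".join(seq)
        annotations[gene] = TranscriptAnnotation(gene, length, orf_start, orf_end)
        if g >= config.n_genes - n_cluster:
            base = int(rng.integers(1, length - 34))
            offsets = rng.choice(np.arange(1, 35), size=3, replace=False)
            positions = sorted({base} | {base + int(o) for o in offsets})
            while len(positions) < 4:  # extremely unlikely retry path
                positions = sorted(
                    {base}
                    | {base + int(o) for o in rng.choice(np.arange(1, 35), 3, False)}
                )
        else:
            n_snps = int(rng.poisson(config.snps_per_gene))
            positions = sorted(
                int(p) + 1
                for p in rng.choice(length, size=min(n_snps, length), replace=False)
            )
        layout.extend((gene, p) for p in positions)
    return sequences, annotations, layout


def _quantize(x: np.ndarray) -> np.ndarray:
    # quarters are exactly representable in float32, so VCF round-trips
    # reproduce FS/QD bit-for-bit
    return np.round(x * 4.0) / 4.0


def simulate_genotypes(
    config: SimulationConfig,
    freqs: LocusFrequencies,
    layout: list[tuple[str, int]],
    sequences: dict[str, str],
    rng: np.random.Generator,
) -> tuple[list[SnpRecord], SampleSheet, dict]:
    """Hardy–Weinberg genotype draws plus artifact-field models and
    planted filter violations; returns records, sample sheet and the
    ground-truth bookkeeping."""
    n = config.n_per_pop
    samples = tuple(
        [f"{POP_ANCESTRAL}_{i + 1:03d}" for i in range(n)]
        + [f"{POP_DERIVED}_{i + 1:03d}" for i in range(n)]
    )
    sheet = SampleSheet(
        samples=samples,
        population_of={
            s: (POP_ANCESTRAL if s.startswith(POP_ANCESTRAL) else POP_DERIVED)
            for s in samples
        },
    )
    members = cluster_memberships(config, rng)
    cluster_idx = np.concatenate([members[POP_ANCESTRAL], members[POP_DERIVED]])

    n_loci = len(layout)
    assert freqs.clusters.shape[0] >= n_loci

    # disjoint planted artifact sites among non-cluster-gene SNPs
    cluster_genes = {
        f"g{g + 1:05d}"
        for g in range(config.n_genes - min(config.n_cluster_genes, config.n_genes),
                       config.n_genes)
    }
    eligible = np.array(
        [i for i, (g, _) in enumerate(layout) if g not in cluster_genes]
    )
    rng.shuffle(eligible)
    n_fs = round(config.fs_fail_rate * n_loci)
    n_qd = round(config.qd_fail_rate * n_loci)
    n_dp = round(config.depth_fail_rate * n_loci)
    fs_fail = set(eligible[:n_fs].tolist())
    qd_fail = set(eligible[n_fs : n_fs + n_qd].tolist())
    dp_fail = set(eligible[n_fs + n_qd : n_fs + n_qd + n_dp].tolist())

    disp = config.depth_dispersion
    p_nb = disp / (disp + config.depth_mean)

    records: list[SnpRecord] = []
    for i, (gene, pos) in enumerate(layout):
        f_by_cluster = freqs.clusters[i]
        f_ind = f_by_cluster[cluster_idx]
        gts = rng.binomial(2, f_ind).astype(np.int8)
        miss = rng.random(len(samples)) < config.missing_rate
        gts[miss] = MISSING
        low = rng.random(len(samples)) < config.low_gq_rate
        gq = np.where(
            low,
            rng.integers(0, 20, size=len(samples)),
            rng.integers(20, 100, size=len(samples)),
        ).astype(np.int16)
        fs = float(_quantize(rng.uniform(0.0, 20.0, size=1))[0])
        qd = float(_quantize(rng.uniform(5.0, 35.0, size=1))[0])
        depth = int(rng.negative_binomial(disp, p_nb)) + 25
        if i in fs_fail:
            fs = float(_quantize(rng.uniform(30.5, 60.0, size=1))[0])
        if i in qd_fail:
            qd = float(_quantize(rng.uniform(0.0, 1.75, size=1))[0])
        if i in dp_fail:
            depth = int(rng.integers(0, 25))
        ref = sequences[gene][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        records.append(
            SnpRecord(
                unigene_id=gene,
                pos=pos,
                ref=ref,
                alt=alt,
                genotypes=gts,
                genotype_quals=gq,
                samples=samples,
                fs=fs,
                qd=qd,
                depth=depth,
            )
        )

    truth = {
        "fs_fail": sorted([list(layout[i]) for i in fs_fail]),
        "qd_fail": sorted([list(layout[i]) for i in qd_fail]),
        "depth_fail": sorted([list(layout[i]) for i in dp_fail]),
        "cluster_genes": sorted(cluster_genes),
        "memberships": {
            s: f"C{int(c) + 1}" for s, c in zip(samples, cluster_idx)
        },
    }
    return records, sheet, truth


def simulate(config: SimulationConfig) -> SimulatedData:
    """Full generator: transcripts, frequencies, genotypes, ground truth."""
    rng = np.random.default_rng(config.seed)
    sequences, annotations, layout = simulate_transcripts(config, rng)
    freqs = simulate_frequencies(config, n_loci=len(layout), rng=rng)
    records, sheet, truth = simulate_genotypes(config, freqs, layout, sequences, rng)
    truth["n_snps"] = len(records)
    truth["true_freqs"] = {
        f"{g}:{p}": [float(freqs.clusters[i, 0]), float(freqs.clusters[i, 1])]
        for i, (g, p) in enumerate(layout)
    }
    return SimulatedData(
        config=config,
        records=records,
        sequences=sequences,
        annotations=annotations,
        sheet=sheet,
        truth=truth,
    )


def write_fixture(sim: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + FASTA + annotation/sample TSVs + JSON manifest.

    Identical seeds produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "snps.vcf",
        "fasta": outdir / "transcripts.fasta",
        "annotations": outdir / "annotations.tsv",
        "samples": outdir / "samples.tsv",
        "manifest": outdir / "manifest.json",
    }
    contig_lengths = {a.unigene_id: a.length for a in sim.annotations.values()}
    tio.write_vcf(
        sim.records, paths["vcf"], samples=sim.sheet.samples,
        contig_lengths=contig_lengths,
    )
    tio.write_fasta(sim.sequences, paths["fasta"])
    tio.write_annotations(sim.annotations.values(), paths["annotations"])
    tio.write_sample_sheet(sim.sheet, paths["samples"])
    manifest = {
        "config": {
            k: getattr(sim.config, k) for k in sim.config.__dataclass_fields__
        },
        "truth": sim.truth,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths
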