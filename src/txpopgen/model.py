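"""Shared data model for the transcriptome SNP pipeline.

Conventions
-----------
* Coordinates are 1-based and inclusive, as in VCF. Transcripts are
  single-exon, plus-strand unigene consensus sequences; there is no
  strand handling anywhere in the pipeline.
* Genotypes are stored as alt-allele dosage in ``{0, 1, 2}`` with ``-1``
  marking a missing ("no call") genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

MISSING = -1  # sentinel dosage for a missing genotype call

VALID_BASES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """Raised when inputs or thresholds are inconsistent with each other."""


class VcfParseError(ValueError):
    """Raised on a malformed VCF header or data line."""


class ValidationError(ValueError):
    """Raised when a record violates a data-model invariant."""


@dataclass
class SnpRecord:
    """One biallelic SNP on a transcript.

    ``genotypes`` and ``genotype_quals`` are aligned with ``samples``
    (a tuple shared by all records from one read).
    """

    unigene_id: str
    pos: int  # 1-based position on the transcript
    ref: str
    alt: str
    genotypes: np.ndarray  # int8 dosage, -1 missing
    genotype_quals: np.ndarray  # int16 phred GQ
    samples: tuple[str, ...]
    fs: float | None = None  # FisherStrand phred score
    qd: float | None = None  # quality by depth
    depth: int | None = None  # site-level DP

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.unigene_id}: pos must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValidationError(
                f"{self.unigene_id}:{self.pos}: alleles must be A/C/G/T, got {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.unigene_id}:{self.pos}: ref == alt")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.genotype_quals = np.asarray(self.genotype_quals, dtype=np.int16)
        ok = (self.genotypes == MISSING) | (
            (self.genotypes >= 0) & (self.genotypes <= 2)
        )
        if not ok.all():
            raise ValidationError(
                f"{self.unigene_id}:{self.pos}: dosage must be 0/1/2 or missing"
            )

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of samples with a non-missing genotype."""
        return self.genotypes != MISSING

    def with_genotypes(self, genotypes: np.ndarray) -> "SnpRecord":
        return replace(self, genotypes=np.asarray(genotypes, dtype=np.int8))


@dataclass(frozen=True)
class TranscriptAnnotation:
    """ORF annotation for one unigene; coordinates 1-based inclusive."""

    unigene_id: str
    length: int
    orf_start: int | None = None
    orf_end: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.unigene_id}: length must be >= 1")
        if (self.orf_start is None) != (self.orf_end is None):
            raise ValidationError(f"{self.unigene_id}: partial ORF coordinates")
        if self.orf_start is not None:
            if not (1 <= self.orf_start < self.orf_end <= self.length):
                raise ValidationError(
                    f"{self.unigene_id}: ORF {self.orf_start}..{self.orf_end} "
                    f"outside 1..{self.length}"
                )
            if (self.orf_end - self.orf_start + 1) % 3 != 0:
                raise ValidationError(
                    f"{self.unigene_id}: ORF length "
                    f"{self.orf_end - self.orf_start + 1} not divisible by 3"
                )

    @property
    def has_orf(self) -> bool:
        return self.orf_start is not None


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-population assignment; exactly two populations expected
    by the divergence operations."""

    samples: tuple[str, ...]
    population_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids in sample sheet")
        missing = [s for s in self.samples if s not in self.population_of]
        if missing:
            raise ValidationError(f"samples without population label: {missing}")

    @property
    def populations(self) -> tuple[str, ...]:
        """Unique population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population_of[s], None)
        return tuple(seen)

    def masks(self, samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Per-population boolean masks over ``samples`` (e.g. VCF order)."""
        unknown = [s for s in samples if s not in self.population_of]
        if unknown:
            raise ConfigurationError(
                f"samples absent from sample sheet: {unknown}"
            )
        return {
            pop: np.array([self.population_of[s] == pop for s in samples])
            for pop in self.populations
        }


@dataclass(frozen=True)
class SiteAlleleCounts:
    """Called allele-copy counts at one site, per population.

    ``ref_counts[i]`` / ``alt_counts[i]`` are the called ref/alt allele
    copies in population ``labels[i]``; ``het_counts`` and ``ind_counts``
    (heterozygous and called diploid individuals) feed the bias-corrected
    heterozygosity estimators.
    """

    labels: tuple[str, ...]
    ref_counts: tuple[int, ...]
    alt_counts: tuple[int, ...]
    het_counts: tuple[int, ...] | None = None
    ind_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.ref_counts + self.alt_counts):
            raise ValidationError("negative allele counts")

    @property
    def n_per_pop(self) -> tuple[int, ...]:
        return tuple(r + a for r, a in zip(self.ref_counts, self.alt_counts))

    @property
    def n_total(self) -> int:
        return sum(self.n_per_pop)

    @property
    def alt_freqs(self) -> tuple[float, ...]:
        return tuple(
            a / n if n else float("nan")
            for a, n in zip(self.alt_counts, self.n_per_pop)
        )


@dataclass
class SnpDivergence:
    """Per-SNP two-population differentiation record (report row)."""

    unigene_id: str
    pos: int
    hs: float
    ht: float
    gst: float
    gst_hedrick: float
    jost_d: float
    phi_st: float
    fisher_p: float
    significant: bool = False
    effect_class: str | None = None


@dataclass
class DivergenceSummary:
    mean_gst: float
    global_gst: float  # ratio of means: (mean ht - mean hs) / mean ht
    n_snps: int
    n_significant_snps: int
    n_significant_genes: int
    gst_range_significant: tuple[float, float] | None


@dataclass
class GeneDiversity:
    """Per-unigene, per-population diversity record (report row)."""

    unigene_id: str
    population: str
    pi_per_length: float
    pi_per_snp: float
    S: int
    n_bar: float
    tajima_d: float  # NaN when undefined
    outlier: bool = False


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cascade thresholds (defaults follow the analysed study)."""

    fs_max: float = 30.0
    qd_min: float = 2.0
    cluster_window: int = 35
    cluster_max_snps: int = 3
    depth_min: int = 25
    gq_min: int = 20
    min_called_per_pop: int = 16
    maf_min: float = 0.01
    strict_info: bool = True  # missing FS/QD/DP removes the record
    depth_per_sample: bool = False  # alternative per-sample depth rule

    def __post_init__(self) -> None:
        numeric = (
            self.fs_max, self.qd_min, self.depth_min,
            self.gq_min, self.min_called_per_pop, self.maf_min,
        )
        if any(v < 0 for v in numeric):
            raise ConfigurationError("filter thresholds must be non-negative")
        if self.cluster_window < 1:
            raise ConfigurationError("cluster_window must be >= 1")
        if self.cluster_max_snps < 1:
            raise ConfigurationError("cluster_max_snps must be >= 1")


# Rule labels in attribution order (a record counts against the first
# rule it violates).
FILTER_RULES = (
    "fs",
    "qd",
    "snp_cluster",
    "depth",
    "min_called_per_pop",
    "maf",
)


@dataclass
class FilterOutcome:
    kept: list[SnpRecord]
    removed_by_rule: dict[str, int]
    genotypes_masked: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by_rule.values())


@dataclass
class PcaResult:
    scores: np.ndarray  # individuals x components
    variance_explained: np.ndarray  # fraction of total variance
    loadings: np.ndarray  # components x SNPs
    samples: tuple[str, ...]
    populations: tuple[str, ...]


@dataclass
class GenotypeMatrix:
    """Complete-case dosage matrix: individuals x SNPs, no missing entries."""

    X: np.ndarray
    samples: tuple[str, ...]
    populations: tuple[str, ...]  # per-row population label
    snp_ids: tuple[tuple[str, int], ...]  # (unigene_id, pos) per column
    n_dropped_missing: int = 0
    n_dropped_constant: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-population / standing-variation generator."""

    n_genes: int = 500
    gene_length_mean: int = 1200
    snps_per_gene: float = 5.0
    n_per_pop: int = 48
    F: float = 0.05
    scenario: str = "two_pop"  # or "standing_variation"
    mix_weight: float = 0.25  # ancestral-pop fraction drawn from subcluster 2
    missing_rate: float = 0.02
    depth_mean: float = 200.0
    depth_dispersion: float = 5.0
    low_gq_rate: float = 0.03  # fraction of calls drawn from the GQ<20 tail
    orf_fraction: float = 0.8
    fs_fail_rate: float = 0.0
    qd_fail_rate: float = 0.0
    depth_fail_rate: float = 0.0
    n_cluster_genes: int = 0  # genes given a planted >3-SNPs/35bp cluster
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ConfigurationError(f"F must be in (0, 1), got {self.F}")
        if not (0.0 <= self.mix_weight <= 1.0):
            raise ConfigurationError("mix_weight must be in [0, 1]")
        for name in ("missing_rate", "low_gq_rate", "orf_fraction",
                     "fs_fail_rate", "qd_fail_rate", "depth_fail_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.scenario not in ("two_pop", "standing_variation"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
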