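"""End-to-end orchestration: read -> mask -> filter -> divergence ->
diversity -> effects -> structure -> reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import divergence as dv
from . import diversity as dy
from . import effects as fx
from . import filtering as fl
from . import io as tio
from . import structure as st
from .model import ConfigurationError, FilterThresholds

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    fasta: str
    annotations: str
    samples: str
    outdir: str
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    corrected: bool = True  # Nei–Chesser bias-corrected Hs/Ht
    alpha: float = 0.05
    outlier_pct: float = 2.5
    integer_n: bool = False  # round n_bar for Tajima constants
    pca_components: int = 10
    pca_scale: bool = False
    cluster_k: int = 3
    seed: int = 1

    def validate(self) -> None:
        for name in ("vcf", "fasta", "annotations", "samples"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = data.pop("thresholds", None)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if thresholds:
            cfg.thresholds = FilterThresholds(**thresholds)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def stage(name):
        t0 = time.monotonic()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.monotonic() - t0, 3),
                **counts,
            }
            logger.info("stage %s: %s", name, counts)

        return done

    # --- read ---------------------------------------------------------
    done = stage("read")
    sheet = tio.read_sample_sheet(config.samples)
    result = tio.read_vcf(config.vcf, sheet)
    sequences = tio.read_fasta(config.fasta)
    annotations = tio.read_annotations(config.annotations)
    pop_masks = sheet.masks(result.samples)
    done(n_snps=len(result.records), n_skipped=result.n_skipped)

    # --- filter -------------------------------------------------------
    done = stage("filter")
    outcome = fl.run_filters(result.records, config.thresholds, pop_masks)
    kept = outcome.kept
    done(
        n_kept=len(kept),
        genotypes_masked=outcome.genotypes_masked,
        **{f"removed_{k}": v for k, v in outcome.removed_by_rule.items()},
    )
    pd.DataFrame(
        [
            {"rule": rule, "removed": count}
            for rule, count in outcome.removed_by_rule.items()
        ]
    ).to_csv(outdir / "filter_summary.tsv", sep="\t", index=False)

    # --- divergence ---------------------------------------------------
    done = stage("divergence")
    divs = dv.snp_divergence(
        kept, pop_masks, corrected=config.corrected, alpha=config.alpha
    )
    summary = dv.summarize(divs)
    done(n_tested=len(divs), n_significant=summary.n_significant_snps)

    # --- effects ------------------------------------------------------
    done = stage("effects")
    classes = fx.classify_all(kept, annotations, sequences)
    class_of = {(r.unigene_id, r.pos): c for r, c in zip(kept, classes)}
    for d in divs:
        d.effect_class = class_of.get((d.unigene_id, d.pos))
    eff_summary = fx.class_summary(kept, classes, annotations)
    pd.DataFrame([eff_summary]).to_csv(
        outdir / "effect_summary.tsv", sep="\t", index=False, float_format="%.4f"
    )
    done(**{k: round(v, 4) for k, v in eff_summary.items()})

    tio.write_divergence_report(divs, outdir / "divergence.tsv")
    _write_divergence_summary(summary, outdir / "divergence_summary.tsv")

    # --- diversity ----------------------------------------------------
    done = stage("diversity")
    gene_lengths = {a.unigene_id: a.length for a in annotations.values()}
    gds = dy.gene_diversity(
        kept, pop_masks, gene_lengths, integer_n=config.integer_n
    )
    dy.classify_outliers(gds, pct=config.outlier_pct)
    tio.write_diversity_report(gds, outdir / "diversity.tsv")
    done(n_gene_pop=len(gds), n_outlier_genes=len(dy.overall_outlier_genes(gds)))

    # --- structure ----------------------------------------------------
    done = stage("structure")
    structure_counts: dict = {}
    try:
        matrix = st.complete_case_matrix(kept, sheet.population_of)
        pca_res = st.pca(
            matrix, n_components=config.pca_components, scale=config.pca_scale
        )
        clusters = st.cluster_summary(
            pca_res, k=config.cluster_k, seed=config.seed
        )
        _write_structure(pca_res, clusters, outdir)
        structure_counts = {
            "n_complete_snps": matrix.X.shape[1],
            "silhouette": round(clusters.silhouette, 4),
        }
    except ValueError as exc:
        logger.warning("structure stage skipped: %s", exc)
        structure_counts = {"skipped": str(exc)}
    done(**structure_counts)

    manifest["counts"] = {
        "snps_parsed": len(result.records),
        "snps_kept": len(kept),
        "removed_by_rule": outcome.removed_by_rule,
        "snps_tested": len(divs),
        "significant_snps": summary.n_significant_snps,
        "significant_genes": summary.n_significant_genes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_divergence_summary(summary, path: Path) -> None:
    lo, hi = summary.gst_range_significant or (float("nan"), float("nan"))
    pd.DataFrame(
        [
            {
                "mean_gst": summary.mean_gst,
                "global_gst": summary.global_gst,
                "n_snps": summary.n_snps,
                "n_significant_snps": summary.n_significant_snps,
                "n_significant_genes": summary.n_significant_genes,
                "gst_sig_min": lo,
                "gst_sig_max": hi,
            }
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_structure(pca_res, clusters, outdir: Path) -> None:
    n_comp = pca_res.scores.shape[1]
    scores = pd.DataFrame(
        pca_res.scores, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    scores.insert(0, "sample", list(pca_res.samples))
    scores.insert(1, "population", list(pca_res.populations))
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(n_comp)],
            "variance_explained": pca_res.variance_explained,
        }
    ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "sample": list(pca_res.samples),
            "population": list(pca_res.populations),
            "cluster": clusters.assignments,
        }
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
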