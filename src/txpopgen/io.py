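"""Readers and writers for the formats the pipeline touches.

VCF reading is backed by cyvcf2; everything written here is plain text
(VCF 4.2, FASTA, TSV) so fixtures and reports survive text-only
round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    ConfigurationError,
    GeneDiversity,
    SampleSheet,
    SnpDivergence,
    SnpRecord,
    TranscriptAnnotation,
    ValidationError,
    VcfParseError,
)

logger = logging.getLogger(__name__)

_SNP_ALLELES = {"A", "C", "G", "T"}


@dataclass
class VcfReadResult:
    """Parsed biallelic SNPs plus bookkeeping about skipped lines."""

    records: list[SnpRecord]
    samples: tuple[str, ...]
    n_skipped_indel: int = 0
    n_skipped_multiallelic: int = 0
    gq_defaulted: bool = False  # GQ absent from FORMAT, defaulted to 99

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_indel + self.n_skipped_multiallelic

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_vcf(path: str | Path, sample_sheet: SampleSheet) -> VcfReadResult:
    """Read biallelic SNPs from a VCF 4.x file.

    CHROM is interpreted as the unigene id and POS as the 1-based
    transcript coordinate. Indel and multiallelic lines are skipped and
    counted. Missing INFO FS/QD/DP become ``None`` on the record (the
    filter stage decides what that means). A FORMAT without GQ yields
    GQ 99 for every call, logged once.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises plain exceptions on bad headers
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = tuple(vcf.samples)
    sample_sheet.masks(samples)  # raises ConfigurationError on unknown samples

    records: list[SnpRecord] = []
    n_indel = 0
    n_multi = 0
    gq_defaulted = False
    for i, v in enumerate(vcf, start=1):
        try:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            ref, alt = v.REF.upper(), v.ALT[0].upper()
            if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
                n_indel += 1
                continue
            gts = np.full(len(samples), MISSING, dtype=np.int8)
            for j, (a1, a2, *_rest) in enumerate(v.genotypes):
                if a1 >= 0 and a2 >= 0:
                    gts[j] = a1 + a2
            gq = v.format("GQ")
            if gq is None:
                if not gq_defaulted:
                    logger.warning(
                        "%s: FORMAT has no GQ; defaulting all calls to GQ 99",
                        path,
                    )
                gq_defaulted = True
                quals = np.full(len(samples), 99, dtype=np.int16)
            else:
                quals = np.asarray(gq, dtype=float).reshape(len(samples))
                quals = np.where(np.isfinite(quals) & (quals >= 0), quals, 99)
                quals = quals.astype(np.int16)
            info = v.INFO
            fs = info.get("FS")
            qd = info.get("QD")
            dp = info.get("DP")
            records.append(
                SnpRecord(
                    unigene_id=v.CHROM,
                    pos=v.POS,
                    ref=ref,
                    alt=alt,
                    genotypes=gts,
                    genotype_quals=quals,
                    samples=samples,
                    fs=float(fs) if fs is not None else None,
                    qd=float(qd) if qd is not None else None,
                    depth=int(dp) if dp is not None else None,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise VcfParseError(f"{path}: bad record #{i} ({v.CHROM}:{v.POS}): {exc}") from exc

    if n_indel or n_multi:
        logger.info(
            "%s: skipped %d indel and %d multiallelic lines",
            path, n_indel, n_multi,
        )
    return VcfReadResult(
        records=records,
        samples=samples,
        n_skipped_indel=n_indel,
        n_skipped_multiallelic=n_multi,
        gq_defaulted=gq_defaulted,
    )


def write_vcf(
    records: Iterable[SnpRecord],
    path: str | Path,
    samples: Sequence[str] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as minimal, deterministic VCF 4.2 text (GT:GQ calls,
    INFO FS/QD/DP). Missing genotypes are written ``./.`` but keep their
    GQ so a round-trip is lossless."""
    records = list(records)
    if samples is None:
        if not records:
            raise ValueError("cannot infer samples from an empty record list")
        samples = records[0].samples
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand phred score">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total site depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    if contig_lengths:
        for cid, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={cid},length={ln}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for r in records:
        info_parts = []
        if r.fs is not None:
            info_parts.append(f"FS={_fmt_float(r.fs)}")
        if r.qd is not None:
            info_parts.append(f"QD={_fmt_float(r.qd)}")
        if r.depth is not None:
            info_parts.append(f"DP={r.depth}")
        info = ";".join(info_parts) or "."
        calls = "\t".join(
            f"{gt_strings[int(g)]}:{int(q)}"
            for g, q in zip(r.genotypes, r.genotype_quals)
        )
        lines.append(
            f"{r.unigene_id}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\tGT:GQ\t{calls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt_float(v: float) -> str:
    s = f"{v:.2f}"
    return s


def read_annotations(path: str | Path) -> dict[str, TranscriptAnnotation]:
    """Read the ORF annotation TSV (unigene_id, length, orf_start, orf_end;
    empty ORF columns mean no ORF). Invariant-violating rows raise."""
    df = pd.read_csv(path, sep="\t", dtype={"unigene_id": str})
    required = {"unigene_id", "length", "orf_start", "orf_end"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"annotation table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, TranscriptAnnotation] = {}
    bad: list[str] = []
    for row in df.itertuples(index=False):
        start = None if pd.isna(row.orf_start) else int(row.orf_start)
        end = None if pd.isna(row.orf_end) else int(row.orf_end)
        try:
            ann = TranscriptAnnotation(
                unigene_id=str(row.unigene_id),
                length=int(row.length),
                orf_start=start,
                orf_end=end,
            )
        except ValidationError:
            bad.append(str(row.unigene_id))
            continue
        out[ann.unigene_id] = ann
    if bad:
        raise ValidationError(f"invalid ORF annotations for: {bad}")
    return out


def write_annotations(
    annotations: Iterable[TranscriptAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "unigene_id": a.unigene_id,
            "length": a.length,
            "orf_start": a.orf_start if a.has_orf else "",
            "orf_end": a.orf_end if a.has_orf else "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["unigene_id", "length", "orf_start", "orf_end"]).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read the sample → population TSV (columns sample_id, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"}.issubset(df.columns):
        raise ValidationError(
            "sample sheet needs columns sample_id, population"
        )
    return SampleSheet(
        samples=tuple(df["sample_id"]),
        population_of=dict(zip(df["sample_id"], df["population"])),
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": list(sheet.samples),
            "population": [sheet.population_of[s] for s in sheet.samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


DIVERGENCE_COLUMNS = [
    "unigene",
    "position",
    "Hs",
    "Ht",
    "G_ST",
    "G_ST_hedrick",
    "Jost_D",
    "phi_ST",
    "fisher_p",
    "significant",
    "effect_class",
]


def write_divergence_report(records: Iterable[SnpDivergence], path: str | Path) -> None:
    rows = [
        {
            "unigene": r.unigene_id,
            "position": r.pos,
            "Hs": r.hs,
            "Ht": r.ht,
            "G_ST": r.gst,
            "G_ST_hedrick": r.gst_hedrick,
            "Jost_D": r.jost_d,
            "phi_ST": r.phi_st,
            "fisher_p": r.fisher_p,
            "significant": r.significant,
            "effect_class": r.effect_class if r.effect_class is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=DIVERGENCE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


DIVERSITY_COLUMNS = [
    "unigene",
    "population",
    "pi_per_length",
    "pi_per_snp",
    "S",
    "n_bar",
    "tajima_D",
    "outlier",
]


def write_diversity_report(records: Iterable[GeneDiversity], path: str | Path) -> None:
    rows = [
        {
            "unigene": r.unigene_id,
            "population": r.population,
            "pi_per_length": r.pi_per_length,
            "pi_per_snp": r.pi_per_snp,
            "S": r.S,
            "n_bar": r.n_bar,
            "tajima_D": r.tajima_d,
            "outlier": r.outlier,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=DIVERSITY_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
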