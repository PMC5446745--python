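"""SNP effect classification against transcript ORFs.

Each SNP gets exactly one class: ``synonymous``, ``nonsynonymous``,
``utr`` (inside an ORF-bearing transcript but outside the ORF) or
``noncoding`` (transcript without a predicted ORF). Stop gain/loss
counts as nonsynonymous; transcripts are unspliced, plus-strand
unigenes, so there is no splice or strand logic.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .model import SnpRecord, TranscriptAnnotation, ValidationError

EFFECT_CLASSES = ("synonymous", "nonsynonymous", "utr", "noncoding")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


def is_transition(ref: str, alt: str) -> bool:
    """True iff the substitution is purine<->purine or
    pyrimidine<->pyrimidine ({A,G} or {C,T})."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    return {ref, alt} in _TRANSITIONS


def classify_snp(
    snp: SnpRecord, annotation: TranscriptAnnotation, transcript_seq: str
) -> str:
    """Classify one SNP against its transcript's ORF.

    The reference allele must match the transcript base at the SNP
    position (1-based); a mismatch raises ValidationError.
    """
    seq = transcript_seq.upper()
    if snp.pos > annotation.length or snp.pos > len(seq):
        raise ValidationError(
            f"{snp.unigene_id}: position {snp.pos} beyond transcript length"
        )
    if seq[snp.pos - 1] != snp.ref:
        raise ValidationError(
            f"{snp.unigene_id}:{snp.pos}: ref allele {snp.ref} does not match "
            f"transcript base {seq[snp.pos - 1]}"
        )
    if not annotation.has_orf:
        return "noncoding"
    if not (annotation.orf_start <= snp.pos <= annotation.orf_end):
        return "utr"
    offset = snp.pos - annotation.orf_start
    codon_start = annotation.orf_start + 3 * (offset // 3) - 1  # 0-based
    codon = seq[codon_start : codon_start + 3]
    within = offset % 3
    alt_codon = codon[:within] + snp.alt + codon[within + 1 :]
    if _CODON_TABLE[codon] == _CODON_TABLE[alt_codon]:
        return "synonymous"
    return "nonsynonymous"


def utr_side(snp: SnpRecord, annotation: TranscriptAnnotation) -> str | None:
    """5' vs 3' side for a UTR SNP (metadata only, not a class)."""
    if not annotation.has_orf:
        return None
    if snp.pos < annotation.orf_start:
        return "5prime"
    if snp.pos > annotation.orf_end:
        return "3prime"
    return None


def classify_all(
    records: Sequence[SnpRecord],
    annotations: Mapping[str, TranscriptAnnotation],
    sequences: Mapping[str, str],
) -> list[str]:
    out = []
    for r in records:
        ann = annotations.get(r.unigene_id)
        if ann is None:
            raise ValidationError(f"no annotation for unigene {r.unigene_id}")
        out.append(classify_snp(r, ann, sequences[r.unigene_id]))
    return out


def class_summary(
    records: Sequence[SnpRecord],
    classes: Sequence[str],
    annotations: Mapping[str, TranscriptAnnotation],
) -> dict[str, float]:
    """Percentages over all kept SNPs: transitions, SNPs on ORF-bearing
    transcripts, SNPs inside ORFs, and the four effect classes."""
    n = len(records)
    if n == 0:
        return {}
    n_transition = sum(is_transition(r.ref, r.alt) for r in records)
    n_coding_tx = sum(
        1 for r in records if annotations[r.unigene_id].has_orf
    )
    n_in_orf = sum(1 for c in classes if c in ("synonymous", "nonsynonymous"))
    pct = lambda x: 100.0 * x / n
    return {
        "n_snps": n,
        "pct_transitions": pct(n_transition),
        "pct_in_coding_transcripts": pct(n_coding_tx),
        "pct_in_orf": pct(n_in_orf),
        "pct_synonymous": pct(sum(c == "synonymous" for c in classes)),
        "pct_nonsynonymous": pct(sum(c == "nonsynonymous" for c in classes)),
        "pct_utr": pct(sum(c == "utr" for c in classes)),
        "pct_noncoding": pct(sum(c == "noncoding" for c in classes)),
    }
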