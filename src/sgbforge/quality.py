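"""MAG quality tiers (MIMAG) and tRNA/rRNA completeness audits.

Tiers follow the MIMAG standard with strict inequalities: high quality
requires completeness > 90% and contamination < 5%; medium quality requires
completeness > 50% and contamination < 10%; boundary values resolve
downward. Completeness/contamination are consumed from a CheckM-style
report (or synthetic truth) — marker-gene estimation itself is out of scope.

The tRNA audit asks whether at least 18 of the 20 standard amino acids are
decoded by detected tRNAs (distinct isotypes, not gene copies); the rRNA
audit whether all three subunits (5S, 16S, 23S) are present. Both are
reported as audit flags, not catalog filters.
"""

from __future__ import annotations

from .records import RRNA_TYPES, AnnotationAudit

TIER_HIGH = "high"
TIER_MEDIUM = "medium"
TIER_FAIL = "fail"

HIGH_COMPLETENESS = 90.0
HIGH_CONTAMINATION = 5.0
MEDIUM_COMPLETENESS = 50.0
MEDIUM_CONTAMINATION = 10.0

TRNA_MIN_AMINO_ACIDS = 18


def classify_quality(completeness: float, contamination: float) -> str:
    """MIMAG tier for one genome. Strict thresholds; boundaries fail up."""
    if not 0.0 <= completeness <= 100.0:
        raise ValueError(f"completeness out of [0,100]: {completeness}")
    if contamination < 0.0:
        raise ValueError(f"negative contamination: {contamination}")
    if completeness > HIGH_COMPLETENESS and contamination < HIGH_CONTAMINATION:
        return TIER_HIGH
    if completeness > MEDIUM_COMPLETENESS and contamination < MEDIUM_CONTAMINATION:
        return TIER_MEDIUM
    return TIER_FAIL


def trna_pass(audit: AnnotationAudit) -> bool:
    """True iff tRNAs decode at least 18 of the 20 standard amino acids."""
    return len(audit.trna_amino_acids) >= TRNA_MIN_AMINO_ACIDS


def rrna_pass(audit: AnnotationAudit) -> bool:
    """True iff all of 5S, 16S and 23S rRNA genes are present."""
    return RRNA_TYPES <= audit.rrna_types


def n50(contig_lengths: list[int]) -> int:
    """Largest L such that contigs of length >= L cover half the assembly."""
    if not contig_lengths:
        raise ValueError("empty contig length list")
    if any(x <= 0 for x in contig_lengths):
        raise ValueError("contig lengths must be positive")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for x in lengths:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")
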