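"""Core record types shared across the pipeline stages.

A :class:`GenomeRecord` is the unit every stage consumes: an ordered set of
contigs plus provenance flags (reference genome vs MAG, oral vs not).
Quality metrics follow the CheckM report vocabulary; ANI results follow the
fragment-ANI (ANIb) convention of directional identity plus aligned coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_AMINO_ACIDS = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)

RRNA_TYPES = frozenset({"5S", "16S", "23S"})


@dataclass
class GenomeRecord:
    """A genome or MAG: named contigs plus source flags.

    Parameters
    ----------
    genome_id : str
        Unique label.
    contigs : dict[str, str]
        Ordered mapping contig id -> uppercase DNA sequence.
    is_reference : bool
        True for database reference genomes (these bypass the MAG quality
        gate and make their cluster a kSGB).
    oral : bool
        True for oral reference genomes (eHOMD-like) or oral MAGs; any such
        member marks the whole SGB as oral.
    species_id : str | None
        Planted ground-truth species label (synthetic data only).
    """

    genome_id: str
    contigs: dict[str, str]
    is_reference: bool = False
    oral: bool = False
    species_id: str | None = None

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def sequence(self) -> str:
        """Concatenation of all contigs (contig order preserved)."""
        return "".join(self.contigs.values())

    def contig_lengths(self) -> list[int]:
        return [len(s) for s in self.contigs.values()]


@dataclass
class QualityMetrics:
    """CheckM-style per-genome quality report row."""

    genome_id: str
    completeness: float
    contamination: float
    strain_heterogeneity: float = 0.0
    mean_depth: float = 0.0
    n50: int = 0
    genome_length: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness out of [0,100]: {self.completeness}")
        if self.contamination < 0.0:
            raise ValueError(f"negative contamination: {self.contamination}")
        if not 0.0 <= self.strain_heterogeneity <= 100.0:
            raise ValueError(
                f"strain heterogeneity out of [0,100]: {self.strain_heterogeneity}"
            )
        if self.mean_depth < 0.0:
            raise ValueError(f"negative mean depth: {self.mean_depth}")
        if self.genome_length and self.n50 > self.genome_length:
            raise ValueError("n50 exceeds genome length")


@dataclass
class AnnotationAudit:
    """tRNA/rRNA completeness audit for one genome.

    ``trna_amino_acids`` holds the distinct amino-acid isotypes decoded by
    detected tRNAs (three-letter codes); ``rrna_types`` the detected rRNA
    subunits out of {5S, 16S, 23S}.
    """

    genome_id: str
    trna_amino_acids: frozenset[str]
    rrna_types: frozenset[str]

    def __post_init__(self) -> None:
        self.trna_amino_acids = frozenset(self.trna_amino_acids)
        self.rrna_types = frozenset(self.rrna_types)
        bad = self.trna_amino_acids - STANDARD_AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard amino-acid labels: {sorted(bad)}")
        bad_rrna = self.rrna_types - RRNA_TYPES
        if bad_rrna:
            raise ValueError(f"unknown rRNA types: {sorted(bad_rrna)}")


@dataclass
class ANIResult:
    """Directional fragment-ANI result (query fragmented, subject searched)."""

    query_id: str
    subject_id: str
    ani: float  # percent, mean identity of accepted fragments
    coverage: float  # accepted aligned length / query length, in [0,1]
    n_fragments_aligned: int

    @property
    def defined(self) -> bool:
        return self.n_fragments_aligned >= 1


@dataclass
class SGBRecord:
    """One species-level genome bin in the final catalog."""

    sgb_id: str
    member_ids: frozenset[str]
    representative_id: str
    kind: str  # "kSGB" or "uSGB"
    oral: bool

    def __post_init__(self) -> None:
        self.member_ids = frozenset(self.member_ids)
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")
        if self.kind not in ("kSGB", "uSGB"):
            raise ValueError(f"kind must be kSGB or uSGB, got {self.kind!r}")


@dataclass
class SpeciesSpec:
    """Blueprint for one synthetic species and its strain structure."""

    species_id: str
    genome_length: int
    gc_content: float
    strain_subst_rates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0,1)")
        for r in self.strain_subst_rates:
            if not 0.0 <= r <= 0.3:
                raise ValueError(f"substitution rate out of [0,0.3]: {r}")

    @property
    def n_strains(self) -> int:
        return len(self.strain_subst_rates)


@dataclass
class SyntheticTruth:
    """Planted ground truth for a synthetic community."""

    genome_to_species: dict[str, str] = field(default_factory=dict)
    target_ani: dict[frozenset, float] = field(default_factory=dict)
    sample_weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for sample, weights in self.sample_weights.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"sample {sample} weights sum to {total}")
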