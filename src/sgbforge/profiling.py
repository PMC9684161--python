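"""SGB relative-abundance profiles from normalized per-contig depths.

Consumes a per-contig depth table (depths are assumed already normalized
upstream, jgi-style), collapses contigs to a length-weighted mean depth per
genome, assigns each SGB the depth of its representative genome, and
normalizes across SGBs to a relative-abundance profile per sample. Also
provides the profile summaries used downstream: richness above an
abundance threshold, the uSGB ("unknown") share of richness and abundance,
and Bray-Curtis dissimilarity between profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import SGBRecord

RICHNESS_THRESHOLD = 0.001  # "higher than 0.1%" per sample, strict


@dataclass
class AbundanceProfile:
    sample_id: str
    abundance: dict[str, float] = field(default_factory=dict)
    empty: bool = False  # all-zero sample flag

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("negative abundance")
        total = sum(self.abundance.values())
        if not self.empty and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")


def genome_depth(
    depths: pd.DataFrame,
    contig_to_genome: dict[str, str],
    sample_id: str,
) -> dict[str, float]:
    """Length-weighted mean contig depth per genome for one sample.

    Genomes mapped but absent from the sample get depth 0.
    """
    sub = depths[depths["sample_id"] == sample_id]
    unmapped = set(sub["contig_id"]) - set(contig_to_genome)
    if unmapped:
        raise KeyError(f"unmapped contigs: {sorted(unmapped)[:5]}")
    if (sub["depth"] < 0).any():
        raise ValueError("negative depth in table")
    out = {g: 0.0 for g in set(contig_to_genome.values())}
    if sub.empty:
        return out
    sub = sub.assign(genome=sub["contig_id"].map(contig_to_genome))
    grouped = sub.groupby("genome").apply(
        lambda g: (g["length"] * g["depth"]).sum() / g["length"].sum(),
        include_groups=False,
    )
    out.update(grouped.to_dict())
    return out


def relative_abundance(
    genome_depths: dict[str, float],
    genome_to_sgb: dict[str, str],
    sample_id: str = "sample",
) -> AbundanceProfile:
    """Normalize representative-genome depths into an SGB profile.

    Each SGB's depth is the depth of its representative genome; an
    all-zero sample yields a flagged empty profile.
    """
    if not genome_depths:
        raise ValueError("no genomes")
    if any(v < 0 for v in genome_depths.values()):
        raise ValueError("negative depth")
    sgb_depth: dict[str, float] = {}
    for genome, sgb in genome_to_sgb.items():
        sgb_depth[sgb] = genome_depths.get(genome, 0.0)
    total = sum(sgb_depth.values())
    if total == 0.0:
        return AbundanceProfile(
            sample_id=sample_id,
            abundance={s: 0.0 for s in sgb_depth},
            empty=True,
        )
    return AbundanceProfile(
        sample_id=sample_id,
        abundance={s: v / total for s, v in sgb_depth.items()},
    )


def richness(profile: AbundanceProfile, threshold: float = RICHNESS_THRESHOLD) -> int:
    """Number of SGBs strictly above the abundance threshold."""
    return sum(1 for v in profile.abundance.values() if v > threshold)


def unknown_fraction(
    profile: AbundanceProfile,
    catalog: list[SGBRecord],
    threshold: float = RICHNESS_THRESHOLD,
) -> tuple[float, float]:
    """(uSGB share of richness, summed uSGB abundance) for one sample.

    Richness share counts SGBs above the threshold; abundance share sums
    over all uSGBs present in the profile.
    """
    kind = {r.sgb_id: r.kind for r in catalog}
    unknown_ids = set(profile.abundance) - set(kind)
    if unknown_ids:
        raise KeyError(f"sgb ids missing from catalog: {sorted(unknown_ids)[:5]}")
    rich = [s for s, v in profile.abundance.items() if v > threshold]
    u_rich = sum(1 for s in rich if kind[s] == "uSGB")
    richness_share = u_rich / len(rich) if rich else 0.0
    abundance_share = sum(v for s, v in profile.abundance.items() if kind[s] == "uSGB")
    return richness_share, abundance_share


def bray_curtis(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """Bray-Curtis dissimilarity, Σ|p−q| / Σ(p+q); missing keys are 0."""
    keys = set(p.abundance) | set(q.abundance)
    num = sum(abs(p.abundance.get(k, 0.0) - q.abundance.get(k, 0.0)) for k in keys)
    den = sum(p.abundance.get(k, 0.0) + q.abundance.get(k, 0.0) for k in keys)
    if den == 0.0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return num / den


def profile_matrix(profiles: list[AbundanceProfile]) -> pd.DataFrame:
    """Samples × SGBs matrix (missing SGBs filled with 0)."""
    data = {p.sample_id: p.abundance for p in profiles}
    return pd.DataFrame(data).T.fillna(0.0).sort_index(axis=0).sort_index(axis=1)
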