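"""End-to-end orchestration: quality gate -> sketch -> precluster -> ANI ->
catalog -> profile, deterministic under a fixed config/seed.

Only MAGs passing the medium-quality MIMAG tier enter clustering; reference
genomes bypass the gate (the gate filters assembled bins, not database
genomes). Stage outputs are written as plain files into a run directory so
any stage can be re-entered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .ani import anib, symmetrize
from .clustering import (
    DistanceMatrix,
    assemble_catalog,
    label_kind,
    merge_by_ani,
    precluster,
    refinement_pairs,
    select_representative,
)
from .config import PipelineConfig
from .profiling import AbundanceProfile, genome_depth, profile_matrix, relative_abundance
from .quality import TIER_FAIL, classify_quality, n50
from .records import GenomeRecord, QualityMetrics, SGBRecord

logger = logging.getLogger("sgbforge")


@dataclass
class PipelineResult:
    tiers: dict[str, str]
    retained_ids: list[str]
    preclusters: list[set[str]]
    ani_pairs: list[dict]
    catalog: list[SGBRecord]
    profiles: list[AbundanceProfile] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def _full_metrics(
    genomes: dict[str, GenomeRecord], quality: dict[str, QualityMetrics]
) -> dict[str, QualityMetrics]:
    """Attach assembly statistics (length, N50) to the quality report.

    Reference genomes without a CheckM-style row are treated as complete
    and uncontaminated.
    """
    out: dict[str, QualityMetrics] = {}
    for gid, g in genomes.items():
        q = quality.get(gid)
        out[gid] = QualityMetrics(
            genome_id=gid,
            completeness=q.completeness if q else 100.0,
            contamination=q.contamination if q else 0.0,
            strain_heterogeneity=q.strain_heterogeneity if q else 0.0,
            mean_depth=q.mean_depth if q else 0.0,
            n50=n50(g.contig_lengths()),
            genome_length=g.length,
        )
    return out


def cluster_genomes(
    genomes: list[GenomeRecord],
    quality: dict[str, QualityMetrics],
    config: PipelineConfig,
    sketches=None,
) -> PipelineResult:
    """Run quality gate, two-step clustering and catalog assembly in memory."""
    from .sketch import pairwise_mash, sketch_genome

    if not genomes:
        raise ValueError("no input genomes")
    by_id = {g.genome_id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise ValueError("duplicate genome ids")
    metrics = _full_metrics(by_id, quality)

    # stage 1: MIMAG gate (MAGs only; references bypass)
    tiers: dict[str, str] = {}
    retained: list[GenomeRecord] = []
    for g in genomes:
        if g.is_reference:
            tiers[g.genome_id] = "reference"
            retained.append(g)
            continue
        tier = classify_quality(
            metrics[g.genome_id].completeness, metrics[g.genome_id].contamination
        )
        tiers[g.genome_id] = tier
        if tier != TIER_FAIL:
            retained.append(g)
    logger.info("quality gate: %d/%d genomes retained", len(retained), len(genomes))

    # stage 2: sketches and Mash distance matrix
    if sketches is None:
        sketches = [
            sketch_genome(g, k=config.k, s=config.sketch_size) for g in retained
        ]
    ids, dmat = pairwise_mash(sketches)
    dm = DistanceMatrix(ids=ids, d=dmat)

    # stage 3: average-linkage preclusters
    pre = precluster(dm, cutoff=config.precluster_cutoff)
    logger.info("preclustering: %d clusters from %d genomes", len(pre), len(ids))

    # stage 4: kinds, representatives, candidate pairs, fragment ANI
    reference_ids = {g.genome_id for g in genomes if g.is_reference}
    reps: dict[int, str] = {}
    for ci, cluster in enumerate(pre):
        kind = label_kind(cluster, reference_ids)
        reps[ci] = select_representative(cluster, kind, metrics)
    pairs = refinement_pairs(sorted(reps.values()), dm, config.candidate_cutoff)
    logger.info("refinement: %d candidate representative pairs", len(pairs))

    pair_ani: dict[frozenset, tuple[float, float]] = {}
    ani_rows: list[dict] = []
    for a, b in pairs:
        fwd = anib(by_id[a], by_id[b], fragment_length=config.fragment_length)
        rev = anib(by_id[b], by_id[a], fragment_length=config.fragment_length)
        for r in (fwd, rev):
            ani_rows.append(
                {
                    "query_id": r.query_id,
                    "subject_id": r.subject_id,
                    "ani": r.ani,
                    "coverage": r.coverage,
                    "n_fragments_aligned": r.n_fragments_aligned,
                }
            )
        sym = symmetrize(fwd, rev)
        if sym is not None:
            pair_ani[frozenset((a, b))] = sym

    # stage 5: complete-linkage ANI merge and catalog
    final = merge_by_ani(
        pre, reps, pair_ani, ani_cutoff=config.ani_cutoff,
        coverage_cutoff=config.coverage_cutoff,
    )
    oral_ref = {g.genome_id for g in genomes if g.is_reference and g.oral}
    oral_mag = {g.genome_id for g in genomes if not g.is_reference and g.oral}
    catalog = assemble_catalog(final, reference_ids, oral_ref, oral_mag, metrics)
    logger.info("catalog: %d SGBs (%d preclusters merged to %d clusters)",
                len(catalog), len(pre), len(final))

    return PipelineResult(
        tiers=tiers,
        retained_ids=[g.genome_id for g in retained],
        preclusters=pre,
        ani_pairs=ani_rows,
        catalog=catalog,
        stage_counts={
            "input_genomes": len(genomes),
            "retained_genomes": len(retained),
            "preclusters": len(pre),
            "candidate_pairs": len(pairs),
            "sgbs": len(catalog),
        },
    )


def profile_samples(
    catalog: list[SGBRecord],
    genomes: dict[str, GenomeRecord],
    depth_table: pd.DataFrame,
) -> list[AbundanceProfile]:
    """Depth table -> per-sample SGB relative-abundance profiles.

    Profiles are computed against the representative genomes only (depths
    of non-representative contigs are ignored, mirroring profiling against
    a representative-genome index).
    """
    contig_to_genome: dict[str, str] = {}
    genome_to_sgb: dict[str, str] = {}
    for rec in catalog:
        rep = genomes[rec.representative_id]
        genome_to_sgb[rep.genome_id] = rec.sgb_id
        for cid in rep.contigs:
            contig_to_genome[cid] = rep.genome_id
    sub = depth_table[depth_table["contig_id"].isin(contig_to_genome)]
    profiles = []
    for sample_id in sorted(sub["sample_id"].unique()):
        gd = genome_depth(sub, contig_to_genome, sample_id)
        profiles.append(relative_abundance(gd, genome_to_sgb, sample_id=sample_id))
    return profiles


def run_pipeline(
    config: PipelineConfig,
    genomes: list[GenomeRecord],
    quality: dict[str, QualityMetrics],
    depth_table: pd.DataFrame | None,
    run_dir: Path,
) -> PipelineResult:
    """File-producing wrapper: stage outputs written in order into run_dir."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    result = cluster_genomes(genomes, quality, config)

    pd.DataFrame(
        [{"genome_id": g, "tier": t} for g, t in sorted(result.tiers.items())]
    ).to_csv(run_dir / "quality_tiers.tsv", sep="\t", index=False)
    io.write_ani_pairs_tsv(result.ani_pairs, run_dir / "ani_pairs.tsv")
    io.write_catalog_tsv(result.catalog, run_dir / "catalog.tsv")

    if depth_table is not None and not depth_table.empty:
        by_id = {g.genome_id: g for g in genomes}
        result.profiles = profile_samples(result.catalog, by_id, depth_table)
        profile_matrix(result.profiles).to_csv(run_dir / "profiles.tsv", sep="\t")

    with open(run_dir / "run.log", "w") as fh:
        for stage, count in result.stage_counts.items():
            fh.write(f"{stage}\t{count}\n")
    return result
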