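"""Two-step SGB clustering.

Step 1 pre-clusters all genomes by average-linkage hierarchical clustering
on the all-versus-all Mash distance matrix, cut at 0.05. Because MinHash
distances are inflated for incomplete genomes, step 1 can split a species
across pre-clusters; step 2 therefore recomputes a precise fragment-ANI
between pre-cluster representatives (for candidate pairs below a Mash
cutoff), drops pairs whose aligned coverage is not above 0.3, and merges
pre-clusters whose representatives fall in the same complete-linkage ANI
cluster at ANI > 95%.

Pre-clusters containing at least one reference genome are kSGBs, the rest
uSGBs. The kSGB representative is the member with the largest genome; the
uSGB representative minimizes the sum of five competition ranks
(completeness desc, contamination asc, depth desc, strain heterogeneity
asc, N50 desc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .records import QualityMetrics, SGBRecord

DEFAULT_PRECLUSTER_CUTOFF = 0.05
DEFAULT_CANDIDATE_CUTOFF = 0.10
DEFAULT_ANI_CUTOFF = 95.0
DEFAULT_COVERAGE_CUTOFF = 0.3


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise ValueError("nonzero diagonal")
        if self.d.min() < 0.0 or self.d.max() > 1.0:
            raise ValueError("distances out of [0,1]")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def _cut(ids: list[str], dist: np.ndarray, method: str, cutoff: float) -> list[set[str]]:
    """Agglomerate and cut strictly above ``cutoff`` (boundary merges)."""
    if len(ids) == 1:
        return [{ids[0]}]
    z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=cutoff, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for gid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), set()).add(gid)
    return [clusters[k] for k in sorted(clusters)]


def precluster(
    d: DistanceMatrix, cutoff: float = DEFAULT_PRECLUSTER_CUTOFF
) -> list[set[str]]:
    """Average-linkage (UPGMA) clusters with all merge heights <= cutoff."""
    return _cut(d.ids, d.d, "average", cutoff)


def label_kind(cluster: set[str], reference_ids: set[str]) -> str:
    """kSGB iff the cluster contains at least one reference genome."""
    return "kSGB" if cluster & set(reference_ids) else "uSGB"


def select_representative(
    cluster: set[str],
    kind: str,
    metrics: dict[str, QualityMetrics],
) -> str:
    """Pick the cluster representative.

    kSGB: the member with the largest genome (ties break lexicographically).
    uSGB: the member minimizing the sum of five competition ranks —
    completeness (desc), contamination (asc), mean depth (desc), strain
    heterogeneity (asc), N50 (desc); rank-sum ties break lexicographically.
    """
    members = sorted(cluster)
    if len(members) == 1:
        return members[0]
    if kind == "kSGB":
        missing = [m for m in members if m not in metrics]
        if missing:
            raise ValueError(f"missing genome length for members: {missing}")
        return max(members, key=lambda m: (metrics[m].genome_length, _neg_id(m)))
    missing = [m for m in members if m not in metrics]
    if missing:
        raise ValueError(f"missing quality metrics for members: {missing}")
    cols = np.array(
        [
            [
                -metrics[m].completeness,
                metrics[m].contamination,
                -metrics[m].mean_depth,
                metrics[m].strain_heterogeneity,
                -metrics[m].n50,
            ]
            for m in members
        ]
    )
    ranks = np.column_stack(
        [rankdata(cols[:, j], method="min") for j in range(cols.shape[1])]
    )
    sums = ranks.sum(axis=1)
    best = sums.min()
    return min(m for m, s in zip(members, sums) if s == best)


class _neg_id:
    """Reverse lexicographic key so max() tie-breaks to the smallest id."""

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_id") -> bool:
        return self.s > other.s


def refinement_pairs(
    representatives: list[str],
    d: DistanceMatrix,
    candidate_cutoff: float = DEFAULT_CANDIDATE_CUTOFF,
) -> list[tuple[str, str]]:
    """Representative pairs close enough in Mash distance to deserve ANI."""
    idx = {g: d.ids.index(g) for g in representatives}
    reps = sorted(representatives)
    pairs = []
    for i, a in enumerate(reps):
        for b in reps[i + 1 :]:
            if d.d[idx[a], idx[b]] <= candidate_cutoff:
                pairs.append((a, b))
    return pairs


def merge_by_ani(
    preclusters: list[set[str]],
    representatives: dict[int, str],
    pair_ani: dict[frozenset, tuple[float, float]],
    ani_cutoff: float = DEFAULT_ANI_CUTOFF,
    coverage_cutoff: float = DEFAULT_COVERAGE_CUTOFF,
) -> list[set[str]]:
    """Union pre-clusters whose representatives co-cluster at ANI > cutoff.

    ``pair_ani`` maps frozenset({rep_a, rep_b}) to the symmetrized
    (ani percent, coverage). Pairs with coverage not above
    ``coverage_cutoff`` — and pairs absent from the map — are treated as
    maximally distant. Complete linkage on distance 100 − ANI, cut at
    100 − ani_cutoff; whole memberships are unioned.
    """
    reps = sorted(representatives.values())
    if len(reps) <= 1:
        return [set(c) for c in preclusters]
    n = len(reps)
    pos = {r: i for i, r in enumerate(reps)}
    maximal = 100.0
    dist = np.full((n, n), maximal)
    np.fill_diagonal(dist, 0.0)
    for key, (ani_val, cov) in pair_ani.items():
        a, b = sorted(key)
        if a not in pos or b not in pos:
            continue
        if cov > coverage_cutoff:
            dval = max(0.0, 100.0 - ani_val)
            dist[pos[a], pos[b]] = dist[pos[b], pos[a]] = dval
    z = linkage(squareform(dist, checks=False), method="complete")
    # cut strictly below the threshold: ANI > 95 means distance < 5
    eps = 1e-9
    labels = fcluster(z, t=(100.0 - ani_cutoff) - eps, criterion="distance")
    groups: dict[int, list[int]] = {}
    for ci, rep in representatives.items():
        groups.setdefault(int(labels[pos[rep]]), []).append(ci)
    merged = []
    for lab in sorted(groups):
        union: set[str] = set()
        for ci in groups[lab]:
            union |= preclusters[ci]
        merged.append(union)
    return merged


def assemble_catalog(
    final_partition: list[set[str]],
    reference_ids: set[str],
    oral_reference_ids: set[str],
    oral_mag_ids: set[str],
    metrics: dict[str, QualityMetrics],
) -> list[SGBRecord]:
    """Build the final SGB records with stable ids.

    Representatives are re-selected on the merged membership (kSGB rule if
    any member is a reference, else rank-sum). ``oral`` is true iff the
    cluster contains an oral reference genome or an oral MAG. SGB ids are
    assigned in sorted order of representative id.
    """
    seen: set[str] = set()
    for cluster in final_partition:
        overlap = seen & cluster
        if overlap:
            raise ValueError(f"overlapping clusters: {sorted(overlap)[:5]}")
        seen |= cluster
    records = []
    for cluster in final_partition:
        kind = label_kind(cluster, reference_ids)
        rep = select_representative(cluster, kind, metrics)
        oral = bool(cluster & oral_reference_ids) or bool(cluster & oral_mag_ids)
        records.append((rep, cluster, kind, oral))
    records.sort(key=lambda r: r[0])
    out = []
    for i, (rep, cluster, kind, oral) in enumerate(records):
        out.append(
            SGBRecord(
                sgb_id=f"SGB{i + 1:05d}",
                member_ids=frozenset(cluster),
                representative_id=rep,
                kind=kind,
                oral=oral,
            )
        )
    return out
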