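"""Two-step SGB clustering: linkage cuts, kinds, representatives, merging."""

import numpy as np
import pytest
from scipy.stats import rankdata

from sgbforge.clustering import (
    DistanceMatrix,
    assemble_catalog,
    label_kind,
    merge_by_ani,
    precluster,
    refinement_pairs,
    select_representative,
)
from sgbforge.records import QualityMetrics


def _dm(ids, pairs):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=list(ids), d=d)


def _qm(gid, comp=90, cont=1, depth=10, het=5, n50=40_000, length=2_000_000):
    return QualityMetrics(
        genome_id=gid, completeness=comp, contamination=cont,
        strain_heterogeneity=het, mean_depth=depth, n50=n50, genome_length=length,
    )


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        d = np.array([[0, 0.1], [0.2, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=d)

    def test_out_of_range_rejected(self):
        d = np.array([[0, 1.5], [1.5, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=d)


class TestPrecluster:
    def test_all_below_cutoff_single_cluster(self):
        dm = _dm(["a", "b", "c"], {("a", "b"): 0.01, ("a", "c"): 0.01, ("b", "c"): 0.01})
        assert precluster(dm, 0.05) == [{"a", "b", "c"}]

    def test_upgma_hand_example(self):
        # d(A,B)=0.01 merges; d({AB},C) = avg(0.20, 0.20) > cutoff
        dm = _dm(["A", "B", "C"], {("A", "B"): 0.01, ("A", "C"): 0.20, ("B", "C"): 0.20})
        parts = precluster(dm, 0.05)
        assert sorted(map(sorted, parts)) == [["A", "B"], ["C"]]

    def test_all_above_cutoff_singletons(self):
        dm = _dm(["a", "b", "c"], {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5})
        assert len(precluster(dm, 0.05)) == 3

    def test_boundary_distance_merges(self):
        # cut is strictly above the cutoff: d == cutoff still merges
        dm = _dm(["a", "b"], {("a", "b"): 0.05})
        assert precluster(dm, 0.05) == [{"a", "b"}]

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        ids = [f"g{i}" for i in range(12)]
        m = rng.uniform(0, 1, size=(12, 12))
        d = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(d, 0)
        parts = precluster(DistanceMatrix(ids=ids, d=d), 0.3)
        flat = sorted(g for c in parts for g in c)
        assert flat == sorted(ids)


class TestLabelKind:
    def test_with_reference(self):
        assert label_kind({"m1", "r1"}, {"r1", "r2"}) == "kSGB"

    def test_mags_only(self):
        assert label_kind({"m1", "m2"}, {"r1"}) == "uSGB"

    def test_empty_reference_set(self):
        assert label_kind({"m1"}, set()) == "uSGB"


class TestSelectRepresentative:
    def test_ksgb_largest_genome(self):
        metrics = {
            "a": _qm("a", length=2_100_000),
            "b": _qm("b", length=1_800_000),
        }
        assert select_representative({"a", "b"}, "kSGB", metrics) == "a"

    def test_usgb_worked_rank_sum_example(self):
        # competition ranks sum to A=10, B=9, C=11
        metrics = {
            "A": _qm("A", comp=95, cont=1, depth=30, het=5, n50=50_000),
            "B": _qm("B", comp=90, cont=0.5, depth=50, het=2, n50=40_000),
            "C": _qm("C", comp=99, cont=4, depth=10, het=10, n50=60_000),
        }
        assert select_representative({"A", "B", "C"}, "uSGB", metrics) == "B"

    def test_singleton(self):
        assert select_representative({"only"}, "uSGB", {}) == "only"

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError):
            select_representative({"a", "b"}, "uSGB", {"a": _qm("a")})

    def test_matches_bruteforce_on_random_tables(self):
        """Rank-sum winner agrees with exhaustive enumeration (1000 tables)."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(2, 8))
            ids = [f"g{i}" for i in range(n)]
            metrics = {
                g: _qm(
                    g,
                    comp=float(rng.integers(50, 101)),
                    cont=float(rng.integers(0, 10)),
                    depth=float(rng.integers(1, 100)),
                    het=float(rng.integers(0, 50)),
                    n50=int(rng.integers(10_000, 100_000)),
                )
                for g in ids
            }
            # independent oracle: competition ranks per criterion
            cols = np.array(
                [
                    [
                        -metrics[g].completeness,
                        metrics[g].contamination,
                        -metrics[g].mean_depth,
                        metrics[g].strain_heterogeneity,
                        -metrics[g].n50,
                    ]
                    for g in ids
                ]
            )
            sums = np.zeros(n)
            for j in range(5):
                vals = cols[:, j]
                sums += np.array([1 + np.sum(vals < v) for v in vals])
            best = sums.min()
            expected = min(g for g, s in zip(ids, sums) if s == best)
            assert select_representative(set(ids), "uSGB", metrics) == expected


class TestRefinementPairs:
    def test_cutoff_filtering(self):
        dm = _dm(["x", "y", "z"], {("x", "y"): 0.02, ("x", "z"): 0.5, ("y", "z"): 0.5})
        assert refinement_pairs(["x", "y", "z"], dm, 0.10) == [("x", "y")]

    def test_exhaustive_at_cutoff_one(self):
        dm = _dm(["x", "y", "z"], {("x", "y"): 0.3, ("x", "z"): 0.5, ("y", "z"): 0.9})
        assert len(refinement_pairs(["x", "y", "z"], dm, 1.0)) == 3


class TestMergeByAni:
    def _three(self):
        pre = [{"X", "x2"}, {"Y"}, {"Z"}]
        reps = {0: "X", 1: "Y", 2: "Z"}
        return pre, reps

    def test_complete_linkage_hand_example(self):
        # merging Z would need max distance <= 5 but d(X,Z) = 6
        pre, reps = self._three()
        pair_ani = {
            frozenset(("X", "Y")): (97.0, 0.8),
            frozenset(("Y", "Z")): (96.0, 0.8),
            frozenset(("X", "Z")): (94.0, 0.8),
        }
        merged = merge_by_ani(pre, reps, pair_ani)
        assert sorted(map(sorted, merged)) == [["X", "Y", "x2"], ["Z"]]

    def test_coverage_gate_blocks_merge(self):
        pre, reps = self._three()
        pair_ani = {frozenset(("X", "Y")): (99.0, 0.2)}
        merged = merge_by_ani(pre, reps, pair_ani)
        assert len(merged) == 3

    def test_boundary_ani_is_strict(self):
        pre, reps = self._three()
        pair_ani = {frozenset(("X", "Y")): (95.0, 0.8)}
        assert len(merge_by_ani(pre, reps, pair_ani)) == 3  # needs ANI > 95

    def test_no_pairs_identity(self):
        pre, reps = self._three()
        merged = merge_by_ani(pre, reps, {})
        assert sorted(map(sorted, merged)) == sorted(map(sorted, pre))

    def test_idempotent(self):
        pre, reps = self._three()
        pair_ani = {frozenset(("X", "Y")): (97.0, 0.8)}
        once = merge_by_ani(pre, reps, pair_ani)
        reps2 = {i: sorted(c)[0] for i, c in enumerate(once)}
        twice = merge_by_ani(once, reps2, pair_ani)
        assert sorted(map(sorted, twice)) == sorted(map(sorted, once))


class TestAssembleCatalog:
    def test_oral_flag_and_kinds(self):
        metrics = {g: _qm(g) for g in ["m1", "m2", "n1"]}
        metrics["r1"] = _qm("r1", length=3_000_000)  # largest genome wins kSGB
        catalog = assemble_catalog(
            [{"r1", "m1"}, {"m2"}, {"n1"}],
            reference_ids={"r1", "n1"},
            oral_reference_ids={"r1"},
            oral_mag_ids={"m2"},
            metrics=metrics,
        )
        by_rep = {r.representative_id: r for r in catalog}
        assert by_rep["r1"].kind == "kSGB" and by_rep["r1"].oral
        assert by_rep["m2"].kind == "uSGB" and by_rep["m2"].oral
        assert by_rep["n1"].kind == "kSGB" and not by_rep["n1"].oral

    def test_singleton_catalog(self):
        catalog = assemble_catalog([{"g"}], set(), set(), set(), {"g": _qm("g")})
        assert len(catalog) == 1 and catalog[0].representative_id == "g"

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError):
            assemble_catalog(
                [{"a", "b"}, {"b"}], set(), set(), set(),
                {g: _qm(g) for g in "ab"},
            )

    def test_stable_ids_sorted_by_representative(self):
        metrics = {g: _qm(g) for g in "abc"}
        catalog = assemble_catalog(
            [{"c"}, {"a"}, {"b"}], set(), set(), set(), metrics
        )
        assert [r.representative_id for r in catalog] == ["a", "b", "c"]
        assert [r.sgb_id for r in catalog] == ["SGB00001", "SGB00002", "SGB00003"]
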