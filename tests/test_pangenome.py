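import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancore.pangenome import (
    PresenceMatrix, build_presence_matrix, clade_specific_genes,
    classify_openness, hgt_screen, partition_pangenome, quality_filter,
    rarefaction_curves, read_matrix_tsv, write_matrix_tsv, RarefactionCurve,
)


def _matrix(rows: dict[str, list[int]], genomes: list[str]) -> PresenceMatrix:
    return PresenceMatrix(pd.DataFrame(rows, index=genomes).T)


class TestQualityFilter:
    def test_single_outlier_excluded(self):
        counts = dict(zip("abcdefghij",
                          [100, 101, 99, 100, 100, 100, 100, 100, 100, 160]))
        kept, excluded = quality_filter(counts)
        # mean 106, population sigma ~18.0 => bounds ~[70, 142]
        assert excluded == ["j"]
        assert len(kept) == 9

    def test_all_equal_none_excluded(self):
        kept, excluded = quality_filter({f"g{i}": 50 for i in range(5)})
        assert excluded == []

    def test_single_genome_kept_with_warning(self):
        with pytest.warns(UserWarning):
            kept, excluded = quality_filter({"only": 7})
        assert kept == ["only"] and excluded == []

    def test_planted_outliers_recovered(self, tiny_sim):
        genomes, truth = tiny_sim
        _, excluded = quality_filter(genomes.gene_counts())
        assert set(excluded) == truth.outlier_genomes


class TestPresenceMatrix:
    def test_copy_counts_and_conservation(self, tiny_matrix, tiny_kept):
        total_genes = sum(len(g.genes) for g in tiny_kept)
        assert int(tiny_matrix.counts.values.sum()) == total_genes
        # column sums equal genome gene counts
        counts = tiny_kept.gene_counts()
        for genome in tiny_matrix.genome_ids:
            assert int(tiny_matrix.counts[genome].sum()) == counts[genome]

    def test_paralogs_count_once_for_occupancy(self):
        m = _matrix({"c1": [2, 0, 1]}, ["gA", "gB", "gC"])
        assert int(m.occupancy()["c1"]) == 2

    def test_private_cluster_is_a_row(self, tiny_matrix):
        assert (tiny_matrix.occupancy() >= 1).all()

    def test_unknown_gene_rejected(self, tiny_clusters, tiny_kept):
        broken = tiny_kept.subset(tiny_kept.genome_ids[:2])
        with pytest.raises(ValueError, match="absent"):
            build_presence_matrix(tiny_clusters, broken)


class TestPartition:
    def test_occupancy_bands_at_n100(self):
        genomes = [f"g{i}" for i in range(100)]
        rows = {
            "full": [1] * 100,
            "o96": [1] * 96 + [0] * 4,
            "o94": [1] * 94 + [0] * 6,
            "o3": [1] * 3 + [0] * 97,
            "o2": [1] * 2 + [0] * 98,
        }
        report = partition_pangenome(_matrix(rows, genomes))
        cls = report.cluster_class
        assert cls["full"] == "core"
        assert cls["o96"] == "softcore"
        assert cls["o94"] == "shell"
        assert cls["o3"] == "shell"
        assert cls["o2"] == "cloud"
        # core is included in the softcore size
        assert report.sizes["softcore"] == 2

    def test_conservation_invariant(self, tiny_matrix):
        sizes = partition_pangenome(tiny_matrix).sizes
        assert (sizes["softcore"] + sizes["shell"] + sizes["cloud"]
                == sizes["pan"])

    def test_truth_classes_recovered(self, tiny_matrix, tiny_clusters,
                                     tiny_sim):
        _, truth = tiny_sim
        report = partition_pangenome(tiny_matrix)
        fam_of = {c.id: truth.gene_family[c.members[0]] for c in tiny_clusters}
        for cid, cls in report.cluster_class.items():
            assert cls == truth.family_class[fam_of[cid]]

    def test_too_few_genomes_rejected(self):
        with pytest.raises(ValueError):
            partition_pangenome(_matrix({"c": [1, 1]}, ["a", "b"]))


class TestRarefaction:
    def test_set_enumeration_example(self):
        # genomes with families {a,b,c},{b,c,d},{c,d,e} => pan 3,4,5 core 3,2,1
        genomes = ["g1", "g2", "g3"]
        rows = {
            "a": [1, 0, 0], "b": [1, 1, 0], "c": [1, 1, 1],
            "d": [0, 1, 1], "e": [0, 0, 1],
        }
        m = _matrix(rows, genomes)
        curves = rarefaction_curves(m, 50, seed=1)
        identity_order = next(c for c in curves if c.order == genomes)
        assert identity_order.pan == [3, 4, 5]
        assert identity_order.core == [3, 2, 1]

    def test_monotonicity_and_common_endpoint(self, tiny_matrix):
        curves = rarefaction_curves(tiny_matrix, 10, seed=3)
        ends = {(c.pan[-1], c.core[-1]) for c in curves}
        assert len(ends) == 1
        for c in curves:
            assert all(a <= b for a, b in zip(c.pan, c.pan[1:]))
            assert all(a >= b for a, b in zip(c.core, c.core[1:]))

    def test_seeded_determinism(self, tiny_matrix):
        a = rarefaction_curves(tiny_matrix, 5, seed=9)
        b = rarefaction_curves(tiny_matrix, 5, seed=9)
        assert [c.order for c in a] == [c.order for c in b]


def _linear_curve(slope, n=30, start=1000):
    pan = [int(start + slope * i) for i in range(n)]
    core = [start] * n
    return RarefactionCurve(0, [f"g{i}" for i in range(n)], pan, core, 0)


class TestOpenness:
    def test_slope_50_is_open(self):
        call, slope = classify_openness([_linear_curve(50)])
        assert call == "open"
        assert slope == pytest.approx(50.0)

    def test_slope_4_5_is_closed(self):
        call, slope = classify_openness([_linear_curve(4.5)])
        assert call == "closed"
        assert slope == pytest.approx(4.5, abs=0.5)

    def test_constant_curve_closed(self):
        call, slope = classify_openness([_linear_curve(0)])
        assert call == "closed" and slope == 0.0


class TestCladeSpecific:
    def test_specific_and_rejected(self):
        genomes = ["a1", "a2", "b1", "b2"]
        rows = {
            "spec": [1, 1, 0, 0],
            "leaky": [1, 1, 1, 0],
        }
        m = _matrix(rows, genomes)
        specific, _ = clade_specific_genes(m, ["a1", "a2"], ["b1", "b2"])
        assert specific == ["spec"]

    def test_expansions(self):
        genomes = ["a1", "a2", "a3", "b1", "b2"]
        rows = {
            "exp": [2, 2, 3, 1, 1],   # min A = 2 > max B = 1
            "noexp": [2, 1, 1, 1, 1],  # min A = 1, not > 1
        }
        m = _matrix(rows, genomes)
        _, expanded = clade_specific_genes(m, ["a1", "a2", "a3"], ["b1", "b2"])
        assert expanded == ["exp"]

    def test_overlap_rejected(self, tiny_matrix):
        ids = tiny_matrix.genome_ids
        with pytest.raises(ValueError, match="overlap"):
            clade_specific_genes(tiny_matrix, ids[:2], ids[1:3])


class TestHGTScreen:
    def _m(self, present_a, present_b):
        genomes = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        row = [1] * present_a + [0] * (10 - present_a) \
            + [1] * present_b + [0] * (10 - present_b)
        m = _matrix({"x": row}, genomes)
        clades = {g: g[0] for g in genomes}
        return m, clades

    def test_candidate_in_band(self):
        m, clades = self._m(5, 3)
        assert list(hgt_screen(m, clades).index) == ["x"]

    def test_rejected_out_of_band(self):
        m, clades = self._m(5, 2)
        assert hgt_screen(m, clades).empty

    def test_inclusive_bounds(self):
        m, clades = self._m(7, 7)
        assert list(hgt_screen(m, clades).index) == ["x"]
        m, clades = self._m(3, 3)
        assert list(hgt_screen(m, clades).index) == ["x"]

    def test_small_clade_rejected(self):
        m = _matrix({"x": [1, 0, 1]}, ["a1", "a2", "b1"])
        with pytest.raises(ValueError, match="fewer than 2"):
            hgt_screen(m, {"a1": "a", "a2": "a", "b1": "b"})

    def test_planted_hgt_recovered(self, tiny_matrix, tiny_clusters, tiny_sim):
        _, truth = tiny_sim
        clades = {g: truth.clade_of[g] for g in tiny_matrix.genome_ids}
        got = set(hgt_screen(tiny_matrix, clades).index)
        fam_of = {c.id: truth.gene_family[c.members[0]] for c in tiny_clusters}
        assert {fam_of[c] for c in got} == truth.hgt_families


@settings(max_examples=25, deadline=None)
@given(counts=st.lists(st.integers(min_value=0, max_value=10_000),
                       min_size=3, max_size=30),
       k=st.floats(min_value=0.5, max_value=4.0))
def test_quality_filter_partitions_input(counts, k):
    mapping = {f"g{i}": c for i, c in enumerate(counts)}
    kept, excluded = quality_filter(mapping, k_sigma=k)
    assert sorted(kept + excluded) == sorted(mapping)


def test_matrix_tsv_round_trip(tmp_path, tiny_matrix):
    path = write_matrix_tsv(tiny_matrix, tmp_path / "m.tsv")
    back = read_matrix_tsv(path)
    pd.testing.assert_frame_equal(back.counts, tiny_matrix.counts,
                                  check_names=False)
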