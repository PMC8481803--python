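import numpy as np
import pandas as pd
import pytest

from trailkit.singlecell import (
    CellActivityMatrix,
    build_activity_matrix,
    group_activity_test,
    normalize_cells,
    per_cell_ora,
    pseudo_bulk,
    qc_filter,
    top_n_genes,
)
from trailkit.simulate import GenesetSpec, SingleCellSpec, make_genesets, make_single_cell
from trailkit.types import (
    ComputationError,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)


def counts_matrix(arr, genes=None, cells=None, meta=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=cells)
    return ExpressionMatrix(df, meta, mode="counts")


class TestQcFilter:
    def test_empty_cell_removed(self):
        m = counts_matrix([[5, 0], [3, 0], [2, 0]])
        out = qc_filter(m, min_genes=2, max_genes=10)
        assert out.columns == ["c0"]

    def test_all_within_bounds_is_identity_on_cells(self):
        m = counts_matrix([[5, 1], [3, 2], [2, 4]])
        out = qc_filter(m, min_genes=1, max_genes=10)
        assert out.columns == m.columns
        assert np.array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_planted_failing_cells_removed_exactly(self):
        m, meta, truth = make_single_cell(SingleCellSpec(seed=3))
        out = qc_filter(
            m, min_genes=truth["qc_min_genes"], max_total=truth["qc_max_total"]
        )
        removed = set(m.columns) - set(out.columns)
        assert removed == set(truth["failing_cells"])

    def test_max_total_rule(self):
        m = counts_matrix([[5, 500], [3, 600]])
        out = qc_filter(m, min_genes=1, max_genes=10, max_total=100)
        assert out.columns == ["c0"]

    def test_no_survivor_is_error(self):
        m = counts_matrix([[1, 1], [0, 0]])
        with pytest.raises(ComputationError):
            qc_filter(m, min_genes=5, max_genes=10)

    def test_requires_counts_mode(self):
        df = pd.DataFrame([[1.0]], index=["g"], columns=["c"])
        with pytest.raises(ValidationError, match="counts"):
            qc_filter(ExpressionMatrix(df, mode="normalized"))


class TestNormalizeCells:
    def test_single_gene_cell_scaled_to_full_depth(self):
        m = counts_matrix([[7, 3], [0, 2]])
        out = normalize_cells(m)
        assert out.values.loc["G0", "c0"] == pytest.approx(np.log1p(10000.0))

    def test_depth_doubling_invariance(self):
        m1 = counts_matrix([[4, 1], [6, 1]])
        m2 = counts_matrix([[8, 1], [12, 1]])
        assert np.allclose(
            normalize_cells(m1).values["c0"], normalize_cells(m2).values["c0"]
        )

    def test_column_sums_hit_scale(self):
        rng = np.random.default_rng(0)
        m = counts_matrix(rng.integers(0, 30, size=(50, 8)) + (rng.random((50, 8)) < 0.5))
        out = normalize_cells(m)
        pre_log = np.expm1(out.values.to_numpy())
        assert np.allclose(pre_log.sum(axis=0), 10000.0, atol=1e-6)

    def test_zero_total_cell_is_error(self):
        m = counts_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValidationError, match="zero total"):
            normalize_cells(m)


class TestTopNGenes:
    def test_fewer_detected_than_n_uses_all(self):
        m = counts_matrix([[5, 1], [0, 2], [0, 3]])
        top = top_n_genes(normalize_cells(m), n=10)
        assert top["c0"] == frozenset({"G0"})
        assert top["c1"] == frozenset({"G0", "G1", "G2"})

    def test_n_one_is_argmax(self):
        m = counts_matrix([[5, 1], [2, 9]])
        top = top_n_genes(normalize_cells(m), n=1)
        assert top["c0"] == frozenset({"G0"})
        assert top["c1"] == frozenset({"G1"})

    def test_boundary_tie_broken_lexicographically(self):
        # gb and ga tie at the boundary; ga wins by token
        m = counts_matrix([[9], [4], [4]], genes=["gc", "gb", "ga"])
        top = top_n_genes(normalize_cells(m), n=2)
        assert top["c0"] == frozenset({"GC", "GA"})


class TestPerCellOra:
    @pytest.fixture
    def activity_setup(self):
        reference = {f"G{i}" for i in range(20)}
        top = {
            "c0": frozenset({"G0", "G1", "G2", "G3"}),
            "c1": frozenset({"G10", "G11", "G12", "G13"}),
        }
        coll = GeneSetCollection(
            [
                GeneSet("hitset", "", frozenset({"G0", "G1", "G2", "G3", "G4"})),
                GeneSet("offset", "", frozenset({"G15", "G16", "G17"})),
            ]
        )
        return top, coll, reference

    def test_activity_nonnegative_and_identical_category_filter(self, activity_setup):
        top, coll, ref = activity_setup
        activity, p_raw, tested = per_cell_ora(top, coll, ref)
        assert (activity.to_numpy() >= 0).all()
        assert tested == ["hitset", "offset"]
        assert activity.shape == (2, 2)

    def test_disjoint_category_matches_k_zero_tail(self, activity_setup):
        from scipy.stats import hypergeom

        top, coll, ref = activity_setup
        _, p_raw, _ = per_cell_ora(top, coll, ref)
        expected = float(hypergeom.sf(-1, 20, 3, 4))  # k=0 tail = 1
        assert p_raw.loc["c0", "offset"] == pytest.approx(expected)

    def test_program_cells_more_active(self):
        m, meta, truth = make_single_cell(SingleCellSpec(seed=5))
        f = qc_filter(m, min_genes=truth["qc_min_genes"], max_total=truth["qc_max_total"])
        n = normalize_cells(f)
        coll = make_genesets(GenesetSpec(seed=5, n_decoys=10), m.genes, truth)
        am = build_activity_matrix(n, coll, n=200)
        labels = am.cell_meta.loc[am.activity.index, "group"]
        prog = am.activity.loc[labels == truth["program_group"], "planted_program"]
        rest = am.activity.loc[labels != truth["program_group"], "planted_program"]
        assert prog.median() > rest.median()


class TestGroupActivityTest:
    def _activity(self, values_by_group):
        rows, cells, groups = [], [], []
        i = 0
        for group, vals in values_by_group.items():
            for v in vals:
                rows.append(v)
                cells.append(f"c{i}")
                groups.append(group)
                i += 1
        act = pd.DataFrame({"cat": rows}, index=cells)
        meta = pd.DataFrame({"group": groups}, index=cells)
        return CellActivityMatrix(
            activity=act, p_raw=np.exp(-act * np.log(10)).clip(upper=1.0),
            cell_meta=meta, tested_categories=["cat"],
        )

    def test_identical_groups_not_significant(self):
        vals = [0.1, 0.5, 0.9, 1.3, 1.7]
        a = self._activity({"x": vals, "y": vals})
        recs = group_activity_test(a)
        assert all(r.p_adj > 0.05 for r in recs)

    def test_direction_flips_under_negated_ranks(self):
        a = self._activity({"x": [3.0, 3.5, 4.0, 4.5], "y": [0.5, 1.0, 1.5, 2.0]})
        recs = {r.group: r for r in group_activity_test(a)}
        assert recs["x"].direction == "more_active"
        assert recs["y"].direction == "less_active"

    def test_small_group_excluded(self):
        a = self._activity({"x": [1.0, 2.0, 3.0], "y": [4.0, 5.0, 6.0], "z": [9.0]})
        recs = group_activity_test(a)
        assert {r.group for r in recs} == {"x", "y"}

    def test_planted_group_recovery_single_seed(self):
        m, meta, truth = make_single_cell(SingleCellSpec(seed=11))
        f = qc_filter(m, min_genes=truth["qc_min_genes"], max_total=truth["qc_max_total"])
        coll = make_genesets(GenesetSpec(seed=11, n_decoys=30), m.genes, truth)
        am = build_activity_matrix(normalize_cells(f), coll, n=200)
        recs = [r for r in group_activity_test(am) if r.category == "planted_program"]
        sig_more = {r.group for r in recs if r.p_adj <= 0.05 and r.direction == "more_active"}
        assert sig_more == {truth["program_group"]}


class TestPseudoBulk:
    def test_one_cell_per_sample_is_identity(self):
        meta = pd.DataFrame({"sample": ["s1", "s2"]}, index=["c0", "c1"])
        m = counts_matrix([[1, 2], [3, 4]], meta=meta)
        out = pseudo_bulk(m)
        assert np.array_equal(
            out.values[["s1", "s2"]].to_numpy(), m.values.to_numpy()
        )

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 50, size=(30, 12))
        meta = pd.DataFrame(
            {"sample": [f"s{i % 3}" for i in range(12)]},
            index=[f"c{i}" for i in range(12)],
        )
        m = counts_matrix(arr, meta=meta)
        out = pseudo_bulk(m)
        assert out.values.to_numpy().sum() == arr.sum()

    def test_hand_summed_columns(self):
        meta = pd.DataFrame(
            {"sample": ["s1", "s1", "s2"]}, index=["c0", "c1", "c2"]
        )
        m = counts_matrix([[1, 2, 4], [3, 5, 6]], meta=meta)
        out = pseudo_bulk(m)
        assert out.values["s1"].tolist() == [3.0, 8.0]
        assert out.values["s2"].tolist() == [4.0, 6.0]

    def test_unlabeled_cell_is_error(self):
        meta = pd.DataFrame({"sample": ["s1", None]}, index=["c0", "c1"])
        m = counts_matrix([[1, 2]], meta=meta)
        with pytest.raises(ValidationError, match="no 'sample'"):
            pseudo_bulk(m)
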