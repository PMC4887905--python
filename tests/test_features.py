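import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from mirspace import features, io, ontology, synthetic
from mirspace.features import (
    NeighborParams,
    build_disease_matrix,
    build_family_matrix,
    build_neighbor_matrix,
    build_word_matrix,
    concatenate,
    genomic_distance,
    project_targets,
    read_combined,
    sigmoid_weight,
    write_combined,
)
from mirspace.io import Dataset, MirnaRecord


def make_dataset(records, diseases=None, genes=None, families=None):
    return Dataset(
        mirnas=records,
        diseases=diseases or sorted({d for r in records for d in r.diseases}),
        genes=genes or sorted({g for r in records for g in r.targets}),
        families=families or sorted({r.family for r in records if r.family}),
        vocabulary=sorted({t for r in records for t in io.tokenize(r.abstract_text)}),
    )


class TestSigmoid:
    def test_midpoint_is_exactly_half(self):
        for k in (2e-4, 1e-5, 3.7):
            for dist0 in (6e4, 6e5, 123.0):
                assert sigmoid_weight(dist0, NeighborParams(dist0=dist0, steepness=k)) == 0.5

    def test_zero_distance_near_one(self):
        params = NeighborParams()
        w = sigmoid_weight(0.0, params)
        assert w == pytest.approx(1 / (1 + np.exp(-params.steepness * params.dist0)))
        assert w > 0.99

    def test_strictly_decreasing(self):
        params = NeighborParams()
        dists = np.linspace(0, 3e5, 50)
        weights = [sigmoid_weight(d, params) for d in dists]
        assert all(a > b for a, b in zip(weights, weights[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeighborParams(dist0=-1.0)
        with pytest.raises(ValueError):
            NeighborParams(steepness=0.0)


class TestGenomicDistance:
    def test_gap_between_closest_ends(self):
        a = [("chr1", "+", 100, 200)]
        b = [("chr1", "-", 500, 600)]
        assert genomic_distance(a, b) == 300

    def test_overlap_is_zero(self):
        assert genomic_distance([("chr1", "+", 100, 200)], [("chr1", "+", 150, 250)]) == 0

    def test_different_chromosomes_infinite(self):
        assert genomic_distance([("chr1", "+", 1, 2)], [("chr2", "+", 1, 2)]) == np.inf

    def test_multi_location_takes_minimum(self):
        a = [("chr1", "+", 100, 200), ("chr2", "+", 100, 200)]
        b = [("chr2", "+", 300, 400)]
        assert genomic_distance(a, b) == 100


class TestDiseaseMatrix:
    @pytest.fixture()
    def onto(self):
        codes = {"a": {"C01"}, "b": {"C01.100"}, "c": {"C01.200"}, "d": {"C02"}}
        assoc = {"m1": {"b"}, "m2": {"c"}, "m3": {"d"}, "m4": {"d"}}
        return ontology.build_ontology(codes, assoc)

    def test_known_association_is_one(self, onto):
        ds = make_dataset([MirnaRecord(id="m1", diseases={"b"})], diseases=["b", "c", "d"])
        fm = build_disease_matrix(ds, onto)
        assert fm.matrix[0, fm.cols.index("b")] == 1.0

    def test_no_associations_zero_row(self, onto):
        ds = make_dataset(
            [MirnaRecord(id="m1", diseases={"b"}), MirnaRecord(id="m0")],
            diseases=["b", "c", "d"],
        )
        fm = build_disease_matrix(ds, onto)
        assert fm.matrix[fm.rows.index("m0")].nnz == 0

    def test_propagated_value_is_max_lin(self, onto):
        # m1 known only for b; column c gets lin(b, c) = 0.5 exactly
        assert ontology.lin_similarity(onto, "b", "c") == pytest.approx(0.5)
        ds = make_dataset([MirnaRecord(id="m1", diseases={"b"})], diseases=["b", "c", "d"])
        fm = build_disease_matrix(ds, onto)
        assert fm.matrix[0, fm.cols.index("c")] == pytest.approx(0.5)

    def test_floor_drops_small_values(self, onto):
        ds = make_dataset([MirnaRecord(id="m1", diseases={"b"})], diseases=["b", "c", "d"])
        fm = build_disease_matrix(ds, onto, floor=0.6)
        assert fm.matrix[0, fm.cols.index("c")] == 0.0

    def test_exclude_masks_entry_and_propagation(self, onto):
        ds = make_dataset([MirnaRecord(id="m1", diseases={"b"})], diseases=["b", "c", "d"])
        fm = build_disease_matrix(ds, onto, exclude={"m1": {"b"}})
        assert fm.matrix[0].nnz == 0  # nothing left to propagate from

    def test_bounds_and_known_entries(self, small_dataset, small_ontology):
        fm = build_disease_matrix(small_dataset, small_ontology)
        assert fm.matrix.min() >= 0.0 and fm.matrix.max() <= 1.0
        for i, rec in enumerate(small_dataset.mirnas):
            for d in rec.diseases:
                assert fm.matrix[i, fm.cols.index(d)] == 1.0


class TestNeighborMatrix:
    def records(self):
        return [
            MirnaRecord(id="m1", locations=[("chr1", "+", 1000, 1100)]),
            MirnaRecord(id="m2", locations=[("chr1", "-", 61100, 61200)]),  # 60 kb away
            MirnaRecord(id="m3", locations=[("chr2", "+", 1000, 1100)]),
            MirnaRecord(id="m4"),
        ]

    def test_midpoint_weight(self):
        ds = make_dataset(self.records())
        fm = build_neighbor_matrix(ds, NeighborParams(dist0=6e4, steepness=2e-4))
        assert fm.matrix[0, 1] == pytest.approx(0.5)

    def test_symmetric_with_unit_diagonal(self):
        ds = make_dataset(self.records())
        fm = build_neighbor_matrix(ds)
        assert (fm.matrix != fm.matrix.T).nnz == 0
        assert fm.matrix[0, 0] == 1.0

    def test_cross_chromosome_zero(self):
        ds = make_dataset(self.records())
        fm = build_neighbor_matrix(ds)
        assert fm.matrix[0, 2] == 0.0

    def test_unlocated_mirna_zero_row(self):
        ds = make_dataset(self.records())
        fm = build_neighbor_matrix(ds)
        assert fm.matrix[3].nnz == 0
        assert fm.matrix[:, 3].nnz == 0


class TestTargetProjection:
    def test_printed_coefficients(self):
        # worked example: alpha's own-resource coefficient 3/4, beta's 1/6
        M, _, targets = synthetic.fig3_fixture()
        W, MT = project_targets(M)
        a = targets.index("alpha")
        b = targets.index("beta")
        assert W[a, a] == pytest.approx(3 / 4)
        assert W[b, a] == pytest.approx(1 / 6)

    def test_first_step_split(self):
        # miRNA b receives half of alpha's resource and a third of beta's
        M, mirnas, targets = synthetic.fig3_fixture()
        deg_t = np.asarray(M.sum(axis=0)).ravel()
        step1 = M.toarray() / deg_t  # miRNA x target share matrix
        row_b = step1[mirnas.index("b")]
        assert row_b[targets.index("alpha")] == pytest.approx(1 / 2)
        assert row_b[targets.index("beta")] == pytest.approx(1 / 3)

    def test_asymmetry(self):
        M, _, targets = synthetic.fig3_fixture()
        W, _ = project_targets(M)
        a, b = targets.index("alpha"), targets.index("beta")
        assert W[b, a] == pytest.approx(1 / 6)
        assert W[a, b] == pytest.approx(1 / 4)

    def test_single_edge(self):
        W, MT = project_targets(sp.csr_matrix(np.array([[1.0]])))
        assert np.allclose(W.toarray(), [[1.0]])
        assert np.allclose(MT.toarray(), [[1.0]])

    def test_existing_edges_keep_positive_weight_and_new_edges_appear(self):
        M, _, _ = synthetic.fig3_fixture()
        _, MT = project_targets(M)
        dense, mt = M.toarray(), MT.toarray()
        assert np.all(mt[dense == 1] > 0)
        assert np.any(mt[dense == 0] > 0)  # implied associations

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            project_targets(np.array([[0.5]]))

    def _diffusion_oracle(self, M):
        """Explicit two-step resource diffusion, one unit per source target."""
        M = np.asarray(M, dtype=float)
        m, t = M.shape
        deg_m = M.sum(axis=1)
        deg_t = M.sum(axis=0)
        W = np.zeros((t, t))
        for j in range(t):
            if deg_t[j] == 0:
                continue
            # step 1: target j's unit spreads equally to its miRNAs
            g = M[:, j] / deg_t[j]
            # step 2: each miRNA redistributes over its targets
            for i in range(m):
                if deg_m[i]:
                    W[j] += g[i] * M[i] / deg_m[i]
        return W

    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=1, max_value=12),
           st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_conservation_against_diffusion_oracle(self, m, t, seed):
        rng = np.random.default_rng(seed)
        M = (rng.random((m, t)) < 0.4).astype(float)
        W, MT = project_targets(sp.csr_matrix(M))
        oracle = self._diffusion_oracle(M)
        assert np.allclose(W.toarray(), oracle, atol=1e-12)
        # conservation: every target with at least one miRNA redistributes
        # its full resource (its distribution sums to one)
        covered = M.sum(axis=0) > 0
        sums = np.asarray(W.sum(axis=1)).ravel()
        assert np.allclose(sums[covered], 1.0, atol=1e-12)
        assert np.allclose(sums[~covered], 0.0)
        assert np.allclose(MT.toarray(), M @ oracle, atol=1e-12)


class TestWordMatrix:
    def test_empty_abstract_zero_row(self):
        ds = make_dataset([
            MirnaRecord(id="m1", abstract_text="lung tumour lung"),
            MirnaRecord(id="m2", abstract_text=""),
        ])
        fm = build_word_matrix(ds)
        assert fm.matrix[1].nnz == 0

    def test_single_word_normalizes_to_one(self):
        ds = make_dataset([MirnaRecord(id="m1", abstract_text="lung lung lung")])
        fm = build_word_matrix(ds)
        assert np.allclose(fm.matrix.toarray(), [[1.0]])

    def test_shared_word_has_smaller_idf(self):
        ds = make_dataset([
            MirnaRecord(id="m1", abstract_text="shared unique"),
            MirnaRecord(id="m2", abstract_text="shared"),
        ])
        fm = build_word_matrix(ds)
        row = fm.matrix[0].toarray().ravel()
        assert row[fm.cols.index("shared")] < row[fm.cols.index("unique")]

    def test_rows_l2_normalized(self, small_dataset):
        fm = build_word_matrix(small_dataset)
        norms = np.sqrt(np.asarray(fm.matrix.multiply(fm.matrix).sum(axis=1))).ravel()
        nonzero = norms > 0
        assert np.allclose(norms[nonzero], 1.0)

    def test_zero_rows_blanks_documents(self, small_dataset):
        mid = small_dataset.mirna_ids[0]
        fm = build_word_matrix(small_dataset, zero_rows={mid})
        assert fm.matrix[0].nnz == 0


class TestFamilyMatrix:
    def test_one_hot_rows(self):
        ds = make_dataset([
            MirnaRecord(id="m1", family="f1"),
            MirnaRecord(id="m2"),
            MirnaRecord(id="m3", family="f1"),
        ])
        fm = build_family_matrix(ds)
        assert fm.matrix[0].toarray().ravel().tolist() == [1.0]
        assert fm.matrix[1].nnz == 0
        assert (fm.matrix[0] != fm.matrix[2]).nnz == 0  # same family, identical rows


class TestConcatenate:
    def test_widths_add_up(self, small_pipeline):
        cm = small_pipeline.combined()
        d = len(small_pipeline.dataset.diseases)
        m = len(small_pipeline.dataset.mirnas)
        t = len(small_pipeline.dataset.genes)
        w = len(small_pipeline.dataset.vocabulary)
        f = len(small_pipeline.dataset.families)
        assert cm.shape == (m, d + m + t + w + f)
        assert [b[0] for b in cm.column_blocks] == list(features.BLOCK_ORDER)
        starts = [b[1] for b in cm.column_blocks]
        stops = [b[2] for b in cm.column_blocks]
        assert starts[0] == 0 and stops[-1] == cm.shape[1]
        assert all(a == b for a, b in zip(stops, starts[1:]))

    def test_single_block_passthrough(self):
        ds = make_dataset([MirnaRecord(id="m1", family="f1")])
        fm = build_family_matrix(ds)
        cm = concatenate([fm])
        assert (cm.X != fm.matrix).nnz == 0
        assert cm.col_labels == fm.cols

    def test_row_mismatch_rejected(self):
        a = build_family_matrix(make_dataset([MirnaRecord(id="m1", family="f")]))
        b = build_word_matrix(make_dataset([MirnaRecord(id="m2", abstract_text="lung")]))
        with pytest.raises(ValueError, match="row labels differ"):
            concatenate([a, b])

    def test_round_trip_export(self, small_pipeline, tmp_path):
        cm = small_pipeline.combined()
        write_combined(cm, tmp_path)
        back = read_combined(tmp_path)
        assert back.row_labels == cm.row_labels
        assert back.col_labels == cm.col_labels
        assert back.column_blocks == cm.column_blocks
        assert np.allclose(back.X.toarray(), cm.X.toarray())
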