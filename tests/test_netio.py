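import numpy as np
import pandas as pd
import pytest

from repowalk import (
    AssociationNetwork,
    WalkConfig,
    read_associations,
    read_matrix,
    read_scores,
    simulate_fixture,
    write_associations,
    write_scores,
)
from repowalk.netio import SCORE_COLUMNS, FeatureMatrix, SimilarityMatrix, write_matrix


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadAssociations:
    def test_transcribes_edge_list(self, tmp_path):
        path = _write(tmp_path, "edges.tsv", "c1\td1\nc1\td2\nc2\td2\n")
        net = read_associations(path)
        assert net.drug_ids == ("c1", "c2")
        assert net.disease_ids == ("d1", "d2")
        assert net.adjacency.tolist() == [[1, 1], [0, 1]]

    def test_duplicate_lines_collapse_to_one_edge(self, tmp_path):
        path = _write(tmp_path, "dup.tsv", "c1\td1\nc1\td1\n")
        net = read_associations(path)
        assert net.adjacency.tolist() == [[1]]

    def test_optional_header_is_skipped(self, tmp_path):
        path = _write(tmp_path, "h.tsv", "drug_id\tdisease_id\nc1\td1\n")
        net = read_associations(path)
        assert net.drug_ids == ("c1",)

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = _write(tmp_path, "bad.tsv", "c1\td1\nc2\n")
        with pytest.raises(ValueError, match="line 2"):
            read_associations(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = _write(tmp_path, "empty.tsv", "")
        with pytest.raises(ValueError, match="no associations"):
            read_associations(path)

    def test_write_read_round_trip_is_identity(self, tmp_path):
        net, _, _ = simulate_fixture(12, 9, 3, 0.5, 0.1, 16, 0.1, seed=3)
        path = tmp_path / "rt.tsv"
        write_associations(net, path)
        back = read_associations(path)
        # ids may be reordered to first-appearance order; compare as edge sets
        assert set(back.edges()) == set(net.edges())
        assert back.adjacency.sum() == net.adjacency.sum()


class TestReadMatrix:
    def test_fingerprint_table(self, tmp_path):
        path = _write(tmp_path, "fp.tsv", "id\tb0\tb1\tb2\nc1\t1\t0\t1\nc2\t0\t0\t1\n")
        fm = read_matrix(path, "fingerprint")
        assert fm.kind == "fingerprint"
        assert fm.values.shape == (2, 3)
        assert fm.row_ids == ("c1", "c2")

    def test_similarity_range_is_validated(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\tc1\tc2\nc1\t1\t1.2\nc2\t1.2\t1\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            read_matrix(path, "similarity")

    def test_symmetric_similarity_is_flagged(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\tc1\tc2\nc1\t1\t0.5\nc2\t0.5\t1\n")
        sim = read_matrix(path, "similarity")
        assert isinstance(sim, SimilarityMatrix) and sim.symmetric

    def test_asymmetric_similarity_is_unflagged(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\tc1\tc2\nc1\t1\t0.5\nc2\t0.25\t1\n")
        assert not read_matrix(path, "similarity").symmetric

    def test_non_square_similarity_is_an_error(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\ta\tb\tc\nc1\t0\t0\t0\nc2\t0\t0\t0\n")
        with pytest.raises(ValueError, match="square"):
            read_matrix(path, "similarity")

    def test_fingerprint_rejects_non_binary(self, tmp_path):
        path = _write(tmp_path, "fp.tsv", "id\tb0\nc1\t0.5\n")
        with pytest.raises(ValueError, match="0 or 1"):
            read_matrix(path, "fingerprint")

    def test_dot_label_is_rejected(self, tmp_path):
        path = _write(tmp_path, "fp.tsv", "id\tb0\n.\t1\n")
        with pytest.raises(ValueError, match=r"'\.'"):
            read_matrix(path, "fingerprint")


def _score_table(rows):
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS[:-1])
    df["rank"] = np.arange(1, len(df) + 1)
    return df


class TestScoreTableIO:
    def test_single_row_and_header(self, tmp_path):
        table = _score_table([("c1", "d1", 0.1, 0.2, 0.15)])
        path = tmp_path / "scores.tsv"
        write_scores(table, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].split("\t") == SCORE_COLUMNS

    def test_equal_means_break_ties_on_ids(self, tmp_path):
        table = _score_table(
            [("c2", "d1", 0.1, 0.2, 0.15), ("c1", "d2", 0.2, 0.1, 0.15)]
        )
        path = tmp_path / "scores.tsv"
        write_scores(table, path)
        back = read_scores(path)
        assert list(back["drug_id"]) == ["c1", "c2"]

    def test_probabilities_round_trip_at_10_significant_digits(self, tmp_path):
        table = _score_table([("c1", "d1", 0.010013127, 0.0027618815, 0.006387504)])
        path = tmp_path / "scores.tsv"
        write_scores(table, path)
        back = read_scores(path)
        assert back.loc[0, "drug_centric_prob"] == 0.010013127
        assert back.loc[0, "disease_centric_prob"] == 0.0027618815
        assert back.loc[0, "mean_prob"] == 0.006387504

    def test_empty_table_is_refused(self):
        with pytest.raises(ValueError, match="empty"):
            write_scores(_score_table([]), "/dev/null")

    def test_matrix_corner_label_cannot_be_dot(self, tmp_path):
        with pytest.raises(ValueError, match="corner"):
            write_matrix(("a",), np.eye(1), tmp_path / "m.tsv", corner=".")


class TestSimulateFixture:
    ARGS = dict(
        n_drugs=10,
        n_diseases=10,
        n_blocks=2,
        within_density=0.6,
        between_density=0.05,
        fp_bits=64,
        fp_flip_rate=0.1,
    )

    def test_identical_seed_gives_bitwise_identical_output(self):
        a = simulate_fixture(seed=7, **self.ARGS)
        b = simulate_fixture(seed=7, **self.ARGS)
        assert np.array_equal(a[0].adjacency, b[0].adjacency)
        assert np.array_equal(a[1].values, b[1].values)
        assert np.array_equal(a[2].values, b[2].values)

    def test_different_seed_changes_output(self):
        a = simulate_fixture(seed=7, **self.ARGS)
        b = simulate_fixture(seed=8, **self.ARGS)
        assert not np.array_equal(a[0].adjacency, b[0].adjacency)

    def test_degenerate_densities_give_exact_block_diagonal(self):
        net, _, _ = simulate_fixture(10, 10, 2, 1.0, 0.0, 16, 0.1, seed=1)
        expected = np.zeros((10, 10))
        expected[:5, :5] = 1
        expected[5:, 5:] = 1
        assert np.array_equal(net.adjacency, expected)

    def test_within_block_edge_rate_is_binomial(self):
        # empirical within-block rate within 3 binomial standard deviations
        net, _, _ = simulate_fixture(40, 30, 3, 0.5, 0.02, 128, 0.05, seed=11)
        drug_blocks = np.repeat([0, 1, 2], [13, 13, 14])
        disease_blocks = np.repeat([0, 1, 2], [10, 10, 10])
        within = drug_blocks[:, None] == disease_blocks[None, :]
        n_within = int(within.sum())
        observed = int(net.adjacency[within].sum())
        sd = np.sqrt(n_within * 0.5 * 0.5)
        assert abs(observed - 0.5 * n_within) <= 3 * sd

    def test_within_block_jaccard_exceeds_between_over_seeds(self):
        from repowalk import jaccard_similarity

        for seed in range(20):
            net, fp, _ = simulate_fixture(12, 12, 2, 0.5, 0.05, 64, 0.2, seed=seed)
            w = jaccard_similarity(fp).values
            blocks = np.repeat([0, 1], 6)
            same = blocks[:, None] == blocks[None, :]
            np.fill_diagonal(same, False)
            assert w[same].mean() > w[~same & ~np.eye(12, dtype=bool)].mean()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_blocks=11),
            dict(within_density=1.5),
            dict(between_density=-0.1),
            dict(within_density=0.1, between_density=0.5),
            dict(fp_flip_rate=2.0),
            dict(fp_bits=0),
        ],
    )
    def test_out_of_range_parameters_raise(self, bad):
        args = {**self.ARGS, **bad}
        with pytest.raises(ValueError):
            simulate_fixture(seed=0, **args)


class TestDomainTypes:
    def test_adjacency_must_be_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            AssociationNetwork(("c1",), ("d1",), np.array([[2]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AssociationNetwork(("c1", "c1"), ("d1",), np.ones((2, 1)))

    def test_feature_kind_constraints(self):
        with pytest.raises(ValueError):
            FeatureMatrix(("c1",), np.array([[0.5]]), "fingerprint")
        with pytest.raises(ValueError):
            FeatureMatrix(("d1",), np.array([[-1.0]]), "concept")

    def test_similarity_symmetry_flag_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(("a", "b"), np.array([[0, 0.5], [0.2, 0]]), symmetric=True)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("lambda_jump", 1.5),
            ("alpha_restart", 0.0),
            ("eta_tradeoff", -0.1),
            ("epsilon", 0.0),
            ("max_iter", 0),
        ],
    )
    def test_walk_config_ranges(self, field, value):
        with pytest.raises(ValueError):
            WalkConfig(**{field: value})

    def test_walk_config_defaults_match_reference_setting(self):
        cfg = WalkConfig()
        assert (cfg.lambda_jump, cfg.alpha_restart, cfg.eta_tradeoff) == (0.8, 0.3, 0.4)
        assert cfg.epsilon == 1.0e-10
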