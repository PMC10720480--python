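"""Benchmark loaders, label transforms and split schemes."""

import json

import numpy as np
import pytest

from kcdta.data_io import (DTARecord, load_csv_dataset, load_deepdta_dataset,
                           load_fasta, make_splits, pkd_transform,
                           save_csv_dataset)


class TestPkdTransform:
    @pytest.mark.parametrize("kd,expected", [
        (1e9, 0.0),
        (10000, 5.0),   # the benchmark's non-binder fill value
        (1, 9.0),
    ])
    def test_closed_form(self, kd, expected):
        assert pkd_transform(kd) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ValueError, match="positive"):
            pkd_transform(bad)


def _write_deepdta_dir(root, name="davis", with_folds=False):
    (root / "ligands_can.txt").write_text(json.dumps(
        {"drugA": "CCO", "drugB": "c1ccccc1"}))
    (root / "proteins.txt").write_text(json.dumps(
        {"prot1": "MKVLFACDAG", "prot2": "AAAAHWKLMV"}))
    matrix = np.array([[10000.0, 100.0], [np.nan, 1.0]])
    (root / "Y.txt").write_text("\n".join(
        " ".join(str(v) for v in row) for row in matrix))
    if with_folds:
        (root / "train_fold_setting1.txt").write_text(json.dumps([[0], [1]]))
        (root / "test_fold_setting1.txt").write_text(json.dumps([2]))
    return matrix


class TestDeepDtaLoader:
    def test_missing_cells_are_skipped(self, tmp_path):
        _write_deepdta_dir(tmp_path)
        records, folds = load_deepdta_dataset(tmp_path, "davis")
        assert len(records) == 3  # one NaN cell excluded
        assert folds is None

    def test_davis_labels_are_pkd_transformed(self, tmp_path):
        _write_deepdta_dir(tmp_path)
        records, _ = load_deepdta_dataset(tmp_path, "davis")
        by_pair = {(r.molecule_id, r.protein_id): r.affinity for r in records}
        assert by_pair[("drugA", "prot1")] == pytest.approx(5.0)
        assert by_pair[("drugB", "prot2")] == pytest.approx(9.0)

    def test_kiba_labels_pass_through(self, tmp_path):
        _write_deepdta_dir(tmp_path)
        records, _ = load_deepdta_dataset(tmp_path, "kiba")
        by_pair = {(r.molecule_id, r.protein_id): r.affinity for r in records}
        assert by_pair[("drugA", "prot1")] == 10000.0

    def test_record_order_is_row_major(self, tmp_path):
        """Fold index files index non-missing cells in row-major order."""
        _write_deepdta_dir(tmp_path)
        records, _ = load_deepdta_dataset(tmp_path, "davis")
        assert [(r.molecule_id, r.protein_id) for r in records] == [
            ("drugA", "prot1"), ("drugA", "prot2"), ("drugB", "prot2")]

    def test_published_folds_are_loaded(self, tmp_path):
        _write_deepdta_dir(tmp_path, with_folds=True)
        _, folds = load_deepdta_dataset(tmp_path, "davis")
        assert [list(f) for f in folds["train"]] == [[0], [1]]
        assert list(folds["test"]) == [2]

    def test_missing_file_error_names_candidates(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="ligands"):
            load_deepdta_dataset(tmp_path, "davis")

    def test_shape_mismatch_rejected(self, tmp_path):
        _write_deepdta_dir(tmp_path)
        (tmp_path / "Y.txt").write_text("1.0 2.0 3.0\n4.0 5.0 6.0")
        with pytest.raises(ValueError, match="does not match"):
            load_deepdta_dataset(tmp_path, "davis")

    def test_unknown_dataset_name(self, tmp_path):
        with pytest.raises(ValueError, match="davis"):
            load_deepdta_dataset(tmp_path, "metz")


class TestCsvLoader:
    def _write(self, path, rows, header="smiles,sequence,affinity"):
        path.write_text(header + "\n" + "\n".join(rows) + "\n")

    def test_well_formed_rows(self, tmp_path):
        path = tmp_path / "data.csv"
        self._write(path, [f"CCO,MKVLF,{5 + i}" for i in range(5)])
        assert len(load_csv_dataset(path)) == 5

    def test_invalid_smiles_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "data.csv"
        self._write(path, ["CCO,MKVLF,5", "xx[zz,MKVLF,6", "CC,AAAA,7",
                           "c1ccccc1,HWKL,8", "CCC,MMMM,9"])
        with caplog.at_level("WARNING", logger="kcdta"):
            records = load_csv_dataset(path)
        assert len(records) == 4
        assert "1 rows" in caplog.text

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_csv_dataset(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "data.csv"
        self._write(path, ["CCO,5"], header="smiles,affinity")
        with pytest.raises(ValueError, match="sequence"):
            load_csv_dataset(path)

    def test_round_trip(self, tmp_path, tiny_records):
        records, _ = tiny_records
        path = tmp_path / "roundtrip.csv"
        save_csv_dataset(records, path)
        reloaded = load_csv_dataset(path, source="synthetic")
        assert reloaded == records


class TestFasta:
    def test_multi_record(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        path.write_text(">p1 desc\nMKVLF\nACDAG\n>p2\nAAAA\n")
        seqs = load_fasta(path)
        assert seqs == {"p1": "MKVLFACDAG", "p2": "AAAA"}


def _records(n, years=None):
    return [DTARecord(molecule_id=f"m{i}", smiles="CCO", protein_id=f"p{i}",
                      sequence="MKVLF", affinity=5.0,
                      year=None if years is None else years[i])
            for i in range(n)]


class TestMakeSplits:
    def test_deepdta_cv_equal_partition(self):
        plan = make_splits(_records(600), "deepdta_cv", seed=0)
        assert len(plan.cv_folds) == 5
        assert plan.test_indices.size == 100
        assert all(f.size == 100 for f in plan.cv_folds)
        np.testing.assert_array_equal(plan.all_indices(), np.arange(600))

    def test_partition_with_remainder(self):
        plan = make_splits(_records(101), "deepdta_cv", seed=1)
        sizes = [plan.test_indices.size] + [f.size for f in plan.cv_folds]
        assert max(sizes) - min(sizes) <= 1
        np.testing.assert_array_equal(plan.all_indices(), np.arange(101))

    def test_random_ratio_is_4_to_1_and_deterministic(self):
        a = make_splits(_records(100), "random_ratio", seed=1)
        b = make_splits(_records(100), "random_ratio", seed=1)
        assert a.test_indices.size == 20 and a.train_indices.size == 80
        np.testing.assert_array_equal(a.test_indices, b.test_indices)
        c = make_splits(_records(100), "random_ratio", seed=2)
        assert not np.array_equal(a.test_indices, c.test_indices)

    def test_temporal_cutoffs(self):
        years = [2010, 2011, 2012, 2013, 2015, 2011]
        plan = make_splits(_records(6, years), "temporal")
        assert sorted(plan.train_indices) == [0, 1, 5]
        assert sorted(plan.val_indices) == [2]
        assert sorted(plan.test_indices) == [3, 4]

    def test_temporal_requires_years(self):
        with pytest.raises(ValueError, match="year"):
            make_splits(_records(4), "temporal")

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            make_splits(_records(4), "bootstrap")

    def test_published_folds_used_verbatim(self):
        published = {"train": [[0, 1], [2, 3]], "test": [4, 5]}
        plan = make_splits(_records(6), "deepdta_cv", published_folds=published)
        assert [list(f) for f in plan.cv_folds] == [[0, 1], [2, 3]]
        assert list(plan.test_indices) == [4, 5]


class TestDTARecord:
    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="sequence"):
            DTARecord("m", "C", "p", "", 5.0)

    def test_non_finite_affinity_rejected(self):
        with pytest.raises(ValueError, match="affinity"):
            DTARecord("m", "C", "p", "MKV", float("nan"))
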