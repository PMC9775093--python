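"""Container invariants and round-trips of the on-disk formats."""

import numpy as np
import pandas as pd
import pytest

import omicsgraphnet as og
from omicsgraphnet import io


def _write(path, text):
    path.write_text(text)
    return path


class TestReadOmicsMatrix:
    def test_methylation_round_trip(self, tmp_path):
        m = og.OmicsMatrix(
            [[0.1, 0.9], [0.5, 0.4], [0.2, 0.8]],
            ["s1", "s2", "s3"],
            ["cg001", "cg002"],
            "methylation",
        )
        io.write_omics_matrix(m, tmp_path / "m.tsv")
        back = io.read_omics_matrix(tmp_path / "m.tsv", "methylation")
        assert back.sample_ids == m.sample_ids
        assert back.feature_ids == m.feature_ids
        assert np.array_equal(back.values, m.values)
        assert back.omics_kind is og.OmicsKind.METHYLATION

    def test_duplicate_feature_id_errors(self, tmp_path):
        p = _write(
            tmp_path / "dup.tsv",
            "sample_id\tcg001\tcg001\ns1\t0.1\t0.2\n",
        )
        with pytest.raises(ValueError, match="cg001"):
            io.read_omics_matrix(p, "methylation")

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = _write(
            tmp_path / "bad.tsv",
            "sample_id\tg1\tg2\ns1\t1.0\toops\ns2\t2.0\t3.0\n",
        )
        with pytest.raises(ValueError, match="s1.*g2"):
            io.read_omics_matrix(p, "expression")

    def test_beta_out_of_range_errors(self, tmp_path):
        p = _write(
            tmp_path / "beta.tsv", "sample_id\tcg1\ns1\t0.5\ns2\t1.5\n"
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            io.read_omics_matrix(p, "methylation")

    def test_missing_value_errors_then_imputes_column_mean(self, tmp_path):
        p = _write(
            tmp_path / "na.tsv",
            "sample_id\tg1\tg2\ns1\t1.0\t4.0\ns2\tNA\t6.0\ns3\t3.0\t8.0\n",
        )
        with pytest.raises(ValueError, match="missing value"):
            io.read_omics_matrix(p, "expression")
        m = io.read_omics_matrix(p, "expression", impute_missing=True)
        # column mean of observed g1 values: (1.0 + 3.0) / 2
        assert m.values[1, 0] == pytest.approx(2.0)
        assert np.array_equal(m.values[:, 1], [4.0, 6.0, 8.0])

    def test_transpose_flag_reads_genes_as_rows(self, tmp_path):
        p = _write(
            tmp_path / "t.csv",
            "gene,s1,s2\ng1,1,2\ng2,3,4\n",
        )
        m = io.read_omics_matrix(p, "expression", transpose=True)
        assert m.sample_ids == ["s1", "s2"]
        assert m.feature_ids == ["g1", "g2"]
        assert np.array_equal(m.values, [[1.0, 3.0], [2.0, 4.0]])


class TestAlignCohort:
    def _mk(self, ids, p=2, kind="expression", seed=0):
        rng = np.random.default_rng(seed)
        return og.OmicsMatrix(
            rng.random((len(ids), p)), ids, [f"f{j}" for j in range(p)], kind
        )

    def test_intersection_and_drop_report(self):
        m1 = self._mk(["s1", "s2", "s3"])
        m2 = self._mk(["s2", "s1", "s4"], seed=1)
        labels = og.LabelVector(["s1", "s2", "s3", "s4"], [1, 0, 1, 0])
        bundle = og.align_cohort([m1, m2], labels)
        assert bundle.sample_ids == ["s1", "s2"]
        assert sorted(bundle.dropped_samples) == ["s3", "s4"]
        assert all(m.sample_ids == ["s1", "s2"] for m in bundle.matrices)

    def test_identical_sets_keep_first_matrix_order(self):
        m1 = self._mk(["s2", "s1"])
        m2 = self._mk(["s1", "s2"], seed=1)
        labels = og.LabelVector(["s1", "s2"], [1, 0])
        bundle = og.align_cohort([m1, m2], labels)
        assert bundle.sample_ids == ["s2", "s1"]
        assert bundle.dropped_samples == []

    def test_disjoint_sets_error(self):
        m1 = self._mk(["s1"])
        m2 = self._mk(["s2"], seed=1)
        labels = og.LabelVector(["s1", "s2"], [1, 0])
        with pytest.raises(ValueError, match="intersection"):
            og.align_cohort([m1, m2], labels)

    def test_idempotent(self):
        m1 = self._mk(["s1", "s2", "s3"])
        m2 = self._mk(["s3", "s2"], seed=1)
        labels = og.LabelVector(["s2", "s3"], [1, 0])
        once = og.align_cohort([m1, m2], labels)
        twice = og.align_cohort(once.matrices, once.labels)
        assert twice.sample_ids == once.sample_ids
        assert twice.dropped_samples == []
        for a, b in zip(once.matrices, twice.matrices):
            assert np.array_equal(a.values, b.values)


class TestMetricsReportIO:
    def _report(self):
        return og.MetricsReport(
            sensitivity=0.9,
            specificity=0.8,
            accuracy=0.85,
            precision=0.818,
            auc_roc=0.93,
            macro_f1=0.849,
            weighted_f1=0.849,
            confusion=og.ConfusionCounts(9, 2, 8, 1),
            metadata={"seed": 3},
        )

    def test_round_trip_and_byte_determinism(self, tmp_path):
        r = self._report()
        io.write_metrics_report(r, tmp_path / "a.json")
        io.write_metrics_report(r, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (
            tmp_path / "b.json"
        ).read_bytes()
        back = io.read_metrics_report(tmp_path / "a.json")
        assert back.as_dict() == r.as_dict()

    def test_confusion_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            og.MetricsReport(
                sensitivity=1.0,
                specificity=1.0,
                accuracy=1.0,
                precision=1.0,
                auc_roc=1.0,
                macro_f1=1.0,
                weighted_f1=1.0,
                confusion=og.ConfusionCounts(1, 0, 1, 0),
                n_samples=5,
            )


class TestTables:
    def test_variant_table_round_trip_and_validation(self, tmp_path):
        vt = og.VariantTable(
            pd.DataFrame(
                [
                    ("s1", "EGFR", "SNV", "L858R"),
                    ("s1", "ALK", "fusion", "EML4-ALK"),
                ],
                columns=["sample_id", "gene", "alteration", "detail"],
            )
        )
        io.write_variant_table(vt, tmp_path / "v.tsv")
        back = io.read_variant_table(tmp_path / "v.tsv")
        assert back.records.equals(vt.records)
        with pytest.raises(ValueError, match="alteration"):
            og.VariantTable(
                pd.DataFrame(
                    [("s1", "EGFR", "bogus", "")],
                    columns=["sample_id", "gene", "alteration", "detail"],
                )
            )

    def test_therapy_rules_unique_pairs(self):
        with pytest.raises(ValueError, match="duplicate"):
            og.TherapyRuleTable(
                pd.DataFrame(
                    [("EGFR", "SNV", "a"), ("EGFR", "SNV", "b")],
                    columns=["gene", "alteration_pattern", "agent"],
                )
            )

    def test_labels_validation(self):
        with pytest.raises(ValueError, match="0/1"):
            og.LabelVector(["s1", "s2"], [0, 2])
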