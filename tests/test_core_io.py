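import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtol import (
    CtRecord,
    LatencyRecord,
    RunConfig,
    SampleDesign,
    TargetPrediction,
    aggregate_sites,
    read_ct,
    read_expression,
    read_latencies,
    read_predictions,
)
from mirtol.core_io import (
    build_id_index,
    write_ct,
    write_latencies,
    write_predictions,
)


def _write_design(path, sample_ids, treatments, strains):
    pd.DataFrame(
        {
            "sample_id": sample_ids,
            "treatment": treatments,
            "strain": strains,
            "replicate": list(range(1, len(sample_ids) + 1)),
        }
    ).to_csv(path, sep="\t", index=False)


class TestReadExpression:
    def test_shape_and_column_alignment(self, tmp_path):
        mat = tmp_path / "m.tsv"
        des = tmp_path / "d.tsv"
        # design order differs from file column order: columns must realign
        mat.write_text(
            "feature_id\ts2\ts1\ts3\ts4\n"
            "f1\t1.0\t2.0\t3.0\t4.0\n"
            "f2\t5.0\t6.0\t7.0\t8.0\n"
            "f3\t9.0\t10.0\t11.0\t12.0\n"
        )
        _write_design(des, ["s1", "s2", "s3", "s4"],
                      ["saline", "saline", "morphine", "morphine"],
                      ["b6"] * 4)
        matrix, design = read_expression(mat, des)
        assert matrix.shape == (3, 4)
        assert list(matrix.sample_ids) == ["s1", "s2", "s3", "s4"]
        assert matrix.values[0].tolist() == [2.0, 1.0, 3.0, 4.0]

    def test_duplicate_sample_column_rejected(self, tmp_path):
        mat = tmp_path / "m.tsv"
        des = tmp_path / "d.tsv"
        mat.write_text("feature_id\ts1\ts1\nf1\t1.0\t2.0\n")
        _write_design(des, ["s1"], ["saline"], ["b6"])
        with pytest.raises(ValueError, match="duplicated sample"):
            read_expression(mat, des)

    def test_unmatched_sample_is_hard_error(self, tmp_path):
        mat = tmp_path / "m.tsv"
        des = tmp_path / "d.tsv"
        mat.write_text("feature_id\ts1\tsX\nf1\t1.0\t2.0\n")
        _write_design(des, ["s1"], ["saline"], ["b6"])
        with pytest.raises(ValueError, match="sX"):
            read_expression(mat, des)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        mat = tmp_path / "m.tsv"
        des = tmp_path / "d.tsv"
        mat.write_text("feature_id\ts1\ts2\nf1\t1.0\toops\n")
        _write_design(des, ["s1", "s2"], ["saline", "morphine"], ["b6", "b6"])
        with pytest.raises(ValueError, match="f1.*s2"):
            read_expression(mat, des)

    def test_duplicate_feature_ids_allowed(self, tmp_path):
        # distinct probes may share a miRNA name (e.g. star/mature forms
        # reported in both directions)
        mat = tmp_path / "m.tsv"
        des = tmp_path / "d.tsv"
        mat.write_text("feature_id\ts1\ts2\nmiR-29b\t1.0\t2.0\nmiR-29b\t3.0\t4.0\n")
        _write_design(des, ["s1", "s2"], ["saline", "morphine"], ["b6", "b6"])
        matrix, _ = read_expression(mat, des)
        assert list(matrix.feature_ids) == ["miR-29b", "miR-29b"]


class TestPredictions:
    def test_two_sites_sum_to_combined_score(self, tmp_path):
        # two predicted sites on one 3'-UTR combine by summing mirSVR
        p = tmp_path / "p.tsv"
        p.write_text(
            "mirna_id\tmrna_id\tmirsvr\n"
            "miR-27a\tSerpini1\t-1.0\n"
            "miR-27a\tSerpini1\t-0.9\n"
        )
        preds = read_predictions(p)
        assert len(preds) == 1
        assert preds[0].mirsvr == pytest.approx(-1.9)

    def test_single_row_passes_through(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("mirna_id\tmrna_id\tmirsvr\tphastcons\nmiR-9\tSerpini1\t-0.7\t0.8\n")
        (pred,) = read_predictions(p)
        assert pred == TargetPrediction("miR-9", "Serpini1", -0.7, 0.8)

    def test_empty_file_returns_empty_list(self, tmp_path, caplog):
        p = tmp_path / "p.tsv"
        p.write_text("mirna_id\tmrna_id\tmirsvr\n")
        with caplog.at_level("WARNING", logger="mirtol"):
            assert read_predictions(p) == []
        assert "empty" in caplog.text

    def test_positive_mirsvr_kept_with_warning(self, tmp_path, caplog):
        p = tmp_path / "p.tsv"
        p.write_text("mirna_id\tmrna_id\tmirsvr\nmiR-1\tGeneA\t0.2\n")
        with caplog.at_level("WARNING", logger="mirtol"):
            preds = read_predictions(p)
        assert preds[0].mirsvr == 0.2
        assert "positive mirSVR" in caplog.text

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["miR-a", "miR-b"]),
                st.sampled_from(["g1", "g2", "g3"]),
                st.floats(-2.0, -0.01, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_aggregation_sums_per_pair(self, rows):
        preds = [TargetPrediction(m, g, s) for m, g, s in rows]
        combined = aggregate_sites(preds)
        keys = [(p.mirna_id, p.mrna_id) for p in combined]
        assert len(keys) == len(set(keys))  # exactly one record per pair
        for p in combined:
            expected = sum(s for m, g, s in rows if (m, g) == (p.mirna_id, p.mrna_id))
            assert p.mirsvr == pytest.approx(expected, abs=1e-12)


class TestRoundTrips:
    def test_latency_round_trip(self, tmp_path):
        records = [
            LatencyRecord("a1", "b6", "saline", 1, 6.4),
            LatencyRecord("a1", "b6", "saline", 2, 7.6),
            LatencyRecord("a2", "b6", "morphine", 1, 25.0),
        ]
        path = tmp_path / "lat.tsv"
        write_latencies(records, path, RunConfig())
        assert read_latencies(path) == records

    def test_ct_round_trip(self, tmp_path):
        records = [
            CtRecord("s1", "U6", 20.0, "control", True),
            CtRecord("s1", "miR-27a", 24.5, "control", False),
        ]
        path = tmp_path / "ct.tsv"
        write_ct(records, path)
        assert read_ct(path) == records

    def test_prediction_round_trip(self, tmp_path):
        records = [
            TargetPrediction("miR-27a", "Serpini1", -1.9421, 0.77),
            TargetPrediction("miR-505", "Sap25", -1.2974, None),
        ]
        path = tmp_path / "p.tsv"
        write_predictions(records, path)
        assert read_predictions(path) == records

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(fdr_q=0.05, mirsvr_cutoff=-0.2, rng_seed=42, universe="predicted")
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg
        assert RunConfig.from_yaml(path).config_hash == cfg.config_hash


class TestValidation:
    def test_ct_requires_reference_per_sample(self, tmp_path):
        path = tmp_path / "ct.tsv"
        write_ct([CtRecord("s1", "miR-27a", 24.0, "control", False),
                  CtRecord("s2", "U6", 20.0, "control", True),
                  CtRecord("s2", "miR-27a", 23.0, "control", False)],
                 tmp_path / "raw.tsv")
        (tmp_path / "raw.tsv").rename(path)
        with pytest.raises(ValueError, match="s1"):
            read_ct(path)

    def test_non_contiguous_injections_rejected(self, tmp_path):
        path = tmp_path / "lat.tsv"
        pd.DataFrame(
            {
                "animal_id": ["a1", "a1"],
                "genotype": ["b6", "b6"],
                "treatment": ["saline", "saline"],
                "injection_number": [1, 3],
                "latency_s": [6.0, 7.0],
            }
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="contiguous"):
            read_latencies(path)

    def test_design_rejects_duplicates_and_bad_treatment(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleDesign(pd.DataFrame({
                "sample_id": ["s1", "s1"], "treatment": ["saline", "saline"],
                "strain": ["b6", "b6"], "replicate": [1, 2]}))
        with pytest.raises(ValueError, match="treatment"):
            SampleDesign(pd.DataFrame({
                "sample_id": ["s1"], "treatment": ["vehicle"],
                "strain": ["b6"], "replicate": [1]}))

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(fdr_q=1.5)
        with pytest.raises(ValueError):
            RunConfig(cutoff_factor=1.0)
        with pytest.raises(ValueError):
            RunConfig(phastcons_cutoff=2.0)

    def test_case_insensitive_index_warns_on_conflict(self, caplog):
        with caplog.at_level("WARNING", logger="mirtol"):
            idx = build_id_index(["Serpini1", "SERPINI1", "Dicer1"])
        assert idx["serpini1"] == "Serpini1"
        assert "case conflict" in caplog.text
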