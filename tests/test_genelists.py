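import json

import pytest

from ragscore import (
    AliasMap,
    Call,
    Cohort,
    ConditionLabel,
    ContradictionError,
    Corpus,
    DatasetRecord,
    GeneCall,
    GenelistError,
    StudyMetadata,
    collapse_by_study,
    harmonize_corpus,
    harmonize_symbols,
    load_fixture_tables,
    parse_comparison,
    read_corpus,
    read_genelist,
    write_corpus,
)
from ragscore import genelists

from helpers import make_corpus, make_dataset


META = StudyMetadata(study_id="S1", sample_size=10)


def write_list(tmp_path, body, name="list.tsv"):
    p = tmp_path / name
    p.write_text(body, encoding="utf-8")
    return p


class TestConditionLabel:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("receptive", "receptive"),
            ("Mid-Secretory", "receptive"),
            ("LH+7", "receptive"),
            ("LH+2", "pre_receptive"),
            ("early secretory", "pre_receptive"),
            ("pre-receptive", "pre_receptive"),
            ("proliferative", "proliferative"),
        ],
    )
    def test_default_map(self, raw, expected):
        assert ConditionLabel.from_raw(raw).canonical == expected

    def test_unmapped_label_is_tagged_not_dropped(self):
        lbl = ConditionLabel.from_raw("day 21 biopsy")
        assert lbl.canonical == "other(day 21 biopsy)"
        assert lbl.raw_label == "day 21 biopsy"

    def test_user_override(self):
        lbl = ConditionLabel.from_raw("day 21 biopsy", {"day 21 biopsy": "receptive"})
        assert lbl.canonical == "receptive"

    def test_canonicalization_deterministic(self):
        assert ConditionLabel.from_raw("LH+7") == ConditionLabel.from_raw("LH+7")


class TestParseComparison:
    def test_string_form(self):
        comp = parse_comparison("receptive_vs_pre_receptive")
        assert comp[0].canonical == "receptive"
        assert comp[1].canonical == "pre_receptive"

    def test_identical_members_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            parse_comparison("receptive_vs_mid-secretory")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_comparison("receptive")


class TestStudyMetadata:
    def test_invalid_sample_size(self):
        with pytest.raises(ValueError, match="sample_size"):
            StudyMetadata(study_id="S", sample_size=0)

    def test_negative_hybridizations(self):
        with pytest.raises(ValueError, match="n_hybridizations"):
            StudyMetadata(study_id="S", n_hybridizations=-1)

    def test_cohort_is_explicit_enum(self):
        assert StudyMetadata(study_id="S").cohort is Cohort.HEALTHY
        assert StudyMetadata(study_id="S", cohort="ivf_failure").cohort is Cohort.IVF_FAILURE
        with pytest.raises(ValueError):
            StudyMetadata(study_id="S", cohort="sick")


class TestGeneCallInvariants:
    def test_status_call_needs_condition(self):
        with pytest.raises(ValueError, match="exactly one condition"):
            GeneCall(symbol="A", call=Call.EXPRESSED, source_dataset="D")

    def test_pattern_call_needs_comparison(self):
        with pytest.raises(ValueError, match="ordered condition pair"):
            GeneCall(symbol="A", call=Call.UP, source_dataset="D")

    def test_dataset_rejects_contradiction(self):
        with pytest.raises(ContradictionError):
            make_dataset("D1", [("A", Call.EXPRESSED), ("A", Call.NOT_DETECTED)])
        with pytest.raises(ContradictionError):
            make_dataset("D1", [("A", Call.UP), ("A", Call.DOWN)])

    def test_reversed_orientations_are_distinct_keys(self):
        # up on A_vs_B and up on B_vs_A disagree but are distinct assertions
        ds = make_dataset("D1", [("A", Call.UP, "fwd"), ("A", Call.UP, "rev")])
        assert len(ds.calls) == 2


class TestReadGenelist:
    def test_basic_tsv(self, tmp_path):
        p = write_list(
            tmp_path,
            "symbol\tcall\n"
            "SPP1\texpressed\nGPX3\texpressed\nPAEP\texpressed\n"
            "IL15\texpressed\nLIF\texpressed\nSPP1\tup\n",
        )
        ds = read_genelist(p, META, condition="receptive",
                           comparison="receptive_vs_pre_receptive")
        assert ds.dataset_id == "list"
        assert len(ds.calls) == 6
        assert ds.symbols == {"SPP1", "GPX3", "PAEP", "IL15", "LIF"}

    def test_comma_autodetected(self, tmp_path):
        p = write_list(
            tmp_path,
            "symbol,call\nA,expressed\nB,expressed\nC,expressed\nD,expressed\nE,expressed\n",
            name="list.csv",
        )
        ds = read_genelist(p, META, condition="receptive")
        assert len(ds.calls) == 5

    def test_short_list_warns(self, tmp_path):
        p = write_list(tmp_path, "symbol\tcall\nA\texpressed\nB\texpressed\nC\texpressed\nD\texpressed\n")
        with pytest.warns(UserWarning, match="5-gene curation threshold"):
            ds = read_genelist(p, META, condition="receptive")
        assert len(ds.calls) == 4  # warning, not an error

    def test_empty_file_errors(self, tmp_path):
        p = write_list(tmp_path, "")
        with pytest.raises(GenelistError, match="no calls"):
            read_genelist(p, META, condition="receptive")

    def test_header_only_errors(self, tmp_path):
        p = write_list(tmp_path, "symbol\tcall\n")
        with pytest.raises(GenelistError, match="no calls"):
            read_genelist(p, META, condition="receptive")

    def test_duplicate_rows_collapse(self, tmp_path):
        p = write_list(tmp_path, "symbol\tcall\nSPP1\texpressed\nSPP1\texpressed\n")
        with pytest.warns(UserWarning):
            ds = read_genelist(p, META, condition="receptive")
        assert len(ds.calls) == 1

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        p = write_list(
            tmp_path,
            "symbol\tcall\nA\texpressed\n\texpressed\nB\tmaybe\n",
        )
        with pytest.raises(GenelistError) as exc:
            read_genelist(p, META, condition="receptive")
        lines = [ln for ln, _ in exc.value.row_errors]
        assert lines == [3, 4]
        assert "maybe" in str(exc.value)

    def test_contradictory_dataset_rejected(self, tmp_path):
        p = write_list(tmp_path, "symbol\tcall\nA\texpressed\nA\tnot_detected\n")
        with pytest.raises(ContradictionError, match="A"):
            read_genelist(p, META, condition="receptive")

    def test_missing_required_column(self, tmp_path):
        p = write_list(tmp_path, "gene\tstate\nA\texpressed\n")
        with pytest.raises(GenelistError, match="symbol"):
            read_genelist(p, META, condition="receptive")

    def test_per_row_condition_and_comparison(self, tmp_path):
        p = write_list(
            tmp_path,
            "symbol\tcall\tcondition\tcomparison\n"
            "A\texpressed\tLH+7\t\n"
            "A\tup\t\treceptive_vs_pre_receptive\n",
        )
        with pytest.warns(UserWarning):
            ds = read_genelist(p, META)
        status = next(c for c in ds.calls if c.call.is_status)
        pattern = next(c for c in ds.calls if c.call.is_pattern)
        assert status.condition.canonical == "receptive"
        assert pattern.comparison[0].canonical == "receptive"

    def test_status_without_any_condition_is_row_error(self, tmp_path):
        p = write_list(tmp_path, "symbol\tcall\nA\texpressed\n")
        with pytest.raises(GenelistError, match="without a condition"):
            read_genelist(p, META)


class TestAliasMap:
    def test_conflicting_alias_rejected(self):
        with pytest.raises(ValueError, match="maps to both"):
            AliasMap({"OPN": "SPP1", "opn": "GPX3"})

    def test_canonical_is_fixed_point(self):
        am = AliasMap({"OPN": "SPP1"})
        assert am.resolve("SPP1") == "SPP1"
        assert am.resolve("opn ") == "SPP1"

    def test_unknown_passes_through_normalized(self):
        assert AliasMap().resolve("  brca1 ") == "BRCA1"


class TestHarmonize:
    def test_direct_lookup(self):
        ds = make_dataset("D1", [("OPN", Call.UP)])
        out = harmonize_symbols(ds, AliasMap({"OPN": "SPP1"}))
        assert out.calls[0].symbol == "SPP1"

    def test_empty_alias_map_unchanged(self):
        ds = make_dataset("D1", [("SPP1", Call.UP), ("GPX3", Call.EXPRESSED)])
        out = harmonize_symbols(ds, AliasMap())
        assert [c.symbol for c in out.calls] == ["SPP1", "GPX3"]

    def test_collision_drops_both_and_logs(self, caplog):
        ds = make_dataset("D1", [("A", Call.EXPRESSED), ("B", Call.NOT_DETECTED)])
        with caplog.at_level("WARNING", logger="ragscore.genelists"):
            out = harmonize_symbols(ds, AliasMap({"A": "G", "B": "G"}))
        assert out.calls == []
        assert "contradictory" in caplog.text

    def test_merge_to_same_call_collapses(self):
        ds = make_dataset("D1", [("A", Call.UP), ("B", Call.UP)])
        out = harmonize_symbols(ds, AliasMap({"A": "G", "B": "G"}))
        assert len(out.calls) == 1

    def test_idempotent(self):
        ds = make_dataset("D1", [("opn", Call.UP), ("gpx3", Call.EXPRESSED)])
        am = AliasMap({"OPN": "SPP1"})
        once = harmonize_symbols(ds, am)
        twice = harmonize_symbols(once, am)
        assert [c.symbol for c in once.calls] == [c.symbol for c in twice.calls]
        assert once.calls == twice.calls


class TestCorpus:
    def test_duplicate_dataset_ids_rejected(self):
        d = make_dataset("D1", [("A", Call.EXPRESSED)])
        with pytest.raises(ValueError, match="duplicate dataset ids"):
            Corpus(datasets=[d, d])

    def test_round_trip(self, tmp_path):
        corpus = make_corpus(
            make_dataset("D1", [("A", Call.EXPRESSED), ("A", Call.UP), ("B", Call.DOWN, "rev")]),
            make_dataset("D2", [("B", Call.NOT_DETECTED)], cohort=Cohort.IVF_FAILURE),
        )
        corpus.alias_map = AliasMap({"OPN": "SPP1"})
        path = tmp_path / "corpus.json"
        write_corpus(corpus, path)
        back = read_corpus(path)
        assert back.digest() == corpus.digest()
        for d1, d2 in zip(corpus.datasets, back.datasets):
            assert sorted(c.dedup_key() for c in d1.calls) == sorted(
                c.dedup_key() for c in d2.calls
            )
            assert d1.metadata == d2.metadata

    def test_schema_version_checked(self, tmp_path):
        path = tmp_path / "corpus.json"
        write_corpus(make_corpus(make_dataset("D1", [("A", Call.UP)])), path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = "99"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="schema version"):
            read_corpus(path)


class TestCollapseByStudy:
    def test_same_study_datasets_merge_by_union(self):
        corpus = make_corpus(
            make_dataset("D1", [("A", Call.EXPRESSED)], study_id="S1"),
            make_dataset("D2", [("A", Call.UP), ("B", Call.EXPRESSED)], study_id="S1"),
            make_dataset("D3", [("C", Call.DOWN)], study_id="S2"),
        )
        out = collapse_by_study(corpus)
        assert {d.dataset_id for d in out.datasets} == {"S1", "S2"}
        merged = next(d for d in out.datasets if d.dataset_id == "S1")
        assert merged.symbols == {"A", "B"}
        assert len(merged.calls) == 3

    def test_union_contradiction_dropped(self, caplog):
        corpus = make_corpus(
            make_dataset("D1", [("A", Call.EXPRESSED), ("B", Call.UP)], study_id="S1"),
            make_dataset("D2", [("A", Call.NOT_DETECTED)], study_id="S1"),
        )
        with caplog.at_level("WARNING", logger="ragscore.genelists"):
            out = collapse_by_study(corpus)
        merged = out.datasets[0]
        assert merged.symbols == {"B"}


class TestFixtureTables:
    def test_row_counts(self):
        res = load_fixture_tables()
        assert len(res.up_ex) == 151
        assert len(res.down_nd) == 28

    def test_every_row_is_additive_even_and_supported(self):
        res = load_fixture_tables()
        for entry in res.up_ex + res.down_nd:
            assert entry.cumulative == entry.pattern_score + entry.status_score
            assert entry.pattern_score % 2 == 0 and entry.status_score % 2 == 0
            assert entry.pattern_score >= 2 and entry.status_score >= 2

    def test_known_top_rows(self):
        res = load_fixture_tables()
        top = res.up_ex[0]
        assert (top.symbol, top.pattern_score, top.status_score, top.cumulative) == (
            "SPP1", 18, 12, 30,
        )
        assert res.up_ex[1].symbol == "GPX3" and res.up_ex[1].cumulative == 26
        assert res.down_nd[0].symbol == "E2F2" and res.down_nd[0].cumulative == 14

    def test_checksum_guard(self, monkeypatch):
        monkeypatch.setitem(
            genelists._FIXTURE_CHECKSUMS, "table_4_downnd.tsv", "0" * 64
        )
        with pytest.raises(ValueError, match="checksum mismatch"):
            load_fixture_tables()
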