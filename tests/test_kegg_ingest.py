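"""Compound/enzyme flat-file parsing and EC → metabolite summarization."""

import io
import logging

import pytest

from metnetweave import fixtures
from metnetweave.kegg_ingest import (
    ECMetaboliteMap,
    ECReactionRecord,
    FlatFileParseError,
    build_ec_metabolite_map,
    normalize_name,
    parse_compound_dictionary,
    parse_ec_reactions,
    read_reactions_slim,
    resolve_metabolite,
    split_equation,
    write_reactions_slim,
)

WATER_RECORD = """\
ENTRY       C00001                      Compound
NAME        H2O;
            Water
///
"""


class TestCompoundDictionary:
    def test_synonyms_map_to_code_after_normalization(self):
        mdict = parse_compound_dictionary(WATER_RECORD)
        assert mdict.entries == {"h2o": "C00001", "water": "C00001"}
        assert mdict.codes == {"C00001"}

    def test_empty_stream_gives_empty_dictionary(self):
        mdict = parse_compound_dictionary("")
        assert len(mdict) == 0 and not mdict.codes

    def test_record_without_name_contributes_only_code(self):
        mdict = parse_compound_dictionary("ENTRY       C00099\n///\n")
        assert mdict.codes == {"C00099"} and len(mdict) == 0

    def test_duplicate_synonym_first_code_wins_with_warning(self, caplog):
        text = (
            "ENTRY       C00022\nNAME        Pyruvate\n///\n"
            "ENTRY       C00033\nNAME        pyruvate\n///\n"
        )
        with caplog.at_level(logging.WARNING):
            mdict = parse_compound_dictionary(text)
        assert mdict.entries["pyruvate"] == "C00022"
        assert any("duplicate metabolite name" in r.message for r in caplog.records)

    def test_record_without_entry_is_parse_error_with_line(self):
        with pytest.raises(FlatFileParseError, match="line 1"):
            parse_compound_dictionary("NAME        Orphan\n///\n")

    def test_normalization_is_idempotent(self):
        for raw in ["  D-Glucose  6-P ", "WATER", "α-ketoglutarate"]:
            once = normalize_name(raw)
            assert normalize_name(once) == once

    def test_accepts_file_object(self):
        mdict = parse_compound_dictionary(io.StringIO(WATER_RECORD))
        assert mdict.entries["water"] == "C00001"


class TestResolveMetabolite:
    @pytest.fixture()
    def mdict(self):
        return parse_compound_dictionary(WATER_RECORD)

    def test_case_folded_lookup(self, mdict):
        assert resolve_metabolite("Water", mdict) == "C00001"

    def test_code_shaped_input_passes_through(self, mdict):
        assert resolve_metabolite("C00022", mdict) == "C00022"

    def test_miss_is_none_never_fabricated(self, mdict):
        assert resolve_metabolite("unobtainium", mdict) is None


class TestParseReactions:
    def test_compact_entry_splits_participants(self):
        records = parse_ec_reactions("EC 2.7.1.1 ; ATP + D-Glucose <=> ADP + D-Glucose-6P")
        assert len(records) == 1
        assert records[0].ec == "2.7.1.1"
        assert records[0].reactions == [["ATP", "D-Glucose", "ADP", "D-Glucose-6P"]]

    def test_two_reaction_lines_preserve_file_order(self):
        records = parse_ec_reactions("EC 1.1.1.1 ; A <=> B\nC <=> D")
        assert records[0].reactions == [["A", "B"], ["C", "D"]]

    def test_stoichiometric_coefficients_stripped(self):
        records = parse_ec_reactions("EC 1.11.1.6 ; 2 H2O2 <=> 2 H2O + O2")
        assert records[0].reactions == [["H2O2", "H2O", "O2"]]

    def test_flatfile_record_with_reaction_field(self):
        text = (
            "ENTRY       EC 2.7.1.1            Enzyme\n"
            "NAME        hexokinase\n"
            "REACTION    ATP + D-glucose = ADP + D-glucose 6-phosphate [RN:R00299]\n"
            "///\n"
        )
        records = parse_ec_reactions(text)
        assert records[0].ec == "2.7.1.1"
        assert records[0].reactions == [["ATP", "D-glucose", "ADP", "D-glucose 6-phosphate"]]

    def test_substrate_product_lists_pooled_when_no_equation(self):
        text = (
            "ENTRY       EC 1.1.1.27           Enzyme\n"
            "SUBSTRATE   (S)-lactate [CPD:C00186];\n"
            "            NAD+\n"
            "PRODUCT     pyruvate [CPD:C00022]\n"
            "///\n"
        )
        records = parse_ec_reactions(text)
        assert records[0].reactions == [["(S)-lactate", "NAD+", "pyruvate"]]

    def test_partial_ec_with_trailing_dash_accepted(self):
        records = parse_ec_reactions("EC 2.7.1.- ; A <=> B")
        assert records[0].ec == "2.7.1.-"

    def test_entry_without_ec_is_parse_error(self):
        with pytest.raises(FlatFileParseError):
            parse_ec_reactions("no identifier here ; A <=> B")

    def test_unparseable_equation_skipped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            records = parse_ec_reactions("EC 1.1.1.1 ; A <=> B\njust some words")
        assert records[0].reactions == [["A", "B"]]
        assert any("unparseable equation" in r.message for r in caplog.records)

    def test_split_equation_pools_and_dedupes(self):
        assert split_equation("A + B -> A") == ["A", "B"]
        assert split_equation("no arrow at all") is None


class TestBuildMap:
    @pytest.fixture()
    def records(self):
        return [ECReactionRecord("1.1.1.1", [["C00001", "C00002"], ["C00002", "C00003"]])]

    def test_union_mode_pools_all_reactions(self, records):
        ecmap = build_ec_metabolite_map(records, None, mode="union")
        assert ecmap.map == {"1.1.1.1": {"C00001", "C00002", "C00003"}}

    def test_main_mode_uses_first_reaction_only(self, records):
        ecmap = build_ec_metabolite_map(records, None, mode="main")
        assert ecmap.map == {"1.1.1.1": {"C00001", "C00002"}}

    def test_empty_records_give_empty_map(self):
        assert build_ec_metabolite_map([], None).map == {}

    def test_unresolvable_names_dropped_with_logged_count(self, caplog):
        records = [ECReactionRecord("1.1.1.1", [["C00001", "mystery"]])]
        mdict = parse_compound_dictionary(WATER_RECORD)
        with caplog.at_level(logging.WARNING):
            ecmap = build_ec_metabolite_map(records, mdict)
        assert ecmap.map == {"1.1.1.1": {"C00001"}}
        assert any("could not be resolved" in r.message for r in caplog.records)

    def test_ec_with_no_resolvable_metabolite_retained_empty(self):
        records = [ECReactionRecord("9.9.9.9", [])]
        assert build_ec_metabolite_map(records, None).map == {"9.9.9.9": set()}

    def test_duplicate_ec_merged_in_union_first_wins_in_main(self):
        records = [
            ECReactionRecord("1.1.1.1", [["C00001"]]),
            ECReactionRecord("1.1.1.1", [["C00002"]]),
        ]
        assert build_ec_metabolite_map(records, None, "union").map == {
            "1.1.1.1": {"C00001", "C00002"}
        }
        assert build_ec_metabolite_map(records, None, "main").map == {"1.1.1.1": {"C00001"}}

    @pytest.mark.parametrize("seed", range(5))
    def test_main_map_is_subset_of_union_map_ec_wise(self, seed):
        kegg = fixtures.generate_toy_kegg(10, 30, 2, 0.3, seed=seed)
        mdict = parse_compound_dictionary(kegg.compound_text)
        records = parse_ec_reactions(kegg.enzyme_text)
        union = build_ec_metabolite_map(records, mdict, "union")
        main = build_ec_metabolite_map(records, mdict, "main")
        for ec in union.map:
            assert main.map[ec] <= union.map[ec]


class TestReactionsSlimRoundTrip:
    def test_write_then_read_reproduces_map_exactly(self, tmp_path):
        ecmap = ECMetaboliteMap(
            map={"1.1.1.1": {"C00001", "C00003"}, "2.7.1.1": set(), "2.7.1.-": {"C00002"}}
        )
        path = tmp_path / "slim.tsv"
        write_reactions_slim(ecmap, path)
        with open(path) as fh:
            again = read_reactions_slim(fh)
        assert again.map == ecmap.map

    def test_bad_first_column_rejected(self):
        with pytest.raises(FlatFileParseError):
            read_reactions_slim(["notanec\tC00001"])


def test_fixture_generated_files_parse_with_zero_warnings(caplog):
    """The parsers are total on generator output: no skipped or unresolved items."""
    kegg = fixtures.generate_toy_kegg(15, 50, 3, 0.2, seed=11)
    with caplog.at_level(logging.WARNING):
        mdict = parse_compound_dictionary(kegg.compound_text)
        records = parse_ec_reactions(kegg.enzyme_text)
        ecmap = build_ec_metabolite_map(records, mdict, "union")
    assert not caplog.records
    assert ecmap.map == kegg.truth_map.map
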