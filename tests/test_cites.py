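"""CITES parsing, filtering, categorisation and source-class adjustment."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from lionmatch import (
    Override,
    TradeCategory,
    TradeRecord,
    adjust_records,
    adjust_source,
    categorize_trade,
    filter_records,
    read_cites_csv,
    reconcile_quantity,
    write_adjusted,
)
from lionmatch.cites import CitesSchemaError, ClassificationError

HEADER = (
    "Year,Taxon,Importer,Exporter,Origin,Importer reported quantity,"
    "Exporter reported quantity,Term,Unit,Purpose,Source"
)


def _csv(tmp_path, *rows, name="trade.csv"):
    p = tmp_path / name
    p.write_text("\n".join((HEADER,) + rows) + "\n")
    return p


def _rec(
    year=2000,
    importer="ZA",
    exporter="ZW",
    source="W",
    purpose="T",
    qty_i=1.0,
    qty_e=None,
    term="live",
    origin="",
):
    return TradeRecord(
        year=year,
        taxon="Panthera leo",
        importer=importer,
        exporter=exporter,
        origin=origin,
        qty_importer=qty_i,
        qty_exporter=qty_e,
        term=term,
        purpose=purpose,
        source=source,
    )


class TestReadCitesCsv:
    def test_happy_path_row_parsed(self, tmp_path):
        p = _csv(tmp_path, "1999,Panthera leo,ZA,ZW,,4,6,live,,T,C")
        res = read_cites_csv(p)
        assert len(res) == 1 and not res.problems
        r = res.records[0]
        assert (r.year, r.importer, r.exporter, r.source, r.purpose) == (1999, "ZA", "ZW", "C", "T")
        assert (r.qty_importer, r.qty_exporter) == (4.0, 6.0)

    def test_subspecies_spelling_parsed(self, tmp_path):
        p = _csv(tmp_path, "1999,Panthera leo persica,IN,IN,,1,,live,,N,W")
        assert read_cites_csv(p).records[0].taxon == "Panthera leo persica"

    def test_non_live_term_parsed_not_dropped(self, tmp_path):
        p = _csv(tmp_path, "1999,Panthera leo,ZA,ZW,,2,,trophies,,H,W")
        res = read_cites_csv(p)
        assert len(res) == 1 and res.records[0].term == "trophies"

    def test_malformed_year_reported_with_line_number(self, tmp_path):
        p = _csv(
            tmp_path,
            "1999,Panthera leo,ZA,ZW,,1,,live,,T,C",
            "199O,Panthera leo,ZA,ZW,,1,,live,,T,C",
        )
        res = read_cites_csv(p)
        assert len(res) == 1
        assert len(res.problems) == 1 and res.problems[0].startswith("line 3:")

    def test_unrecognised_header_raises_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(CitesSchemaError, match="missing"):
            read_cites_csv(p)


class TestReconcileQuantity:
    @pytest.mark.parametrize(
        "qi,qe,expected",
        [(4, 6, 6), (None, 2, 2), (2, None, 2), (0, 0, 0), (None, None, 0), (3.0, 3.0, 3)],
    )
    def test_max_rule(self, qi, qe, expected):
        assert reconcile_quantity(_rec(qty_i=qi, qty_e=qe)) == expected

    def test_exporter_preferred_rule(self):
        assert reconcile_quantity(_rec(qty_i=9, qty_e=2), rule="exporter") == 2

    @given(
        qi=st.one_of(st.none(), st.floats(0, 1e4)),
        qe=st.one_of(st.none(), st.floats(0, 1e4)),
    )
    @settings(max_examples=100, deadline=None)
    def test_max_rule_bounds_both_reports(self, qi, qe):
        q = reconcile_quantity(_rec(qty_i=qi, qty_e=qe))
        assert q >= (qi or 0) - 1e-6 and q >= (qe or 0) - 1e-6


class TestFilterRecords:
    RANGE = frozenset({"ZA", "ZW", "TZ", "KE"})

    def test_empty_input_empty_output(self):
        res = filter_records([], self.RANGE)
        assert res.kept == [] and res.excluded == {}

    @pytest.mark.parametrize(
        "rec,reason",
        [
            (_rec(importer="US"), "importer-not-range-state"),
            (_rec(purpose="Z"), "purpose-excluded"),
            (_rec(term="trophies"), "term-not-live"),
            (_rec(year=1979), "year-out-of-range"),
            (_rec(source="I"), "source-excluded"),
            (_rec(qty_i=0, qty_e=0), "zero-quantity"),
        ],
    )
    def test_each_filter_tallies_its_reason(self, rec, reason):
        res = filter_records([rec], self.RANGE)
        assert res.kept == [] and set(res.excluded) == {reason}

    def test_blank_source_kept(self):
        res = filter_records([_rec(source="")], self.RANGE)
        assert len(res.kept) == 1

    def test_individual_conservation_through_filtering(self):
        records = [
            _rec(qty_i=3),
            _rec(importer="US", qty_i=5),
            _rec(term="trophies", qty_i=2),
            _rec(purpose="Z", qty_i=7),
            _rec(qty_i=1),
        ]
        res = filter_records(records, self.RANGE)
        total_in = sum(reconcile_quantity(r) for r in records)
        assert total_in == res.individuals_kept() + res.individuals_excluded()


class TestCategorizeTrade:
    def test_exhaustive_domain(self):
        expected = {}
        for s in "WFR":
            expected[(s, "N")] = TradeCategory.WILD_REINTRO
            for p in "TBH":
                expected[(s, p)] = TradeCategory.WILD_COMMERCIAL
        expected[("C", "N")] = TradeCategory.CAPTIVE_REINTRO
        for p in "TBH":
            expected[("C", p)] = TradeCategory.CAPTIVE_COMMERCIAL
        assert len(expected) == 16
        for (s, p), cat in expected.items():
            assert categorize_trade(s, p) == cat

    @pytest.mark.parametrize("s,p", [("I", "T"), ("W", "Z"), ("", "N")])
    def test_out_of_domain_raises(self, s, p):
        with pytest.raises(ClassificationError):
            categorize_trade(s, p)


class TestAdjustSource:
    @pytest.mark.parametrize(
        "exporter,year,source,expected,rule_hint",
        [
            ("ZA", 2010, "W", "W2", "post-2005"),
            ("ZA", 2000, "W", "W1", "source code W"),
            ("ZA", 1990, "", "W1", "pre-1995"),
            ("ZA", 1995, "", "W2", "1995+"),
            ("ZM", 2001, "F", "W2", "F/R"),
            ("KE", 2000, "C", "C", "captive"),
            ("KE", 2000, "R", "W2", "F/R"),
            ("TZ", 2000, "", "U", "no source"),
            ("ZW", 1990, "W", "W1", "wild"),
        ],
    )
    def test_clause_precedence(self, exporter, year, source, expected, rule_hint):
        adj = adjust_source(_rec(exporter=exporter, year=year, source=source))
        assert adj.source_class == expected

    def test_explicit_override_wins(self):
        ov = Override(exporter="ZA", importer="RW", year_min=2015, year_max=2017,
                      source_class="W2", citation="Akagera restocking")
        adj = adjust_source(_rec(exporter="ZA", importer="RW", year=2015, source="C"), [ov])
        assert adj.source_class == "W2" and "Akagera" in adj.adjustment_rule

    def test_fr_rule_restrictable_to_za(self):
        adj = adjust_source(_rec(exporter="ZM", year=2001, source="F"), fr_w2_all_exporters=False)
        assert adj.source_class == "U"  # F outside ZA falls through to unknown

    def test_configurable_mid_nineties_cutoff(self):
        adj = adjust_source(_rec(exporter="ZA", year=1995, source=""), mid_nineties_cutoff=1997)
        assert adj.source_class == "W1"

    def test_order_stability_under_permutation(self):
        records = [
            _rec(exporter="ZA", year=2010, source="W"),
            _rec(exporter="ZA", year=1990, source=""),
            _rec(exporter="KE", year=2000, source="C"),
            _rec(exporter="ZM", year=2001, source="F"),
        ]
        fwd = {id(r): a.source_class for r, a in zip(records, adjust_records(records))}
        rev = {id(r): a.source_class for r, a in zip(records[::-1], adjust_records(records[::-1]))}
        assert fwd == rev

    def test_origin_attribution_prefers_origin_over_transit_exporter(self):
        r = _rec(exporter="ZW", origin="BW")
        assert r.source_country == "BW"
        assert _rec(exporter="ZW").source_country == "ZW"


def test_pipeline_idempotent_on_its_own_output(tmp_path):
    records = [
        _rec(exporter="ZA", year=2010, source="W", qty_i=3),
        _rec(exporter="KE", year=2000, source="C", qty_i=2),
        _rec(exporter="ZM", year=2001, source="F", qty_i=1),
    ]
    adjusted = adjust_records(filter_records(records, frozenset({"ZA", "ZW", "TZ", "KE"})).kept)
    out = write_adjusted(adjusted, tmp_path / "adjusted.csv")
    reparsed = read_cites_csv(out)
    assert not reparsed.problems
    readjusted = adjust_records(
        filter_records(reparsed.records, frozenset({"ZA", "ZW", "TZ", "KE"})).kept
    )
    assert [a.source_class for a in readjusted] == [a.source_class for a in adjusted]
    assert [a.quantity for a in readjusted] == [a.quantity for a in adjusted]
    assert [a.category for a in readjusted] == [a.category for a in adjusted]
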