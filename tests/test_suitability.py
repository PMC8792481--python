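"""Decision-tree scoring, suture asymmetry and matrix construction.

The truth-table oracle here is an independent, literal transcription of
the classification rules (India exclusion; shared-nuclear + shared-mt =
first; shared-nuclear only = second; cross-nuclear within melanochaita =
third; else no option; into-suture best case, from-suture worst case,
same-zone first) and is enumerated exhaustively against the engine.
"""

import itertools

import pytest

from lionmatch import (
    SuitabilityLevel,
    apply_suture_direction,
    build_matrix,
    read_matrix,
    score,
    score_pair,
    write_matrix,
)
from lionmatch.registry import RegistryError
from lionmatch.simulate import RegistrySimParams, simulate_registry

L = SuitabilityLevel


# ---------------------------------------------------------------------------
# Independent truth-table oracle
# ---------------------------------------------------------------------------

_SUB = {"West": "leo", "Central": "leo", "India": "leo", "East": "melanochaita", "Southern": "melanochaita"}
_RANK = {"NO_OPTION": 0, "THIRD": 1, "SECOND": 2, "FIRST": 3}


def oracle_level(a_nu, a_mt, b_nu, b_mt):
    if ("India" in a_nu) != ("India" in b_nu):
        return "NO_OPTION"
    if set(a_nu) & set(b_nu):
        return "FIRST" if set(a_mt) & set(b_mt) else "SECOND"
    if "melanochaita" in {_SUB[n] for n in a_nu} & {_SUB[n] for n in b_nu}:
        return "THIRD"
    return "NO_OPTION"


def oracle_score(src, tgt):
    """(nu, mt, suture_zone) triples -> expected level name."""
    (a_nu, a_mt, a_sz), (b_nu, b_mt, b_sz) = src, tgt
    base = oracle_level(a_nu, a_mt, b_nu, b_mt)
    if a_sz and b_sz:
        return "FIRST" if a_sz == b_sz else base
    if b_sz and not a_sz:
        if not set(a_nu) & set(b_nu):
            return base
        return max(
            (oracle_level(a_nu, a_mt, (n,), b_mt) for n in b_nu),
            key=_RANK.__getitem__,
        )
    if a_sz and not b_sz:
        return min(
            (oracle_level((n,), a_mt, b_nu, b_mt) for n in a_nu),
            key=_RANK.__getitem__,
        )
    return base


def enumerate_units():
    """Small exhaustive vocabulary of unit types: 3 nu x 3 mt x suture x hybrid."""
    nu_opts = [("Central",), ("Southern",), ("East",), ("India",)]
    mt_opts = [("Central",), ("East/Southern",), ("Central", "East/Southern")]
    units = []
    for nu, mt, hybrid in itertools.product(nu_opts, mt_opts, (False, True)):
        units.append(((nu, mt, None), hybrid))
    for sz, mt, hybrid in itertools.product(("SZ1", "SZ2"), mt_opts, (False, True)):
        units.append(((("Central", "East"), mt, sz), hybrid))
    return units


def _as_record(make_lcu, unit, hybrid):
    nu, mt, sz = unit
    return make_lcu(nu, mt, suture_zone=sz, hybrid=hybrid)


def test_engine_matches_truth_table_on_every_enumerated_pair(make_lcu, vocab):
    units = enumerate_units()
    records = [(_as_record(make_lcu, unit, hyb), unit, hyb) for unit, hyb in units]
    checked = 0
    for (ra, sa, ha), (rb, sb, hb) in itertools.product(records, repeat=2):
        got = score(ra, rb, vocab)
        assert got.level.name == oracle_score(sa, sb), f"{sa} -> {sb}"
        assert got.hybrid_source == ha
        checked += 1
    assert checked == len(units) ** 2


# ---------------------------------------------------------------------------
# Decision-tree examples
# ---------------------------------------------------------------------------


class TestScorePair:
    @pytest.mark.parametrize(
        "src_nu,src_mt,tgt_nu,tgt_mt,expected",
        [
            # same nuclear clade, same haplogroup
            (["Southern"], ["East/Southern"], ["Southern"], ["East/Southern"], L.FIRST),
            # same nuclear clade, differentiated haplogroups
            (["Southern"], ["South West"], ["Southern"], ["East/Southern"], L.SECOND),
            # cross-nuclear within melanochaita
            (["East"], ["East/Southern"], ["Southern"], ["South West"], L.THIRD),
            # Africa <-> India excluded despite shared subspecies
            (["West"], ["West"], ["India"], ["India"], L.NO_OPTION),
            (["India"], ["India"], ["Central"], ["Central"], L.NO_OPTION),
            # third choice is not available within P. l. leo
            (["West"], ["West"], ["Central"], ["Central"], L.NO_OPTION),
            # multi-label overlap counts as shared (KAZA semantics)
            (
                ["Southern"],
                ["East/Southern", "South West"],
                ["Southern"],
                ["South West"],
                L.FIRST,
            ),
        ],
    )
    def test_rule_examples(self, make_lcu, vocab, src_nu, src_mt, tgt_nu, tgt_mt, expected):
        assert score_pair(make_lcu(src_nu, src_mt), make_lcu(tgt_nu, tgt_mt), vocab).level == expected

    def test_self_pair_is_first_choice(self, make_lcu, vocab):
        x = make_lcu(["East"], ["North East"])
        assert score_pair(x, x, vocab).level == L.FIRST

    def test_hybrid_source_flagged_not_demoted(self, make_lcu, vocab):
        hy = make_lcu(["Southern"], ["East/Southern", "South West"], hybrid=True)
        tgt = make_lcu(["Southern"], ["East/Southern"])
        sc = score_pair(hy, tgt, vocab)
        assert sc.level == L.FIRST and sc.hybrid_source

    def test_metapopulation_source_flagged_w2(self, make_lcu, vocab):
        w2 = make_lcu(["Southern"], ["East/Southern", "South West"], hybrid=True, metapop=True)
        assert score_pair(w2, make_lcu(["Southern"], ["East/Southern"]), vocab).w2_source

    def test_unknown_label_raises_configuration_error(self, make_lcu, vocab):
        from lionmatch import CladeVocabulary, GeneticProfile, LCURecord

        alien = LCURecord(
            id="x",
            name="x",
            countries=frozenset({"TZ"}),
            profile=GeneticProfile(frozenset({"Mt1"}), frozenset({"Nu1"})),
        )
        with pytest.raises(RegistryError):
            score_pair(alien, make_lcu(["East"], ["North East"]), vocab)


class TestSutureDirection:
    def test_into_suture_takes_best_component_case(self, make_lcu, vocab):
        src = make_lcu(["Central"], ["Central"])
        sz1 = make_lcu(["Central", "East"], ["Central", "North East"], suture_zone="SZ1")
        sc = score(src, sz1, vocab)
        assert sc.suture_into and not sc.suture_from
        assert sc.level == L.FIRST  # Central component shares nu + mt

    def test_from_suture_takes_worst_component_case(self, make_lcu, vocab):
        sz2 = make_lcu(["East", "Southern"], ["East/Southern"], suture_zone="SZ2")
        tgt = make_lcu(["Southern"], ["East/Southern"])
        sc = score(sz2, tgt, vocab)
        assert sc.suture_from and not sc.suture_into
        # worst component is the East side: cross-nuclear within melanochaita
        assert sc.level == L.THIRD

    def test_same_suture_zone_pairs_first(self, make_lcu, vocab):
        a = make_lcu(["East", "Southern"], ["East/Southern"], suture_zone="SZ2")
        b = make_lcu(["East", "Southern"], ["East/Southern"], suture_zone="SZ2", countries=("MZ",))
        assert score(a, b, vocab).level == L.FIRST

    def test_into_suture_requires_shared_nuclear_clade(self, make_lcu, vocab):
        src = make_lcu(["West"], ["West"])
        sz1 = make_lcu(["Central", "East"], ["Central", "North East"], suture_zone="SZ1")
        sc = score(src, sz1, vocab)
        assert not sc.suture_into  # no overlap with the zone's clades


# ---------------------------------------------------------------------------
# Matrix properties
# ---------------------------------------------------------------------------


class TestMatrix:
    def test_two_identical_lcus_all_first(self, make_lcu, vocab):
        from lionmatch import Registry

        recs = [make_lcu(["East"], ["East/Southern"]), make_lcu(["East"], ["East/Southern"])]
        reg = Registry(vocabulary=vocab, records=recs, range_states=frozenset())
        m = build_matrix(reg, axis="lcu")
        assert all(sc.level == L.FIRST for sc in m.cells.values())

    def test_symmetric_except_suture_and_hybrid_rows(self, registry):
        m = build_matrix(registry, axis="lcu")
        flagged = {
            r.id for r in registry.records if r.suture_zone or r.hybrid_origin
        }
        for a, b in itertools.combinations(m.axis, 2):
            if a in flagged or b in flagged:
                continue
            assert m[(a, b)].level == m[(b, a)].level, (a, b)

    def test_asymmetry_touches_only_suture_rows(self, make_lcu, vocab):
        from lionmatch import Registry

        plain1 = make_lcu(["East"], ["East/Southern"])
        plain2 = make_lcu(["Southern"], ["South West"])
        sz = make_lcu(["East", "Southern"], ["East/Southern"], suture_zone="SZ2")
        reg = Registry(vocabulary=vocab, records=[plain1, plain2, sz], range_states=frozenset())
        m = build_matrix(reg, axis="lcu")
        asym = {
            (a, b)
            for a in m.axis
            for b in m.axis
            if m[(a, b)].level != m[(b, a)].level
        }
        assert asym  # the suture record does break symmetry
        assert all(sz.id in pair for pair in asym)

    def test_diagonal_is_first_for_every_record(self, registry):
        m = build_matrix(registry, axis="lcu")
        for rec_id in m.axis:
            assert m[(rec_id, rec_id)].level == L.FIRST

    def test_matrix_equals_cell_by_cell_recomputation(self, vocab):
        reg, _ = simulate_registry(RegistrySimParams(n_lcus=10, p_suture=0.3, p_hybrid=0.2, seed=11))
        m = build_matrix(reg, axis="lcu")
        for s in reg.records:
            for t in reg.records:
                assert m[(s.id, t.id)] == score(s, t, reg.vocabulary)

    def test_country_matrix_header_lists_range_states_alphabetically(self, registry, tmp_path):
        import pandas as pd

        m = build_matrix(registry, axis="country")
        assert m.axis == sorted(registry.range_states)
        p = write_matrix(m, tmp_path / "m.csv", format="csv")
        assert list(pd.read_csv(p, index_col=0).columns) == sorted(registry.range_states)

    def test_single_record_matrix_round_trips(self, make_lcu, vocab, tmp_path):
        from lionmatch import Registry

        reg = Registry(
            vocabulary=vocab,
            records=[make_lcu(["East"], ["East/Southern"])],
            range_states=frozenset(),
        )
        m = build_matrix(reg, axis="lcu")
        assert len(m.cells) == 1 and next(iter(m.cells.values())).level == L.FIRST
        p = write_matrix(m, tmp_path / "m.json", format="json")
        back = read_matrix(p)
        assert back.cells == m.cells and back.axis == m.axis

    def test_default_country_matrix_round_trips_json(self, registry, tmp_path):
        m = build_matrix(registry, axis="country")
        back = read_matrix(write_matrix(m, tmp_path / "m.json", format="json"))
        assert back.cells == m.cells

    def test_empty_registry_rejected(self, vocab):
        from lionmatch import Registry

        with pytest.raises(RegistryError):
            build_matrix(Registry(vocabulary=vocab, records=[], range_states=frozenset()))


def test_level_order_is_total():
    assert L.FIRST > L.SECOND > L.THIRD > L.NO_OPTION
    assert max([L.NO_OPTION, L.SECOND]) == L.SECOND
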