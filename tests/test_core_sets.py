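import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hscnet.core_sets import (GeneSet, GmtParseError, OrthologMap, Universe,
                              map_orthologs, normalize_symbols, overlap_counts,
                              read_gmt, read_ortholog_map, read_universe,
                              restrict_universe, write_gmt)


def _gmt(tmp_path, text, name="sets.gmt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGmt:
    def test_dedup_and_normalization(self, tmp_path):
        p = _gmt(tmp_path, "HSC_FP\tna\tGata2\tNdn\tGata2\n")
        (gs,) = read_gmt(p)
        assert gs.name == "HSC_FP"
        assert gs.symbols == {"GATA2", "NDN"}
        assert len(gs) == 2

    def test_preserves_file_order(self, tmp_path):
        p = _gmt(tmp_path, "S1\tna\tA\tB\nS2\tna\tC\tD\n")
        sets = read_gmt(p)
        assert [s.name for s in sets] == ["S1", "S2"]

    def test_short_line_raises_with_line_number(self, tmp_path):
        p = _gmt(tmp_path, "X\tna\n")
        with pytest.raises(GmtParseError, match="line 1"):
            read_gmt(p)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = _gmt(tmp_path, "")
        with caplog.at_level("WARNING"):
            assert read_gmt(p) == []
        assert any("no gene sets" in r.message for r in caplog.records)

    def test_duplicate_set_name_is_an_error(self, tmp_path):
        p = _gmt(tmp_path, "S\tna\tA\nS\tna\tB\n")
        with pytest.raises(GmtParseError, match="duplicate"):
            read_gmt(p)

    def test_crlf_and_comments_tolerated(self, tmp_path):
        p = _gmt(tmp_path, "# header\r\nS1\tna\tA\tB\r\n")
        (gs,) = read_gmt(p)
        assert gs.symbols == {"A", "B"}

    def test_round_trip(self, tmp_path):
        sets = [GeneSet(name="S1", symbols=frozenset({"A", "B"})),
                GeneSet(name="S2", symbols=frozenset({"C"}))]
        p = tmp_path / "out.gmt"
        write_gmt(sets, p)
        back = read_gmt(p)
        assert [(s.name, s.symbols) for s in back] == \
               [(s.name, s.symbols) for s in sets]


class TestNormalize:
    @pytest.mark.parametrize("symbols,policy,expected", [
        ({"Gata2", "GATA2"}, "upper", {"GATA2"}),
        ({"Atxn1l"}, "asis", {"Atxn1l"}),
        (set(), "upper", set()),
    ])
    def test_policies(self, symbols, policy, expected):
        gs = GeneSet(name="S", symbols=frozenset(symbols)) if symbols else \
            GeneSet(name="S", symbols=frozenset())
        assert normalize_symbols(gs, policy).symbols == expected

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            normalize_symbols(GeneSet(name="S", symbols=frozenset({"A"})), "lower")

    def test_size_never_increases(self):
        gs = GeneSet(name="S", symbols=frozenset({"a", "A", "b"}))
        assert len(normalize_symbols(gs, "upper")) <= len(gs)


class TestOrthologMap:
    @pytest.fixture
    def omap(self):
        return OrthologMap(groups=(
            (frozenset({"A"}), frozenset({"A1"})),
            (frozenset({"B"}), frozenset({"B1", "B2"})),
        ))

    def test_all_targets_unions(self, omap):
        gs = GeneSet(name="S", symbols=frozenset({"A", "B"}))
        assert map_orthologs(gs, omap, "all_targets").symbols == {"A1", "B1", "B2"}

    def test_drop_ambiguous(self, omap):
        gs = GeneSet(name="S", symbols=frozenset({"A", "B"}))
        assert map_orthologs(gs, omap, "drop_ambiguous").symbols == {"A1"}

    def test_unmapped_symbol_yields_empty_with_warning(self, omap, caplog):
        gs = GeneSet(name="S", symbols=frozenset({"C"}))
        with caplog.at_level("WARNING"):
            assert map_orthologs(gs, omap).symbols == frozenset()
        assert any("no homology group" in r.message for r in caplog.records)

    def test_idempotent_on_identity_map(self):
        idmap = OrthologMap(groups=tuple(
            (frozenset({s}), frozenset({s})) for s in "ABC"))
        gs = GeneSet(name="S", symbols=frozenset({"A", "B"}))
        once = map_orthologs(gs, idmap)
        twice = map_orthologs(once, idmap)
        assert once.symbols == twice.symbols == gs.symbols

    def test_duplicate_source_symbol_rejected(self):
        with pytest.raises(ValueError, match="more than one group"):
            OrthologMap(groups=(
                (frozenset({"A"}), frozenset({"X"})),
                (frozenset({"A"}), frozenset({"Y"})),
            ))

    def test_from_pairs_merges_many_to_many(self):
        omap = OrthologMap.from_pairs([("a", "X"), ("b", "X"), ("b", "Y")])
        assert len(omap.groups) == 1
        src, tgt = omap.groups[0]
        assert src == {"A", "B"} and tgt == {"X", "Y"}

    def test_read_tsv(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("Gata2\tGATA2\n# comment\nNdn\tNDN\n")
        omap = read_ortholog_map(p)
        gs = GeneSet(name="S", symbols=frozenset({"GATA2"}))
        assert map_orthologs(gs, omap).symbols == {"GATA2"}


class TestRestrictUniverse:
    def test_intersection_discards(self, caplog):
        u = Universe(name="U", symbols=frozenset("ABCD"))
        comp = GeneSet(name="S", symbols=frozenset({"B", "D", "E"}))
        with caplog.at_level("INFO"):
            out = restrict_universe(u, comp)
        assert out.symbols == {"B", "D"}
        assert out.universe_name == "U"
        assert any("discarded 1" in r.message for r in caplog.records)

    def test_subset_unchanged(self):
        u = Universe(name="U", symbols=frozenset("ABCD"))
        comp = GeneSet(name="S", symbols=frozenset({"A", "C"}))
        assert restrict_universe(u, comp).symbols == comp.symbols

    def test_disjoint_gives_empty(self):
        u = Universe(name="U", symbols=frozenset("ABCD"))
        comp = GeneSet(name="S", symbols=frozenset({"X", "Y"}))
        assert restrict_universe(u, comp).symbols == frozenset()

    def test_idempotent(self):
        u = Universe(name="U", symbols=frozenset("ABCD"))
        comp = GeneSet(name="S", symbols=frozenset({"B", "E"}))
        once = restrict_universe(u, comp)
        assert restrict_universe(u, once).symbols == once.symbols


class TestOverlapCounts:
    def test_worked_example(self, small_universe, overlap_sets):
        fixed, comp = overlap_sets
        t = overlap_counts(fixed, comp, small_universe)
        assert (t.a, t.b, t.c, t.d) == (3, 2, 1, 14)

    def test_identical_sets(self, small_universe):
        gs = GeneSet(name="S", symbols=frozenset({"G0", "G1", "G2"}))
        t = overlap_counts(gs, gs, small_universe)
        assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 17)

    def test_disjoint_sets(self, small_universe):
        f = GeneSet(name="F", symbols=frozenset(f"G{i}" for i in range(5)))
        c = GeneSet(name="C", symbols=frozenset(f"G{i}" for i in range(5, 9)))
        t = overlap_counts(f, c, small_universe)
        assert (t.a, t.b, t.c, t.d) == (0, 5, 4, 11)

    def test_stray_symbol_named_in_error(self, small_universe):
        f = GeneSet(name="F", symbols=frozenset({"G0", "NOT_THERE"}))
        c = GeneSet(name="C", symbols=frozenset({"G1"}))
        with pytest.raises(ValueError, match="NOT_THERE"):
            overlap_counts(f, c, small_universe)

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_margins_property(self, data):
        n_universe = data.draw(st.integers(1, 30))
        universe = Universe(name="U",
                            symbols=frozenset(f"G{i}" for i in range(n_universe)))
        syms = sorted(universe.symbols)
        fixed = frozenset(data.draw(
            st.sets(st.sampled_from(syms), max_size=n_universe)))
        comp = frozenset(data.draw(
            st.sets(st.sampled_from(syms), max_size=n_universe)))
        f = GeneSet(name="F", symbols=fixed) if fixed else \
            GeneSet(name="F", symbols=frozenset())
        c = GeneSet(name="C", symbols=comp) if comp else \
            GeneSet(name="C", symbols=frozenset())
        t = overlap_counts(f, c, universe)
        assert t.a + t.b == len(fixed)
        assert t.a + t.c == len(comp)
        assert t.N == n_universe


def test_read_universe(tmp_path):
    p = tmp_path / "u.tsv"
    p.write_text("gata2\nNdn\n# skip\n")
    u = read_universe(p, name="U")
    assert u.symbols == {"GATA2", "NDN"}
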