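import pytest
from hypothesis import given, settings, strategies as st

from xenopept.digestion import DigestionParams
from xenopept.io import ProteinRecord
from xenopept.species import (
    build_peptide_index,
    classify_observed,
    strip_modifications,
    summarize_classification,
)

PARAMS = DigestionParams(max_missed_cleavages=0, min_length=3, max_length=50)


class TestBuildPeptideIndex:
    def test_worked_example_parent_sets(self, toy_index):
        assert toy_index.lookup("AAAK") == (frozenset({"P1"}), frozenset({"M1"}))
        assert toy_index.lookup("TTTK") == (frozenset({"P1"}), frozenset())
        assert toy_index.lookup("SSSK") == (frozenset(), frozenset({"M1"}))

    def test_identical_proteomes_have_no_unique_peptides(self):
        human = [ProteinRecord("P1", "human", "", "AAAKTTTK")]
        mouse = [ProteinRecord("M1", "mouse", "", "AAAKTTTK")]
        index = build_peptide_index(human, mouse, PARAMS)
        for hp, mp in index.entries.values():
            assert hp and mp

    def test_empty_mouse_side(self):
        human = [ProteinRecord("P1", "human", "", "AAAKTTTK")]
        index = build_peptide_index(human, [], PARAMS)
        assert all(mp == frozenset() for _, mp in index.entries.values())

    def test_both_sides_empty_rejected(self):
        with pytest.raises(ValueError):
            build_peptide_index([], [], PARAMS)

    def test_every_key_has_a_parent(self, toy_index):
        for hp, mp in toy_index.entries.values():
            assert hp or mp


class TestClassifyObserved:
    def test_worked_example_labels(self, toy_index):
        table = classify_observed(["AAAK", "TTTK", "SSSK", "QQQQ"], toy_index)
        labels = {r.peptide: r.label for r in table}
        assert labels == {
            "AAAK": "shared",
            "TTTK": "human_unique",
            "SSSK": "mouse_unique",
            "QQQQ": "unmapped",
        }

    def test_empty_observed(self, toy_index):
        assert classify_observed([], toy_index) == []

    def test_duplicates_collapse_to_one_row(self, toy_index):
        table = classify_observed(["AAAK", "aaak", "AAAK"], toy_index)
        assert len(table) == 1

    def test_all_shared_proteomes_yield_no_human_unique(self):
        human = [ProteinRecord("P1", "human", "", "AAAKTTTK")]
        mouse = [ProteinRecord("M1", "mouse", "", "AAAKTTTK")]
        index = build_peptide_index(human, mouse, PARAMS)
        table = classify_observed(["AAAK", "TTTK"], index)
        assert summarize_classification(table)["human_unique"] == 0

    def test_summary_counts(self, toy_index):
        table = classify_observed(["AAAK", "TTTK", "SSSK", "QQQQ"], toy_index)
        counts = summarize_classification(table)
        assert counts == {
            "human_unique": 1,
            "mouse_unique": 1,
            "shared": 1,
            "unmapped": 1,
        }
        assert summarize_classification([]) == {
            "human_unique": 0,
            "mouse_unique": 0,
            "shared": 0,
            "unmapped": 0,
        }

    @given(
        observed=st.lists(
            st.text(alphabet="AKST", min_size=3, max_size=8), max_size=30
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_label_counts_conserve_distinct_total(self, observed):
        human = [ProteinRecord("P1", "human", "", "AAAKTTTK")]
        mouse = [ProteinRecord("M1", "mouse", "", "AAAKSSSK")]
        index = build_peptide_index(human, mouse, PARAMS)
        table = classify_observed(observed, index)
        counts = summarize_classification(table)
        assert sum(counts.values()) == len({p.upper() for p in observed})


class TestEquateIL:
    def make_pair(self):
        human = [ProteinRecord("P1", "human", "", "ILAKTTTKMIKPLI")]
        mouse = [ProteinRecord("M1", "mouse", "", "LLAKTTTKMLKPLL")]
        return human, mouse

    def test_collapsing_il_merges_keys(self):
        human, mouse = self.make_pair()
        strict = build_peptide_index(human, mouse, PARAMS, equate_il=False)
        merged = build_peptide_index(human, mouse, PARAMS, equate_il=True)
        def n_human_unique(index):
            return sum(1 for hp, mp in index.entries.values() if hp and not mp)
        assert n_human_unique(merged) <= n_human_unique(strict)
        # ILAK vs LLAK differ only by I/L, so they collapse entirely
        assert n_human_unique(merged) == 0

    @given(
        hseq=st.text(alphabet="AILKRST", min_size=6, max_size=40),
        mseq=st.text(alphabet="AILKRST", min_size=6, max_size=40),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_equate_il_never_increases_uniqueness(self, hseq, mseq):
        human = [ProteinRecord("P1", "human", "", hseq)]
        mouse = [ProteinRecord("M1", "mouse", "", mseq)]
        params = DigestionParams(max_missed_cleavages=1, min_length=2, max_length=40)
        strict = build_peptide_index(human, mouse, params, equate_il=False)
        merged = build_peptide_index(human, mouse, params, equate_il=True)
        def n_human_unique(index):
            return sum(1 for hp, mp in index.entries.values() if hp and not mp)
        assert n_human_unique(merged) <= n_human_unique(strict)


class TestStripModifications:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("AAAK", "AAAK"),
            ("aam(ox)k", "AAMK"),
            ("M[+15.995]GDVEK", "MGDVEK"),
            ("K.MGDVEK.A", "MGDVEK"),
            ("-.MGDVEK.A", "MGDVEK"),
            ("MGDVEK(Carbamidomethyl)", "MGDVEK"),
        ],
    )
    def test_annotation_stripping(self, raw, expected):
        assert strip_modifications(raw) == expected
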