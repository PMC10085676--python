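"""Mutant libraries: edits, the naming grammar, scans, and the
perfect-invader correction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epbarriers.core import DomainError
from epbarriers.duplex import ColumnKind, align_construct, annotate_elements
from epbarriers.mutagenesis import (ConsistencyError, MutationKind,
                                    MutationSpec, apply_mutation,
                                    apply_mutations, diff_constructs,
                                    name_mutation, parse_mutation_name,
                                    perfect_invader, scan_bulge,
                                    scan_deletion, scan_mismatch, scan_wobble)


class TestApplyMutation:
    def test_substitution_g108c(self, wt):
        mut = apply_mutation(wt, MutationSpec(MutationKind.SUBSTITUTION, 108, "C"))
        assert len(mut.sequence) == len(wt.sequence)
        assert mut.sequence.base(108) == "C"

    def test_deletion_a26_shifts_downstream_regions(self, wt):
        mut = apply_mutation(wt, MutationSpec(MutationKind.DELETION, 26))
        assert len(mut.sequence) == len(wt.sequence) - 1
        assert mut.region("invader").start == wt.region("invader").start - 1
        assert mut.region("polyU").start == wt.region("polyU").start - 1

    def test_insertion_after_110(self, wt):
        mut = apply_mutation(wt, MutationSpec(MutationKind.INSERTION, 110, "A"))
        assert len(mut.sequence) == len(wt.sequence) + 1
        assert mut.sequence.base(110) == wt.sequence.base(110)
        assert mut.sequence.base(111) == "A"
        assert mut.sequence.base(112) == wt.sequence.base(111)
        # insertion inside the invader stretches it
        assert len(mut.region("invader")) == len(wt.region("invader")) + 1

    def test_no_op_substitution_rejected(self, wt):
        with pytest.raises(DomainError, match="no-op"):
            apply_mutation(wt, MutationSpec(MutationKind.SUBSTITUTION, 108, "G"))

    def test_out_of_range_rejected(self, wt):
        with pytest.raises(DomainError):
            apply_mutation(wt, MutationSpec(MutationKind.DELETION, 999))

    def test_region_invariants_preserved_across_scans(self, wt):
        for lib in (scan_deletion(wt), scan_bulge(wt, 3)):
            for entry in lib.mutants:
                c = entry.construct
                assert c.region("P3").end < c.region("invader").start
                assert c.region("invader").end < c.region("polyU").start


class TestNamingGrammar:
    def test_names_match_field_convention(self, wt):
        assert name_mutation(
            MutationSpec(MutationKind.SUBSTITUTION, 108, "C"), wt) == "G108C"
        assert name_mutation(
            MutationSpec(MutationKind.DELETION, 26), wt) == "A26Δ"
        assert name_mutation(
            MutationSpec(MutationKind.INSERTION, 110, "AA"), wt) == "110insAA"

    @pytest.mark.parametrize("name,kind,pos,alt", [
        ("G108C", MutationKind.SUBSTITUTION, 108, "C"),
        ("A26Δ", MutationKind.DELETION, 26, ""),
        ("A26del", MutationKind.DELETION, 26, ""),
        ("110insAA", MutationKind.INSERTION, 110, "AA"),
        ("G108-C109insAAA", MutationKind.INSERTION, 108, "AAA"),
    ])
    def test_parse(self, wt, name, kind, pos, alt):
        spec = parse_mutation_name(name, wt)
        assert (spec.kind, spec.position, spec.alt) == (kind, pos, alt)

    def test_stated_reference_base_checked(self, wt):
        with pytest.raises(ConsistencyError):
            parse_mutation_name("C100G", apply_mutation(
                wt, MutationSpec(MutationKind.SUBSTITUTION, 100, "A")))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=134),
           st.sampled_from(["SUB", "DEL", "INS"]),
           st.text(alphabet="ACGU", min_size=1, max_size=3))
    def test_name_parse_round_trip(self, pos, kind, alt):
        from epbarriers import wt_construct
        wt = wt_construct()
        if kind == "SUB":
            alt1 = alt[0]
            if alt1 == wt.sequence.base(pos):
                return
            spec = MutationSpec(MutationKind.SUBSTITUTION, pos, alt1)
        elif kind == "DEL":
            spec = MutationSpec(MutationKind.DELETION, pos)
        else:
            spec = MutationSpec(MutationKind.INSERTION, pos, alt)
        assert parse_mutation_name(name_mutation(spec, wt), wt) == spec


class TestScans:
    def test_mismatch_scan_contains_g108c_and_skips_bulges(self, wt):
        lib = scan_mismatch(wt)
        assert "G108C" in lib.names()
        positions = {m.specs[0].position for m in lib.mutants}
        assert 115 not in positions and 118 not in positions
        # one mutant per paired invader column
        paired = sum(c.paired for c in align_construct(wt).columns)
        assert len(lib) == paired

    # WC positions far enough from the natural wobbles/bulges that the
    # duplex cannot re-register around the new mismatch
    ISOLATED_WC = {"G108C", "C109G", "C110G", "A120U",
                   "C123G", "U124A", "C125G", "U126A"}

    def test_mismatch_mutants_perturb_the_duplex(self, wt):
        """A mismatch substitution never improves the duplex, and at
        isolated stem positions it leaves a MISMATCH element at exactly its
        barrier index; near natural bulges the stem may re-register
        (strand slippage) and relocate the defect instead."""
        wt_aln = align_construct(wt)
        wt_elements = annotate_elements(wt_aln, wt)
        for entry in scan_mismatch(wt).mutants:
            aln = align_construct(entry.construct)
            assert aln.score <= wt_aln.score, entry.name
            elements = annotate_elements(aln, entry.construct)
            assert elements != wt_elements, entry.name
            if entry.name in self.ISOLATED_WC:
                assert any(e.kind is ColumnKind.MISMATCH and e.r == entry.r
                           for e in elements), entry.name

    def test_deletion_scan_covers_invader(self, wt):
        lib = scan_deletion(wt)
        assert "G108Δ" in lib.names()
        # one mutant per distinct deletion product: the invader's four
        # 2-nt repeats (CC, AA, AA, GG) each collapse to one entry
        assert len(lib) == len(wt.region("invader")) - 4

    def test_bulge_scan_inserts_after_index(self, perfect):
        lib = scan_bulge(perfect, 1)
        entry = next(m for m in lib.mutants if m.r == 3)
        spec = entry.specs[0]
        assert spec.position == 110 and spec.alt == "A"
        # the insertion lands between former positions 110 and 111
        assert entry.construct.sequence.base(111) == "A"

    def test_bulge_scan_rejects_bad_size(self, wt):
        with pytest.raises(DomainError):
            scan_bulge(wt, 4)

    def test_wobble_scan_includes_c110u_and_flags_reversed(self, perfect):
        lib = scan_wobble(perfect)
        assert "C110U" in lib.names()
        reversed_entries = [m for m in lib.mutants if m.note]
        assert {m.name for m in reversed_entries} >= {"A112G", "A114G"}
        strict = scan_wobble(perfect, include_reversed=False)
        assert all(not m.note for m in strict.mutants)

    @pytest.mark.parametrize("scan", [
        scan_mismatch, scan_deletion,
        lambda c: scan_bulge(c, 1), lambda c: scan_bulge(c, 2), scan_wobble,
    ])
    def test_libraries_are_duplicate_free(self, wt, scan):
        lib = scan(wt)
        seqs = [str(m.construct.sequence) for m in lib.mutants]
        assert len(seqs) == len(set(seqs))

    @pytest.mark.parametrize("scan", [scan_mismatch, scan_deletion,
                                      lambda c: scan_bulge(c, 2)])
    def test_diff_recovers_generating_specs(self, wt, scan):
        for entry in scan(wt).mutants:
            assert tuple(diff_constructs(wt, entry.construct)) == entry.specs


class TestPerfectInvader:
    def test_reference_needs_five_corrections(self, wt):
        _, specs = perfect_invader(wt)
        kinds = [s.kind for s in specs]
        assert len(specs) == 5
        assert kinds.count(MutationKind.SUBSTITUTION) == 3
        assert kinds.count(MutationKind.DELETION) == 2
        names = {name_mutation(s, wt) for s in specs}
        assert {"U111C", "G112A", "U115Δ", "C118Δ"} <= names

    def test_corrected_invader_has_no_elements(self, perfect):
        assert annotate_elements(align_construct(perfect), perfect) == []

    def test_idempotent(self, perfect):
        again, specs = perfect_invader(perfect)
        assert specs == []
        assert str(again.sequence) == str(perfect.sequence)

    def test_mismatch_corrected_with_warning(self, wt):
        mismatched = apply_mutation(
            wt, MutationSpec(MutationKind.SUBSTITUTION, 109, "G"))
        with pytest.warns(UserWarning, match="mismatch"):
            corrected, _ = perfect_invader(mismatched)
        assert annotate_elements(
            align_construct(corrected), corrected) == []

    def test_compound_application_matches_specs(self, wt):
        corrected, specs = perfect_invader(wt)
        assert str(apply_mutations(wt, specs).sequence) == str(corrected.sequence)
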