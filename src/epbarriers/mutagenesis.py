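"""Mutant library generation for kinetic-barrier scans.

Libraries follow the field's naming style: substitutions "G108C", deletions
"G108Δ" (ASCII alias "G108del"), insertions "108insA" (alias
"G108-C109insA", bracketing the insertion by its flanking residues).
Coordinates in mutant names always refer to REFERENCE numbering, never
re-numbered mutant coordinates, so compound mutants stay interpretable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum

from .core import COMPLEMENT, Construct, DomainError, Region, RnaSequence
from .duplex import (AlignParams, ColumnKind, align_construct,
                     annotate_elements)


class MutationKind(Enum):
    SUBSTITUTION = "SUBSTITUTION"
    DELETION = "DELETION"
    INSERTION = "INSERTION"


class ConsistencyError(ValueError):
    """A mutation name's stated reference base does not match the reference."""


@dataclass(frozen=True)
class MutationSpec:
    """A single edit in reference coordinates.

    For INSERTION, ``position`` is the residue immediately 5' of the
    inserted bases (insertions sit *after* the indexed nucleotide).
    """

    kind: MutationKind
    position: int
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind is MutationKind.SUBSTITUTION and len(self.alt) != 1:
            raise DomainError("substitution alt must be a single residue")
        if self.kind is MutationKind.INSERTION and len(self.alt) < 1:
            raise DomainError("insertion alt must be nonempty")
        if self.kind is MutationKind.DELETION and self.alt:
            raise DomainError("deletion carries no alt residues")
        if self.alt:
            object.__setattr__(self, "alt",
                               str(RnaSequence(self.alt)))


def apply_mutation(construct: Construct, spec: MutationSpec) -> Construct:
    """Apply one edit, shifting all region coordinates 3' of the edit by the
    length change. A region containing the edit stretches or shrinks."""
    seq = str(construct.sequence)
    pos = spec.position
    if not 1 <= pos <= len(seq):
        raise DomainError(f"position {pos} outside sequence of length {len(seq)}")

    if spec.kind is MutationKind.SUBSTITUTION:
        if seq[pos - 1] == spec.alt:
            raise DomainError(
                f"no-op substitution: reference already {spec.alt} at {pos}")
        new_seq = seq[:pos - 1] + spec.alt + seq[pos:]
        return replace(construct, sequence=RnaSequence(new_seq))

    if spec.kind is MutationKind.DELETION:
        new_seq = seq[:pos - 1] + seq[pos:]
        regions = []
        for reg in construct.regions:
            if reg.end < pos:
                regions.append(reg)
            elif reg.start > pos:
                regions.append(reg.shifted(-1))
            elif len(reg) == 1:
                continue  # region deleted outright
            else:
                regions.append(Region(reg.name, reg.start, reg.end - 1))
        return Construct(construct.id, RnaSequence(new_seq), tuple(regions))

    # INSERTION after `pos`
    ins = spec.alt
    new_seq = seq[:pos] + ins + seq[pos:]
    k = len(ins)
    regions = []
    for reg in construct.regions:
        if reg.end <= pos:
            regions.append(reg)
        elif reg.start > pos:
            regions.append(reg.shifted(k))
        else:  # insertion strictly inside the region: it stretches
            regions.append(Region(reg.name, reg.start, reg.end + k))
    return Construct(construct.id, RnaSequence(new_seq), tuple(regions))


def apply_mutations(construct: Construct,
                    specs: list[MutationSpec]) -> Construct:
    """Apply several edits given in reference coordinates.

    Edits are applied 3'-most first so earlier coordinates stay valid.
    """
    order = sorted(specs, key=lambda s: s.position, reverse=True)
    out = construct
    for spec in order:
        out = apply_mutation(out, spec)
    return out


# ---------------------------------------------------------------------------
# naming grammar

_SUB_RE = re.compile(r"^([ACGU])(\d+)([ACGU])$")
_DEL_RE = re.compile(r"^([ACGU])(\d+)(?:Δ|del)$")
_INS_RE = re.compile(r"^(\d+)ins([ACGU]+)$")
_INS_FLANK_RE = re.compile(r"^([ACGU])(\d+)-([ACGU])(\d+)ins([ACGU]+)$")


def name_mutation(spec: MutationSpec, reference: Construct) -> str:
    ref_base = reference.sequence.base(spec.position)
    if spec.kind is MutationKind.SUBSTITUTION:
        return f"{ref_base}{spec.position}{spec.alt}"
    if spec.kind is MutationKind.DELETION:
        return f"{ref_base}{spec.position}Δ"
    return f"{spec.position}ins{spec.alt}"


def parse_mutation_name(name: str, reference: Construct) -> MutationSpec:
    """Inverse of :func:`name_mutation`; checks the stated reference base."""
    name = name.strip()
    if m := _SUB_RE.match(name):
        stated, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        _check_ref(reference, pos, stated, name)
        return MutationSpec(MutationKind.SUBSTITUTION, pos, alt)
    if m := _DEL_RE.match(name):
        stated, pos = m.group(1), int(m.group(2))
        _check_ref(reference, pos, stated, name)
        return MutationSpec(MutationKind.DELETION, pos)
    if m := _INS_RE.match(name):
        return MutationSpec(MutationKind.INSERTION, int(m.group(1)), m.group(2))
    if m := _INS_FLANK_RE.match(name):
        b5, p5, b3, p3 = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
        if p3 != p5 + 1:
            raise ConsistencyError(f"{name}: flanking positions not adjacent")
        _check_ref(reference, p5, b5, name)
        _check_ref(reference, p3, b3, name)
        return MutationSpec(MutationKind.INSERTION, p5, m.group(5))
    raise ConsistencyError(f"unparseable mutation name {name!r}")


def _check_ref(reference: Construct, pos: int, stated: str, name: str) -> None:
    actual = reference.sequence.base(pos)
    if actual != stated:
        raise ConsistencyError(
            f"{name}: reference has {actual} at {pos}, name states {stated}")


def diff_constructs(reference: Construct, mutant: Construct
                    ) -> list[MutationSpec]:
    """Recover MutationSpecs by diffing a mutant against its reference
    (minimal edit script; used for round-trip checks)."""
    a, b = str(reference.sequence), str(mutant.sequence)
    # prefix/suffix trim, then classify the middle
    i = 0
    while i < len(a) and i < len(b) and a[i] == b[i]:
        i += 1
    j = 0
    while (j < len(a) - i and j < len(b) - i
           and a[len(a) - 1 - j] == b[len(b) - 1 - j]):
        j += 1
    mid_a, mid_b = a[i:len(a) - j], b[i:len(b) - j]
    specs: list[MutationSpec] = []
    if not mid_a and not mid_b:
        return specs
    if not mid_a:
        # left-align: an insertion inside a repeat is reported at its
        # 5'-most equivalent placement (the scans' canonical choice)
        ins = mid_b
        while i > 0 and a[i - 1] == ins[-1]:
            ins = a[i - 1] + ins[:-1]
            i -= 1
        return [MutationSpec(MutationKind.INSERTION, i, ins)]
    if not mid_b:
        while i > 0 and a[i - 1] == a[i + len(mid_a) - 1]:
            i -= 1
        return [MutationSpec(MutationKind.DELETION, i + k + 1)
                for k in range(len(mid_a))]
    if len(mid_a) == len(mid_b):
        return [MutationSpec(MutationKind.SUBSTITUTION, i + k + 1, bb)
                for k, (ab, bb) in enumerate(zip(mid_a, mid_b)) if ab != bb]
    raise DomainError("mutant differs from reference by a compound edit; "
                      "diff is defined for single-spec libraries")


# ---------------------------------------------------------------------------
# scan libraries


@dataclass(frozen=True)
class MutantEntry:
    name: str
    specs: tuple[MutationSpec, ...]
    construct: Construct
    r: int | None = None
    note: str = ""


@dataclass(frozen=True)
class MutantLibrary:
    name: str
    reference: Construct
    mutants: tuple[MutantEntry, ...] = field(default_factory=tuple)

    def names(self) -> list[str]:
        return [m.name for m in self.mutants]

    def __len__(self) -> int:
        return len(self.mutants)


def _paired_invader_columns(construct: Construct,
                            params: AlignParams | None = None):
    aln = align_construct(construct, params)
    return [c for c in aln.columns if c.paired]


def scan_mismatch(construct: Construct,
                  params: AlignParams | None = None) -> MutantLibrary:
    """One mutant per paired invader position, substituting the invader base
    with its own Watson-Crick complement (G<->C, A<->U) — guaranteed to break
    the pair whatever the substrate base is."""
    inv = construct.require_region("invader")
    entries = []
    for col in _paired_invader_columns(construct, params):
        pos = col.invader_pos
        alt = COMPLEMENT[construct.sequence.base(pos)]
        spec = MutationSpec(MutationKind.SUBSTITUTION, pos, alt)
        entries.append(MutantEntry(
            name_mutation(spec, construct), (spec,),
            apply_mutation(construct, spec), r=pos - inv.start + 1))
    return MutantLibrary("mismatch", construct, tuple(entries))


def _dedupe(entries: list[MutantEntry]) -> tuple[MutantEntry, ...]:
    """Drop entries whose sequence duplicates an earlier one.

    Deleting any member of a homopolymer run (or inserting next to one)
    yields the same molecule; the 5'-most (nucleation-proximal) placement is
    kept as the canonical representative.
    """
    seen: set[str] = set()
    out = []
    for entry in entries:
        key = str(entry.construct.sequence)
        if key not in seen:
            seen.add(key)
            out.append(entry)
    return tuple(out)


def scan_deletion(construct: Construct) -> MutantLibrary:
    """One mutant per invader position; equivalent deletions within repeats
    are collapsed to the 5'-most representative."""
    inv = construct.require_region("invader")
    entries = []
    for pos in range(inv.start, inv.end + 1):
        spec = MutationSpec(MutationKind.DELETION, pos)
        entries.append(MutantEntry(
            name_mutation(spec, construct), (spec,),
            apply_mutation(construct, spec), r=pos - inv.start + 1))
    return MutantLibrary("deletion", construct, _dedupe(entries))


def scan_bulge(construct: Construct, n: int, base: str = "A") -> MutantLibrary:
    """Poly-``base`` insertion of length n (1-3) after each invader index
    position; an insertion after index k carries barrier index r = k.
    Equivalent insertions next to repeats collapse to the 5'-most
    placement."""
    if n not in (1, 2, 3):
        raise DomainError(f"bulge size must be 1, 2 or 3, got {n}")
    inv = construct.require_region("invader")
    entries = []
    for pos in range(inv.start, inv.end + 1):
        spec = MutationSpec(MutationKind.INSERTION, pos, base * n)
        entries.append(MutantEntry(
            name_mutation(spec, construct), (spec,),
            apply_mutation(construct, spec), r=pos - inv.start + 1))
    return MutantLibrary(f"bulge{n}", construct, _dedupe(entries))


def scan_wobble(construct: Construct, params: AlignParams | None = None,
                include_reversed: bool = True) -> MutantLibrary:
    """Wobble scan over positions where one substitution turns a WC pair
    into G:U or U:G: C->U on G:C pairs and A->G on U:A pairs.

    The A->G direction replaces a U:A Watson-Crick pair with a U:G wobble,
    which has been observed to *favor* strand displacement rather than
    hinder it; such entries are flagged and can be excluded with
    ``include_reversed=False``.
    """
    inv = construct.require_region("invader")
    entries = []
    for col in _paired_invader_columns(construct, params):
        if col.kind is not ColumnKind.WC:
            continue
        pos, ib = col.invader_pos, col.invader_base
        if ib == "C":  # C:G -> U:G
            alt, note = "U", ""
        elif ib == "A":  # A:U -> G:U (wobble-to-WC direction reversed)
            if not include_reversed:
                continue
            alt, note = "G", "wobble-to-WC direction reversed"
        else:
            continue
        spec = MutationSpec(MutationKind.SUBSTITUTION, pos, alt)
        entries.append(MutantEntry(
            name_mutation(spec, construct), (spec,),
            apply_mutation(construct, spec), r=pos - inv.start + 1, note=note))
    return MutantLibrary("wobble", construct, tuple(entries))


def perfect_invader(construct: Construct,
                    params: AlignParams | None = None
                    ) -> tuple[Construct, list[MutationSpec]]:
    """Correct the invader to perfectly complement its substrate: wobble
    columns are substituted to the WC complement of the substrate base and
    invader bulges are deleted. Returns the corrected construct plus the
    corrective specs (reference coordinates).

    Mismatch columns, absent from the natural reference, are corrected the
    same way with a warning.
    """
    import warnings

    aln = align_construct(construct, params)
    elements = annotate_elements(aln, construct)
    specs: list[MutationSpec] = []
    for el in elements:
        if el.kind is ColumnKind.WOBBLE or el.kind is ColumnKind.MISMATCH:
            if el.kind is ColumnKind.MISMATCH:
                warnings.warn(
                    "mismatch element corrected; the natural reference "
                    "invader has none", stacklevel=2)
            # element positions are stored in column order, so the i-th
            # invader and substrate positions belong to the same column
            for ipos, spos in zip(el.invader_positions,
                                  el.substrate_positions):
                alt = COMPLEMENT[construct.sequence.base(spos)]
                if construct.sequence.base(ipos) != alt:
                    specs.append(MutationSpec(
                        MutationKind.SUBSTITUTION, ipos, alt))
        elif el.kind is ColumnKind.BULGE_INVADER:
            for ipos in el.invader_positions:
                specs.append(MutationSpec(MutationKind.DELETION, ipos))
        # substrate bulges cannot be corrected by editing the invader alone
    specs.sort(key=lambda s: s.position)
    corrected = apply_mutations(construct, specs)
    corrected = corrected.with_id(construct.id + "_perfect")
    return corrected, specs
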