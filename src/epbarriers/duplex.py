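"""Invader-vs-substrate duplex annotation for terminator expression platforms.

The terminator hairpin of a transcriptional ZTP riboswitch forms when the 3'
invader strand-invades the aptamer's P3 stem and pseudoknot, nucleating at
the pair closest to the apical loop and branch-migrating toward the hairpin
base. This module aligns the invader against that substrate span, classifies
the noncomplementary elements (wobbles, mismatches, bulges) that act as
kinetic barriers to strand displacement, and scores hairpin stability with a
reduced nearest-neighbor model.

The alignment is a small deterministic dynamic program: global in the
invader, anchored at the nucleation corner (the substrate window's 3'
terminus), with unscored trailing substrate at the distal end. Scoring
constants are package defaults (WC +3, wobble +1, mismatch -2, gap -4 per
bulged nucleotide), not measured quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .core import Construct, DomainError, Region, RnaSequence

WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})


class ColumnKind(Enum):
    WC = "WC"
    WOBBLE = "WOBBLE"
    MISMATCH = "MISMATCH"
    BULGE_INVADER = "BULGE_INVADER"
    BULGE_SUBSTRATE = "BULGE_SUBSTRATE"


def pair_kind(invader_base: str, substrate_base: str) -> ColumnKind:
    key = (invader_base, substrate_base)
    if key in WC_PAIRS:
        return ColumnKind.WC
    if key in WOBBLE_PAIRS:
        return ColumnKind.WOBBLE
    return ColumnKind.MISMATCH


@dataclass(frozen=True)
class DuplexColumn:
    """One column of the antiparallel invader:substrate duplex.

    Positions are 1-based; bulge columns carry a position on one side only.
    """

    kind: ColumnKind
    invader_pos: int | None
    substrate_pos: int | None
    invader_base: str | None = None
    substrate_base: str | None = None

    @property
    def paired(self) -> bool:
        return self.invader_pos is not None and self.substrate_pos is not None


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring; defaults are package conventions, overridable."""

    wc: float = 3.0
    wobble: float = 1.0
    mismatch: float = -2.0
    gap: float = -4.0
    #: extra substrate nucleotides beyond invader length in the window
    slack: int = 4

    def pair_score(self, inv_base: str, sub_base: str) -> float:
        kind = pair_kind(inv_base, sub_base)
        if kind is ColumnKind.WC:
            return self.wc
        if kind is ColumnKind.WOBBLE:
            return self.wobble
        return self.mismatch


@dataclass(frozen=True)
class DuplexAlignment:
    """Columns ordered from the nucleation site toward the hairpin base.

    Invader positions strictly increase along the list; substrate positions
    strictly decrease (antiparallel pairing).
    """

    columns: tuple[DuplexColumn, ...]
    score: float

    @property
    def paired_columns(self) -> tuple[DuplexColumn, ...]:
        return tuple(c for c in self.columns if c.paired)

    def n_paired(self) -> int:
        return len(self.paired_columns)


# traceback moves, in tie-break preference order: pairing beats gapping,
# and resolving pairs first at the distal end pushes bulges toward the
# nucleation end
_PAIR, _GAP_INV, _GAP_SUB = 0, 1, 2


def align_duplex(invader: RnaSequence | str, substrate: RnaSequence | str,
                 params: AlignParams | None = None) -> DuplexAlignment:
    """Globally align the invader against the substrate, antiparallel.

    ``substrate`` is given 5'->3'; its 3'-most nucleotide is the nucleation
    end and pairs (or bulges) opposite the invader's 5'-most nucleotide.
    Substrate left over at the distal (5') end is unscored and omitted from
    the columns. Deterministic: ties prefer pairing over gapping and place
    bulges as close to the nucleation end as possible.
    """
    params = params or AlignParams()
    inv = invader if isinstance(invader, RnaSequence) else RnaSequence(invader)
    sub = substrate if isinstance(substrate, RnaSequence) else RnaSequence(substrate)
    n, m = len(inv), len(sub)
    # s[j] = substrate base at column j from the nucleation (3') end
    s = sub[::-1]

    NEG = float("-inf")
    dp = [[NEG] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = 0.0
    for j in range(1, m + 1):
        dp[0][j] = params.gap * j
    for i in range(1, n + 1):
        dp[i][0] = params.gap * i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i][j] = max(
                dp[i - 1][j - 1] + params.pair_score(inv[i - 1], s[j - 1]),
                dp[i - 1][j] + params.gap,
                dp[i][j - 1] + params.gap,
            )

    # free trailing substrate: best alignment consuming the whole invader
    best = max(dp[n])
    j_end = min(j for j in range(m + 1) if dp[n][j] == best)

    moves: list[int] = []
    i, j = n, j_end
    while i > 0 or j > 0:
        here = dp[i][j]
        if (i > 0 and j > 0
                and here == dp[i - 1][j - 1] + params.pair_score(inv[i - 1], s[j - 1])):
            moves.append(_PAIR)
            i, j = i - 1, j - 1
        elif i > 0 and here == dp[i - 1][j] + params.gap:
            moves.append(_GAP_INV)
            i -= 1
        else:
            moves.append(_GAP_SUB)
            j -= 1
    moves.reverse()

    columns: list[DuplexColumn] = []
    i = j = 0  # consumed counts
    for mv in moves:
        if mv == _PAIR:
            ib, sb = inv[i], s[j]
            columns.append(DuplexColumn(pair_kind(ib, sb), i + 1, m - j,
                                        invader_base=ib, substrate_base=sb))
            i, j = i + 1, j + 1
        elif mv == _GAP_INV:
            columns.append(DuplexColumn(ColumnKind.BULGE_INVADER, i + 1, None,
                                        invader_base=inv[i]))
            i += 1
        else:
            columns.append(DuplexColumn(ColumnKind.BULGE_SUBSTRATE, None, m - j,
                                        substrate_base=s[j]))
            j += 1
    return DuplexAlignment(tuple(columns), best)


def substrate_window(construct: Construct,
                     params: AlignParams | None = None) -> tuple[RnaSequence, int]:
    """Substrate span the invader is aligned against.

    The window ends at P3's 3' terminus (invasion nucleates there and
    proceeds through the pseudoknot) and extends 5' far enough to absorb the
    invader plus gap slack. Returns (sequence 5'->3', start position).
    """
    params = params or AlignParams()
    p3 = construct.require_region("P3")
    inv = construct.require_region("invader")
    length = len(inv) + params.slack
    start = max(1, p3.end - length + 1)
    return construct.subseq(start, p3.end), start


def align_construct(construct: Construct,
                    params: AlignParams | None = None) -> DuplexAlignment:
    """Align the construct's annotated invader against its substrate window,
    with columns carrying absolute (construct) coordinates."""
    params = params or AlignParams()
    inv = construct.require_region("invader")
    invader_seq = construct.subseq(inv.start, inv.end)
    window_seq, window_start = substrate_window(construct, params)
    aln = align_duplex(invader_seq, window_seq, params)
    columns = tuple(
        DuplexColumn(
            c.kind,
            None if c.invader_pos is None else inv.start + c.invader_pos - 1,
            None if c.substrate_pos is None else window_start + c.substrate_pos - 1,
            c.invader_base,
            c.substrate_base,
        )
        for c in aln.columns
    )
    return DuplexAlignment(columns, aln.score)


# ---------------------------------------------------------------------------
# noncomplementary elements


#: phenomenological annotation bands along the hairpin; labels only, never
#: used in any computation
ON_TUNEBOX_MAX_R = 5
LEAK_TUNEBOX_BASE_DIST = 6


@dataclass(frozen=True)
class DuplexElement:
    """A maximal run of adjacent noncomplementary columns of one kind."""

    kind: ColumnKind
    invader_positions: tuple[int, ...]
    substrate_positions: tuple[int, ...]
    r: int
    tunebox: str = "variable region"

    def span(self) -> int:
        return max(len(self.invader_positions), len(self.substrate_positions))


def annotate_elements(alignment: DuplexAlignment,
                      construct: Construct) -> list[DuplexElement]:
    """Group noncomplementary columns into elements, attach the barrier
    index r of each element's 5'-most invader-side column, and sort by r
    ascending.

    Adjacent MISMATCH or BULGE columns of the same kind coalesce into a
    single element (physically one internal loop or one multi-nt bulge);
    wobble columns remain individual elements — a G:U wobble is still a base
    pair, and adjacent wobbles are distinct pairs.
    """
    inv = construct.require_region("invader")

    runs: list[list[DuplexColumn]] = []
    prev_kind = None
    for idx, col in enumerate(alignment.columns):
        if col.kind is ColumnKind.WC:
            prev_kind = None
            continue
        if (col.kind is prev_kind and col.kind is not ColumnKind.WOBBLE
                and runs):
            runs[-1].append(col)
        else:
            runs.append([col])
        prev_kind = col.kind

    elements = []
    for run in runs:
        inv_pos = tuple(c.invader_pos for c in run if c.invader_pos is not None)
        sub_pos = tuple(c.substrate_pos for c in run if c.substrate_pos is not None)
        if inv_pos:
            anchor = min(inv_pos)
        else:
            anchor = _flanking_invader_pos(alignment.columns, run[0])
        r = anchor - inv.start + 1
        if r <= ON_TUNEBOX_MAX_R:
            tunebox = "ON-state tunebox"
        elif inv.end - anchor < LEAK_TUNEBOX_BASE_DIST:
            tunebox = "leak tunebox"
        else:
            tunebox = "variable region"
        elements.append(DuplexElement(run[0].kind, inv_pos, sub_pos, r, tunebox))
    return sorted(elements, key=lambda e: e.r)


def _adjacent(columns: tuple[DuplexColumn, ...], idx: int) -> bool:
    return idx > 0 and columns[idx - 1].kind is columns[idx].kind


def _flanking_invader_pos(columns: tuple[DuplexColumn, ...],
                          col: DuplexColumn) -> int:
    idx = columns.index(col)
    for j in range(idx - 1, -1, -1):  # nucleation-side flank first
        if columns[j].invader_pos is not None:
            return columns[j].invader_pos
    for j in range(idx + 1, len(columns)):
        if columns[j].invader_pos is not None:
            return columns[j].invader_pos
    raise DomainError("alignment has no invader-side column")


def nucleating_pair(alignment: DuplexAlignment) -> tuple[int, int]:
    """The first paired (non-bulge) column from the nucleation end, as
    (substrate_pos, invader_pos) — e.g. the C100:G108 terminator nucleating
    pair of the reference construct."""
    for col in alignment.columns:
        if col.paired:
            return (col.substrate_pos, col.invader_pos)
    raise DomainError("degenerate alignment: no paired column")


# ---------------------------------------------------------------------------
# poly-U tracts and architecture


def find_polyU(sequence: RnaSequence | str, min_len: int = 5) -> list[Region]:
    """Maximal runs of U of length >= min_len, in 5'->3' order."""
    if min_len < 1:
        raise DomainError("min_len must be >= 1")
    seq = str(sequence).upper().replace("T", "U")
    regions = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "U":
            j = i
            while j < n and seq[j] == "U":
                j += 1
            if j - i >= min_len:
                regions.append(Region("polyU", i + 1, j))
            i = j
        else:
            i += 1
    return regions


class Architecture(Enum):
    LOOP_PLUS_INVADER = "LOOP_PLUS_INVADER"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ArchitectureParams:
    min_stem: int = 8          # minimum paired columns in the duplex
    min_loop: int = 3          # apical loop length bounds
    max_loop: int = 12
    max_gap: int = 2           # nt between invader 3' end and poly-U start


def classify_architecture(construct: Construct,
                          params: ArchitectureParams | None = None,
                          align_params: AlignParams | None = None
                          ) -> Architecture:
    """Does the construct share the reference loop + invader terminator
    architecture? Requires a sufficiently long stem, an apical loop of
    ordinary size, and a poly-U tract flush against the invader."""
    params = params or ArchitectureParams()
    inv = construct.require_region("invader")
    pu = construct.require_region("polyU")
    aln = align_construct(construct, align_params)
    if aln.n_paired() < params.min_stem:
        return Architecture.OTHER
    sub_pos, _ = nucleating_pair(aln)
    loop_len = inv.start - sub_pos - 1
    if not params.min_loop <= loop_len <= params.max_loop:
        return Architecture.OTHER
    if pu.start - inv.end - 1 > params.max_gap:
        return Architecture.OTHER
    return Architecture.LOOP_PLUS_INVADER


# ---------------------------------------------------------------------------
# hairpin stability (reduced nearest-neighbor model)

RT37 = 0.001987 * 310.15  # kcal/mol

#: Watson-Crick nearest-neighbor stack free energies at 37 C (kcal/mol),
#: keyed "XY/ZW" for 5'-XY-3' over 3'-ZW-5' (pairs X:Z and Y:W)
WC_STACKS = {
    "AA/UU": -0.93, "AU/UA": -1.10, "UA/AU": -1.33, "CU/GA": -2.08,
    "CA/GU": -2.11, "GU/CA": -2.24, "GA/CU": -2.35, "CG/GC": -2.36,
    "GG/CC": -3.26, "GC/CG": -3.42,
}

#: reduced treatment of stacks containing a G:U wobble: one representative
#: stabilizing value (the model needs a sane ranking, not full resolution)
WOBBLE_STACK = -1.2

HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
INTERNAL_INIT = {2: 1.0, 3: 1.8, 4: 1.1, 5: 2.0, 6: 1.9}
TERMINAL_AU_GU = 0.45


def _loop_penalty(table: dict[int, float], n: int) -> float:
    n = max(n, min(table))
    if n in table:
        return table[n]
    nmax = max(table)
    return table[nmax] + 1.75 * RT37 * math.log(n / nmax)


def stack_energy(inv5: str, sub5: str, inv3: str, sub3: str) -> float:
    """Free energy of stacking pair (inv5:sub5) on (inv3:sub3), the former
    closer to the apical loop; the invader strand runs 5'->3' loop-to-base."""
    kinds = {pair_kind(inv5, sub5), pair_kind(inv3, sub3)}
    if ColumnKind.MISMATCH in kinds:
        raise DomainError("stack requires two paired columns")
    if ColumnKind.WOBBLE in kinds:
        return WOBBLE_STACK
    key = f"{inv5}{inv3}/{sub5}{sub3}"
    alt = f"{sub3}{sub5}/{inv3}{inv5}"
    return WC_STACKS.get(key, WC_STACKS.get(alt, 0.0))


@dataclass(frozen=True)
class HairpinEnergy:
    delta_g: float  # kcal/mol at 37 C


def hairpin_delta_g(alignment: DuplexAlignment,
                    loop_seq: RnaSequence | str) -> HairpinEnergy:
    """Reduced nearest-neighbor free energy of the annotated hairpin.

    Sums WC/wobble stack terms over uninterrupted paired steps, a hairpin
    loop initiation for the apical loop, bulge penalties (single bulges keep
    the flanking stack), and internal-loop penalties where mismatched columns
    interrupt the stem. A terminal A:U or G:U pair at the hairpin base pays
    the standard end penalty.
    """
    if not alignment.columns:
        raise DomainError("empty alignment")
    cols = alignment.columns
    # only WC/wobble columns stack; mismatches interrupt the stem
    paired_idx = [i for i, c in enumerate(cols)
                  if c.kind in (ColumnKind.WC, ColumnKind.WOBBLE)]
    if not paired_idx:
        raise DomainError("degenerate alignment: no paired column")

    dg = _loop_penalty(HAIRPIN_INIT, len(str(loop_seq)))
    for a, b in zip(paired_idx, paired_idx[1:]):
        between = cols[a + 1:b]
        n_mm = sum(c.kind is ColumnKind.MISMATCH for c in between)
        n_bi = sum(c.kind is ColumnKind.BULGE_INVADER for c in between)
        n_bs = sum(c.kind is ColumnKind.BULGE_SUBSTRATE for c in between)
        pa, pb = cols[a], cols[b]
        if n_mm:
            size = 2 * n_mm + n_bi + n_bs
            dg += _loop_penalty(INTERNAL_INIT, size)
        elif n_bi + n_bs == 0:
            dg += stack_energy(pa.invader_base, pa.substrate_base,
                               pb.invader_base, pb.substrate_base)
        elif n_bi + n_bs == 1:
            dg += stack_energy(pa.invader_base, pa.substrate_base,
                               pb.invader_base, pb.substrate_base)
            dg += _loop_penalty(BULGE_INIT, 1)
        else:
            dg += _loop_penalty(BULGE_INIT, n_bi + n_bs)
    base = cols[paired_idx[-1]]
    if pair_kind(base.invader_base, base.substrate_base) is not ColumnKind.WC \
            or {base.invader_base, base.substrate_base} == {"A", "U"}:
        dg += TERMINAL_AU_GU
    return HairpinEnergy(dg)


def dot_bracket(alignment: DuplexAlignment, loop_len: int) -> str:
    """Dot-bracket string of the annotated hairpin: substrate arm, apical
    loop, invader arm (nucleation-proximal pairs innermost)."""
    sub_arm = "".join(
        "(" if c.paired else "." for c in reversed(alignment.columns)
        if c.substrate_pos is not None
    )
    inv_arm = "".join(
        ")" if c.paired else "." for c in alignment.columns
        if c.invader_pos is not None
    )
    return sub_arm + "." * loop_len + inv_arm
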