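"""Expression-platform curation, chimera construction, and flipped-logic
OFF-switch design.

Curation applies the filters used to narrow genus-wide candidates: a poly-U
tract of at least 5 Us inside the expression platform, a P3 sequence
identical to the reference (exact string match — gapped near-identity is
rejected), and the reference loop + invader terminator architecture.

The flip design inserts an 8-nt "flipping domain" between the terminator
hairpin and the poly-U tract. Ligand absent, the domain is a spacer that
ablates intrinsic termination; ligand bound, it pairs with the leftover
invader suffix to form a synthetic terminator flush against the poly-U,
inverting the switch's logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Construct, DomainError, Region, RnaSequence
from .duplex import (AlignParams, Architecture, ArchitectureParams,
                     align_duplex, classify_architecture, find_polyU)
from .mutagenesis import MutationKind, MutationSpec, apply_mutation


@dataclass(frozen=True)
class CandidateVerdict:
    construct_id: str
    polyU_pass: bool
    P3_identical_pass: bool
    architecture_pass: bool

    @property
    def passed(self) -> bool:
        return self.polyU_pass and self.P3_identical_pass and self.architecture_pass


@dataclass(frozen=True)
class CurationReport:
    verdicts: tuple[CandidateVerdict, ...]
    surviving: tuple[Construct, ...]


def curate_eps(candidates: list[Construct], reference: Construct,
               min_polyU: int = 5,
               arch_params: ArchitectureParams | None = None,
               align_params: AlignParams | None = None) -> CurationReport:
    """Filter candidate expression platforms against the reference.

    Filters are applied in order (poly-U, identical P3, architecture); a
    candidate lacking required annotations fails the corresponding verdicts
    rather than raising. Verdicts are independent of candidate order.
    """
    ref_p3_region = reference.require_region("P3")
    ref_p3 = reference.subseq(ref_p3_region.start, ref_p3_region.end)

    verdicts = []
    surviving = []
    for cand in candidates:
        p3 = cand.region("P3")
        inv = cand.region("invader")
        pu = cand.region("polyU")

        # poly-U: a >= min_polyU tract anywhere in the EP (3' of P3)
        if p3 is not None and p3.end < len(cand.sequence):
            ep_seq = cand.subseq(p3.end + 1, len(cand.sequence))
            polyU_pass = bool(find_polyU(ep_seq, min_polyU))
        else:
            polyU_pass = False

        p3_pass = (p3 is not None
                   and str(cand.subseq(p3.start, p3.end)) == str(ref_p3))

        if p3 is not None and inv is not None and pu is not None:
            arch_pass = classify_architecture(
                cand, arch_params, align_params) is Architecture.LOOP_PLUS_INVADER
        else:
            arch_pass = False

        verdict = CandidateVerdict(cand.id, polyU_pass, p3_pass, arch_pass)
        verdicts.append(verdict)
        if verdict.passed:
            surviving.append(cand)
    return CurationReport(tuple(verdicts), tuple(surviving))


def build_chimera(reference: Construct, foreign_invader: RnaSequence | str,
                  chimera_id: str) -> Construct:
    """Fuse the reference aptamer (and 5' expression platform, through the
    apical loop) with a foreign invader; the reference poly-U tract and any
    downstream sequence are retained."""
    foreign = (foreign_invader if isinstance(foreign_invader, RnaSequence)
               else RnaSequence(foreign_invader))
    inv = reference.require_region("invader")
    pu = reference.require_region("polyU")
    seq = str(reference.sequence)
    new_seq = (seq[:inv.start - 1] + str(foreign) + seq[pu.start - 1:])

    shift = len(foreign) - len(inv)
    regions = []
    for reg in reference.regions:
        if reg.end < inv.start:
            regions.append(reg)
        elif reg.name == "invader":
            regions.append(Region("invader", inv.start,
                                  inv.start + len(foreign) - 1))
        elif reg.start >= pu.start:
            regions.append(reg.shifted(shift))
        # regions overlapping the replaced span are dropped
    return Construct(chimera_id, RnaSequence(new_seq), tuple(regions))


@dataclass(frozen=True)
class FlipDesign:
    """A flipped-logic OFF-switch built from an ON-switch parent."""

    parent: Construct
    construct: Construct
    flipping_domain: RnaSequence
    insertion_point: int       # residue immediately 5' of the insertion
    apo_spacer_len: int        # nt between WT hairpin base and poly-U
    holo_stem_len: int         # paired columns of the synthetic terminator
    holo_stem_elements: int    # noncomplementary elements in that stem
    apo_termination_ablated: bool
    barrier: MutationSpec | None = None
    barrier_r: int | None = None
    barrier_size: int | None = None


#: spacer length at which intrinsic termination is heuristically called
#: ablated; reported only, never used in any fit
SPACER_ABLATION_THRESHOLD = 8


def design_flip(parent: Construct, domain_len: int = 8,
                domain_seq: RnaSequence | str | None = None,
                align_params: AlignParams | None = None) -> FlipDesign:
    """Insert a flipping domain between the terminator hairpin 3' end and
    the poly-U tract.

    By default the domain is the reverse complement of the ``domain_len``-nt
    suffix of the invader — the portion of the expression platform left
    single-stranded when strand displacement of the aptamer fails — so the
    holo-state synthetic terminator is a perfect duplex of that length. An
    explicit ``domain_seq`` overrides the default.
    """
    inv = parent.require_region("invader")
    parent.require_region("polyU")
    if domain_len < 1:
        raise DomainError("flipping domain must be at least 1 nt")
    if domain_len > len(inv):
        raise DomainError(
            f"domain_len {domain_len} exceeds invader length {len(inv)}")

    suffix = parent.subseq(inv.end - domain_len + 1, inv.end)
    if domain_seq is None:
        domain = suffix.reverse_complement()
    else:
        domain = (domain_seq if isinstance(domain_seq, RnaSequence)
                  else RnaSequence(domain_seq))
        if len(domain) != domain_len:
            raise DomainError("explicit domain_seq length != domain_len")

    spec = MutationSpec(MutationKind.INSERTION, inv.end, str(domain))
    flipped = apply_mutation(parent, spec)
    # the insertion sits after the invader's last residue, so no parent
    # region stretches; name the inserted span
    regions = list(flipped.regions)
    regions.append(Region("flipping_domain", inv.end + 1,
                          inv.end + len(domain)))
    flipped = Construct(parent.id + "_flip", flipped.sequence,
                        tuple(sorted(regions, key=lambda r: r.start)))

    holo = align_duplex(domain, suffix, align_params)
    from .duplex import ColumnKind
    holo_elements = sum(c.kind is not ColumnKind.WC for c in holo.columns)
    spacer = len(domain)
    return FlipDesign(
        parent=parent,
        construct=flipped,
        flipping_domain=domain,
        insertion_point=inv.end,
        apo_spacer_len=spacer,
        holo_stem_len=holo.n_paired(),
        holo_stem_elements=holo_elements,
        apo_termination_ablated=spacer >= SPACER_ABLATION_THRESHOLD,
    )


def tune_flip(design: FlipDesign, barrier_spec: MutationSpec,
              align_params: AlignParams | None = None) -> FlipDesign:
    """Add a kinetic barrier to the parent invader of a flip design.

    The barrier is applied to the parent *before* the flipping-domain
    insertion (so the synthetic terminator is recomputed against the mutated
    invader). The barrier must target the invader, not the flipping domain.
    """
    parent = design.parent
    inv = parent.require_region("invader")
    pos = barrier_spec.position
    if not inv.contains(pos):
        raise DomainError(
            f"barrier at {pos} lies outside the parent invader "
            f"[{inv.start},{inv.end}] (flipping-domain edits are not barriers)")

    mutated = apply_mutation(parent, barrier_spec)
    mutated = mutated.with_id(parent.id)
    new_design = design_flip(mutated, domain_len=len(design.flipping_domain),
                             align_params=align_params)
    r = pos - inv.start + 1
    if barrier_spec.kind is MutationKind.INSERTION:
        size = len(barrier_spec.alt)
    elif barrier_spec.kind is MutationKind.DELETION:
        size = 1
    else:
        size = 1
    return FlipDesign(
        parent=parent,
        construct=new_design.construct.with_id(
            design.construct.id + "+" + _barrier_label(barrier_spec)),
        flipping_domain=new_design.flipping_domain,
        insertion_point=new_design.insertion_point,
        apo_spacer_len=new_design.apo_spacer_len,
        holo_stem_len=new_design.holo_stem_len,
        holo_stem_elements=new_design.holo_stem_elements,
        apo_termination_ablated=new_design.apo_termination_ablated,
        barrier=barrier_spec,
        barrier_r=r,
        barrier_size=size,
    )


def _barrier_label(spec: MutationSpec) -> str:
    if spec.kind is MutationKind.DELETION:
        return f"del{spec.position}"
    if spec.kind is MutationKind.INSERTION:
        return f"{spec.position}ins{spec.alt}"
    return f"{spec.position}{spec.alt}"
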