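"""Domain types and coordinate conventions shared by every analysis stage.

Coordinates are 1-based closed intervals numbered from the first transcribed
nucleotide, so residue labels match the mutation names used throughout
(A26, C100, G108, ...). All sequences are RNA internally; DNA input is
silently transcribed (T -> U) on ingest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: region vocabulary; "other" admits annotations outside the named set
REGION_NAMES = frozenset(
    {"P1", "J12", "P2", "PK", "linker", "P3", "loop", "invader",
     "polyU", "flipping_domain", "other"}
)

#: regions of which a construct may carry at most one copy
UNIQUE_REGIONS = ("P3", "invader", "polyU")


class AlphabetError(ValueError):
    """Sequence contains a character outside {A,C,G,U,T}."""


class FastaParseError(ValueError):
    """Malformed FASTA record."""


class RegionError(ValueError):
    """Region annotation violates the construct's coordinate invariants."""


class DomainError(ValueError):
    """An operation was applied outside its domain of validity."""


class RnaSequence(str):
    """A nonempty RNA string over {A,C,G,U}.

    DNA input is accepted: T is normalized to U and letters are upper-cased.
    Any other character raises :class:`AlphabetError` naming the 1-based
    offending position.
    """

    def __new__(cls, residues: str) -> "RnaSequence":
        normalized = str(residues).upper().replace("T", "U")
        if not normalized:
            raise AlphabetError("empty sequence")
        for i, ch in enumerate(normalized, start=1):
            if ch not in RNA_ALPHABET:
                raise AlphabetError(
                    f"illegal character {ch!r} at position {i}"
                )
        return super().__new__(cls, normalized)

    def base(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self):
            raise DomainError(f"position {pos} outside sequence of length {len(self)}")
        return self[pos - 1]

    def reverse_complement(self) -> "RnaSequence":
        return RnaSequence("".join(COMPLEMENT[b] for b in reversed(self)))

    def complement(self) -> "RnaSequence":
        return RnaSequence("".join(COMPLEMENT[b] for b in self))


@dataclass(frozen=True)
class Region:
    """A named 1-based closed interval on a construct."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise RegionError(f"unknown region name {self.name!r}")
        if not 1 <= self.start <= self.end:
            raise RegionError(
                f"region {self.name}: invalid interval [{self.start},{self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def shifted(self, offset: int) -> "Region":
        return Region(self.name, self.start + offset, self.end + offset)


@dataclass(frozen=True)
class BarrierIndex:
    """Distance r (nt) of a position from the strand-displacement nucleation
    site, counting the nucleating invader nucleotide as r = 1."""

    r: int

    def __post_init__(self) -> None:
        if self.r < 1:
            raise DomainError(f"barrier index must be >= 1, got {self.r}")


# regions whose mutual overlap is tolerated (stem nests inside the aptamer span)
_NESTABLE = {frozenset({"P1", "P2"}), frozenset({"P3", "PK"})}


@dataclass(frozen=True)
class Construct:
    """An annotated riboswitch sequence.

    Enforces the architectural ordering the folding model assumes: the
    invader lies 3' of the P3 stem it displaces, and the poly-U tract lies
    3' of the invader.
    """

    id: str
    sequence: RnaSequence
    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        n = len(self.sequence)
        for reg in self.regions:
            if reg.end > n:
                raise RegionError(
                    f"region {reg.name} [{reg.start},{reg.end}] exceeds "
                    f"sequence length {n}"
                )
        for name in UNIQUE_REGIONS:
            if sum(r.name == name for r in self.regions) > 1:
                raise RegionError(f"region {name} annotated more than once")
        p3, inv, pu = (self.region(n) for n in UNIQUE_REGIONS)
        if p3 and inv and not p3.end < inv.start:
            raise RegionError("invader must lie 3' of P3")
        if inv and pu and not inv.end < pu.start:
            raise RegionError("polyU must lie 3' of the invader")
        named = [r for r in self.regions if r.name != "other"]
        for i, a in enumerate(named):
            for b in named[i + 1:]:
                if a.start <= b.end and b.start <= a.end:
                    if frozenset({a.name, b.name}) not in _NESTABLE:
                        raise RegionError(
                            f"regions {a.name} and {b.name} overlap"
                        )

    def region(self, name: str) -> Region | None:
        for r in self.regions:
            if r.name == name:
                return r
        return None

    def require_region(self, name: str) -> Region:
        reg = self.region(name)
        if reg is None:
            raise DomainError(f"construct {self.id!r} lacks a {name} annotation")
        return reg

    def subseq(self, start: int, end: int) -> RnaSequence:
        """Inclusive 1-based slice."""
        if not 1 <= start <= end <= len(self.sequence):
            raise DomainError(f"slice [{start},{end}] out of bounds")
        return RnaSequence(self.sequence[start - 1:end])

    def with_id(self, new_id: str) -> "Construct":
        return replace(self, id=new_id)


# ---------------------------------------------------------------------------
# barrier-index mapping


def barrier_index(construct: Construct, paper_position: int) -> BarrierIndex:
    """Map a residue position inside the invader to its barrier index r.

    The nucleation-site anchor is the 5'-most invader nucleotide (the one
    forming the terminator nucleating pair), so r = pos - invader.start + 1.
    """
    inv = construct.require_region("invader")
    if not inv.contains(paper_position):
        raise DomainError(
            f"position {paper_position} outside invader [{inv.start},{inv.end}]"
        )
    return BarrierIndex(paper_position - inv.start + 1)


def position_of_index(construct: Construct, index: BarrierIndex | int) -> int:
    """Inverse of :func:`barrier_index`."""
    r = index.r if isinstance(index, BarrierIndex) else int(index)
    inv = construct.require_region("invader")
    pos = inv.start + r - 1
    if not inv.contains(pos):
        raise DomainError(f"barrier index {r} outside invader span")
    return pos


# ---------------------------------------------------------------------------
# sequence I/O


def load_fasta(path) -> list[tuple[str, RnaSequence]]:
    """Read FASTA records, normalizing to the RNA alphabet.

    Ids are preserved verbatim; an illegal character raises
    :class:`AlphabetError` naming the record and position.
    """
    records = []
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            try:
                records.append((rec.id, RnaSequence(str(rec.seq))))
            except AlphabetError as exc:
                raise AlphabetError(f"record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    seqrecords = [
        SeqRecord(Seq(str(seq)), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, "fasta-2line")


def load_construct(sequence, region_config: dict, construct_id: str = "construct"
                   ) -> Construct:
    """Build a Construct from a sequence and named 1-based closed intervals.

    ``region_config`` maps region name -> (start, end) (or {"start":, "end":}).
    Unspecified regions are simply omitted.
    """
    seq = sequence if isinstance(sequence, RnaSequence) else RnaSequence(sequence)
    regions = []
    for name, interval in region_config.items():
        if isinstance(interval, dict):
            start, end = int(interval["start"]), int(interval["end"])
        else:
            start, end = int(interval[0]), int(interval[1])
        regions.append(Region(name, start, end))
    return Construct(construct_id, seq, tuple(regions))


# ---------------------------------------------------------------------------
# measurement tables

MEASUREMENT_COLUMNS = [
    "construct_id",
    "ligand_conc",
    "experimental_rep",
    "biological_rep",
    "fluorescence_raw",
    "od600_raw",
    "is_blank",
]


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a well-level measurement table.

    Blank wells must carry an empty construct_id; ligand concentrations are
    in mM and must be nonnegative.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"measurement table missing columns: {missing}")
    out = df[MEASUREMENT_COLUMNS].copy()
    out["construct_id"] = out["construct_id"].fillna("").astype(str)
    out["ligand_conc"] = out["ligand_conc"].astype(float)
    out["experimental_rep"] = out["experimental_rep"].astype(int)
    out["biological_rep"] = out["biological_rep"].astype(int)
    out["fluorescence_raw"] = out["fluorescence_raw"].astype(float)
    out["od600_raw"] = out["od600_raw"].astype(float)
    out["is_blank"] = out["is_blank"].astype(bool)
    if (out["ligand_conc"] < 0).any():
        raise DomainError("ligand_conc must be >= 0")
    if (out.loc[out["is_blank"], "construct_id"] != "").any():
        raise DomainError("blank rows must have an empty construct_id")
    return out


def write_measurement_csv(df: pd.DataFrame, path_or_buf) -> None:
    """Comma-separated, header row, UTF-8 — the fixed dialect used everywhere."""
    validate_measurements(df).to_csv(path_or_buf, index=False)


def read_measurement_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, keep_default_na=False,
                     na_values=[], dtype={"construct_id": str})
    df["is_blank"] = df["is_blank"].astype(str).str.lower().isin(
        {"true", "1", "t"})
    return validate_measurements(df)


def measurements_to_csv_string(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_measurement_csv(df, buf)
    return buf.getvalue()
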