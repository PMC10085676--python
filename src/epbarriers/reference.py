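"""Synthetic reference construct for the *Clostridium beijerinckii pfl* ZTP
riboswitch expression platform.

The published construct sequence is distributed only in supplementary files,
so this module ships a SYNTHETIC 134-nt stand-in designed to reproduce every
printed structural property of the wildtype expression platform:

* terminator nucleating base pair C100:G108;
* invader span 108-126, 3' of the P3 stem, followed immediately by an
  8-U poly-U tract (127-134);
* five noncomplementary elements in the invader-vs-substrate duplex —
  three G:U wobble pairs (U111 vs G97, G112 vs U96, G121 vs U89) and two
  single-nucleotide invader bulges (U115 and C118);
* barrier-index anchor: a bulge at index 3 inserts between C110 and C111;
* a 7-nt apical loop (101-107) between the P3 3' terminus and the invader;
* A at position 26 (the A26del pseudoknot deletion is the broken-OFF
  control);
* perfect-invader correction = 3 substitutions (U111C, G112A, G121A) plus
  2 deletions (U115del, C118del).

Everything upstream of the substrate span (positions 1-83) is filler with
the right alphabet and no confounding poly-U tracts. Do not mistake this
for the organism's genomic sequence.
"""

from __future__ import annotations

from .core import Construct, Region, RnaSequence

# 1-83: synthetic aptamer-side filler (A at position 26)
_UPSTREAM = (
    "GGAGCGCUUG"  # 1-10
    "CAGGCAACCU"  # 11-20
    "GGUAAACGGC"  # 21-30
    "UAGCGGUCAG"  # 31-40
    "GCCUGAUCGG"  # 41-50
    "CAAGCAGGAU"  # 51-60
    "CGCUGCAAUG"  # 61-70
    "CCAGCCGAAG"  # 71-80
    "CAG"         # 81-83
)
# 84-100: substrate span (pseudoknot + P3 3' arm, ends at P3 3' terminus)
_SUBSTRATE = "AGAGCUUUUGUUUGGGC"
# 101-107: apical loop of the terminator hairpin
_LOOP = "GCAAAGC"
# 108-126: invader (G108 nucleates against C100)
_INVADER = "GCCUGAAUCACAAGGCUCU"
# 127-134: poly-U tract
_POLYU = "UUUUUUUU"

WT_SEQUENCE = RnaSequence(_UPSTREAM + _SUBSTRATE + _LOOP + _INVADER + _POLYU)

WT_REGIONS = (
    Region("PK", 84, 89),
    Region("P3", 90, 100),
    Region("loop", 101, 107),
    Region("invader", 108, 126),
    Region("polyU", 127, 134),
)


def wt_construct() -> Construct:
    """The synthetic wildtype-like reference construct."""
    return Construct("Cbe_pfl_WT_synthetic", WT_SEQUENCE, WT_REGIONS)
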