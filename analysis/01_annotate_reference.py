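#!/usr/bin/env python
"""Annotate the reference expression-platform duplex.

Aligns the invader of the reference construct against its substrate span
(P3 3' arm + pseudoknot), classifies the noncomplementary elements that act
as kinetic barriers to strand displacement, and scores the terminator
hairpin with the reduced nearest-neighbor model.

Writes results/wt_elements.csv and results/wt_duplex_columns.csv.
"""

from pathlib import Path

import pandas as pd

import epbarriers as ep
from epbarriers.duplex import dot_bracket, hairpin_delta_g

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    wt = ep.wt_construct()
    aln = ep.align_construct(wt)
    elements = ep.annotate_elements(aln, wt)

    cols = pd.DataFrame([{
        "kind": c.kind.value,
        "invader_pos": c.invader_pos, "substrate_pos": c.substrate_pos,
        "invader_base": c.invader_base, "substrate_base": c.substrate_base,
    } for c in aln.columns])
    els = pd.DataFrame([{
        "kind": e.kind.value, "r": e.r,
        "invader_positions": ";".join(map(str, e.invader_positions)),
        "substrate_positions": ";".join(map(str, e.substrate_positions)),
        "tunebox": e.tunebox,
    } for e in elements])

    RESULTS.mkdir(exist_ok=True)
    cols.to_csv(RESULTS / "wt_duplex_columns.csv", index=False)
    els.to_csv(RESULTS / "wt_elements.csv", index=False)

    sub_pos, inv_pos = ep.nucleating_pair(aln)
    inv = wt.region("invader")
    loop_seq = wt.subseq(sub_pos + 1, inv.start - 1)
    dg = hairpin_delta_g(aln, loop_seq).delta_g

    print(f"reference construct: {wt.id} ({len(wt.sequence)} nt)")
    print(f"terminator nucleating pair: {wt.sequence.base(sub_pos)}{sub_pos}"
          f":{wt.sequence.base(inv_pos)}{inv_pos}")
    print(f"noncomplementary elements: {len(els)} "
          f"({(els.kind == 'WOBBLE').sum()} wobbles, "
          f"{(els.kind == 'BULGE_INVADER').sum()} invader bulges)")
    for e in elements:
        print(f"  r={e.r:>2} {e.kind.value:<14} "
              f"invader {e.invader_positions} [{e.tunebox}]")
    print(f"hairpin dG (reduced NN model): {dg:.2f} kcal/mol")
    print("dot-bracket:",
          dot_bracket(aln, inv.start - sub_pos - 1))


if __name__ == "__main__":
    main()
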