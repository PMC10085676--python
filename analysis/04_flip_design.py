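#!/usr/bin/env python
"""Design the flipped-logic OFF-switch and its barrier-tuned variants.

Inserts the 8-nt flipping domain after the terminator hairpin (ablating
apo-state termination by spacing the hairpin away from the poly-U tract),
then adds successively larger kinetic barriers at the strand-displacement
nucleation site — the G108 deletion, then di- and tri-nucleotide bulges
between positions 108 and 109 — the tuning series that progressively
suppresses leak in the flipped context.

Writes results/flip_designs.csv.
"""

from pathlib import Path

import pandas as pd

import epbarriers as ep
from epbarriers.mutagenesis import MutationKind, MutationSpec

RESULTS = Path(__file__).resolve().parents[1] / "results"

BARRIERS = [
    ("none", None),
    ("G108del", MutationSpec(MutationKind.DELETION, 108)),
    ("108insAA", MutationSpec(MutationKind.INSERTION, 108, "AA")),
    ("108insAAA", MutationSpec(MutationKind.INSERTION, 108, "AAA")),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    wt = ep.wt_construct()
    base = ep.design_flip(wt)

    rows = []
    for label, spec in BARRIERS:
        d = base if spec is None else ep.tune_flip(base, spec)
        rows.append({
            "design_id": d.construct.id,
            "barrier": label,
            "barrier_r": d.barrier_r,
            "barrier_size": d.barrier_size,
            "flipping_domain": str(d.flipping_domain),
            "apo_spacer_len": d.apo_spacer_len,
            "apo_termination_ablated": d.apo_termination_ablated,
            "holo_stem_len": d.holo_stem_len,
            "holo_stem_elements": d.holo_stem_elements,
            "length": len(d.construct.sequence),
            "sequence": str(d.construct.sequence),
        })
    df = pd.DataFrame(rows)
    df.drop(columns=["sequence"]).pipe(print)
    df.to_csv(RESULTS / "flip_designs.csv", index=False)
    print(f"\nflipping domain {base.flipping_domain} pairs the invader "
          f"suffix into a perfect {base.holo_stem_len}-bp synthetic "
          f"terminator; apo spacer {base.apo_spacer_len} nt -> "
          f"termination ablated: {base.apo_termination_ablated}")


if __name__ == "__main__":
    main()
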