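#!/usr/bin/env python
"""Curate candidate expression platforms and build aptamer-invader chimeras.

Builds a synthetic candidate panel around the reference (benign invader
variants plus three seeded defects), applies the curation filters — poly-U
tract of >= 5 Us, P3 identical to the reference, loop + invader terminator
architecture — and constructs chimeras that fuse the reference aptamer with
each surviving candidate's invader.

Writes results/curation.csv and results/chimeras.csv.
"""

from pathlib import Path

import pandas as pd

import epbarriers as ep
from epbarriers.mutagenesis import MutationKind, MutationSpec, apply_mutation

RESULTS = Path(__file__).resolve().parents[1] / "results"


def candidate_panel(wt):
    sub = lambda pos, alt, cid: apply_mutation(
        wt, MutationSpec(MutationKind.SUBSTITUTION, pos, alt)).with_id(cid)
    perfect, _ = ep.perfect_invader(wt)
    return [
        wt.with_id("cand_wt"),
        perfect.with_id("cand_perfect"),
        sub(110, "U", "cand_C110U"),        # the recurring purH-type wobble
        sub(112, "A", "cand_G112A"),
        sub(111, "C", "cand_U111C"),
        sub(114, "G", "cand_A114G"),
        ep.build_chimera(wt, invader_of(wt), "cand_identity_chimera"),
        sub(130, "A", "bad_polyU"),         # poly-U tract drops below 5 Us
        sub(95, "A", "bad_P3"),             # P3 no longer identical
        apply_mutation(wt, MutationSpec(
            MutationKind.INSERTION, 126, "ACG" * 7)).with_id("bad_spacer"),
    ]


def invader_of(construct) -> str:
    inv = construct.require_region("invader")
    return str(construct.subseq(inv.start, inv.end))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    wt = ep.wt_construct()
    panel = candidate_panel(wt)
    report = ep.curate_eps(panel, wt)

    pd.DataFrame([{
        "construct_id": v.construct_id, "polyU_pass": v.polyU_pass,
        "P3_identical_pass": v.P3_identical_pass,
        "architecture_pass": v.architecture_pass, "passed": v.passed,
    } for v in report.verdicts]).to_csv(RESULTS / "curation.csv", index=False)

    print(f"candidates: {len(panel)}, surviving: {len(report.surviving)}")
    for v in report.verdicts:
        flags = (f"polyU={'+' if v.polyU_pass else '-'} "
                 f"P3={'+' if v.P3_identical_pass else '-'} "
                 f"arch={'+' if v.architecture_pass else '-'}")
        print(f"  {v.construct_id:<24} {flags} "
              f"{'PASS' if v.passed else 'fail'}")

    rows = []
    for cand in report.surviving:
        chim = ep.build_chimera(wt, invader_of(cand), f"chimera_{cand.id}")
        elements = ep.annotate_elements(ep.align_construct(chim), chim)
        rows.append({
            "chimera_id": chim.id,
            "invader": invader_of(chim),
            "n_elements": len(elements),
            "element_rs": ";".join(str(e.r) for e in elements),
        })
    pd.DataFrame(rows).to_csv(RESULTS / "chimeras.csv", index=False)
    print(f"built {len(rows)} chimeras; noncomplementary-element counts: "
          f"{[r['n_elements'] for r in rows]}")


if __name__ == "__main__":
    main()
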