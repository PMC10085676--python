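#!/usr/bin/env python
"""Build the kinetic-barrier mutant libraries.

Generates the mismatch and deletion scans on the wildtype-like reference,
derives the perfectly complementary invader, and builds the bulge (A, AA,
AAA), wobble, mismatch and deletion scans on that perfect background — the
scaffold in which each barrier's effect is measured in isolation.

Writes results/scan_<name>.csv manifests and results/perfect_invader.csv.
"""

from pathlib import Path

import pandas as pd

import epbarriers as ep
from epbarriers.mutagenesis import (name_mutation, scan_bulge, scan_deletion,
                                    scan_mismatch, scan_wobble)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def manifest(lib) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": m.name, "r": m.r,
        "kind": m.specs[0].kind.value, "position": m.specs[0].position,
        "alt": m.specs[0].alt, "note": m.note,
        "sequence": str(m.construct.sequence),
    } for m in lib.mutants])


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    wt = ep.wt_construct()
    perfect, corrections = ep.perfect_invader(wt)

    pd.DataFrame([{
        "name": name_mutation(s, wt), "kind": s.kind.value,
        "position": s.position, "alt": s.alt,
    } for s in corrections]).to_csv(RESULTS / "perfect_invader.csv",
                                    index=False)
    print(f"perfect invader: {len(corrections)} corrective mutations "
          f"({', '.join(name_mutation(s, wt) for s in corrections)})")

    libraries = {
        "wt_mismatch": scan_mismatch(wt),
        "wt_deletion": scan_deletion(wt),
        "perfect_mismatch": scan_mismatch(perfect),
        "perfect_deletion": scan_deletion(perfect),
        "perfect_bulge1": scan_bulge(perfect, 1),
        "perfect_bulge2": scan_bulge(perfect, 2),
        "perfect_bulge3": scan_bulge(perfect, 3),
        "perfect_wobble": scan_wobble(perfect),
    }
    for name, lib in libraries.items():
        manifest(lib).to_csv(RESULTS / f"scan_{name}.csv", index=False)
        print(f"{name}: {len(lib)} mutants "
              f"(e.g. {', '.join(lib.names()[:3])}, ...)")


if __name__ == "__main__":
    main()
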