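#!/usr/bin/env python
"""Fit the quantitative models to the simulated assay.

Reads results/measurements.csv (from 05_simulate_assay.py), normalizes the
wells, fits the reference dose response, computes per-mutant ΔF_ON with the
saturation correction, fits the barrier power law ΔF_ON = B/r², and runs
Welch tests (with Bonferroni correction) of each mutant against the
reference at 1 mM.

Writes results/dose_response.csv, results/barrier_fit.csv and
results/stats.csv, and reports recovered vs true parameters.
"""

import json
from pathlib import Path

import pandas as pd

import epbarriers as ep
from epbarriers.core import read_measurement_csv
from epbarriers.quant import (barrier_points, bonferroni, fit_barrier_model,
                              fit_dose_response, fold_change, normalize,
                              values_at, welch_test)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_measurement_csv(RESULTS / "measurements.csv")
    manifest = pd.read_csv(RESULTS / "manifest.csv")
    truth = json.loads((RESULTS / "truth.json").read_text())
    out = normalize(table)

    # dose-response per construct
    dr_rows = []
    for cid, sub in out.groupby("construct_id"):
        fit = fit_dose_response(sub[["ligand_conc", "value"]].to_numpy())
        dr_rows.append({"construct_id": cid, "a": fit.a, "b": fit.b,
                        "ec50": fit.ec50, "se_ec50": fit.se_ec50,
                        "rss": fit.rss, "n": fit.n})
    dr = pd.DataFrame(dr_rows).sort_values("construct_id")
    dr.to_csv(RESULTS / "dose_response.csv", index=False)
    ref_fit = dr[dr.construct_id == "perfect"].iloc[0]
    print(f"reference fit: a={ref_fit.a:.1f} (true {truth['a']}), "
          f"b={ref_fit.b:.1f} (true {truth['b']}), "
          f"EC50={ref_fit.ec50:.4f} mM (true {truth['ec50_mM']})")

    # barrier power law with saturation-corrected ΔF_ON
    pts = barrier_points(out, manifest, "perfect", on_conc=1.0,
                         ec50=float(ref_fit.ec50))
    fit_rows = []
    for cls, p in pts.items():
        bf = fit_barrier_model(p)
        fit_rows.append({"mutation_class": cls, "B": bf.B, "se_B": bf.se_B,
                         "n_points": len(p), "negative_B": bf.negative_B})
        print(f"barrier fit [{cls}]: B={bf.B:.1f} ± {bf.se_B:.1f} "
              f"(true {truth['barrier_size']})")
    pd.DataFrame(fit_rows).to_csv(RESULTS / "barrier_fit.csv", index=False)

    # replicate statistics vs the reference at 1 mM
    ref_on = values_at(out, "perfect", 1.0)
    ref_leak = values_at(out, "perfect", 0.0)
    stat_rows, results = [], []
    for cid in manifest["construct_id"]:
        res = welch_test(values_at(out, cid, 1.0), ref_on)
        results.append(res)
        stat_rows.append({
            "construct_id": cid,
            "fold_change": fold_change(values_at(out, cid, 1.0),
                                       values_at(out, cid, 0.0)),
            "t": res.t, "df": res.df, "p": res.p, "tier": res.tier})
    for row, res in zip(stat_rows, bonferroni(results)):
        row["p_bonferroni"] = res.p_adj
    stats = pd.DataFrame(stat_rows)
    stats.to_csv(RESULTS / "stats.csv", index=False)

    ref_fc = fold_change(ref_on, ref_leak)
    print(f"reference fold change: {ref_fc:.1f}; "
          f"mutant fold changes {stats.fold_change.min():.1f}-"
          f"{stats.fold_change.max():.1f}")
    sig = stats[stats.p_bonferroni < 0.05]
    print(f"{len(sig)}/{len(stats)} mutants significant vs reference "
          f"after Bonferroni (alpha 0.05): {', '.join(sig.construct_id)}")


if __name__ == "__main__":
    main()
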