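"""End-to-end recovery pipelines tying the generator to the fits.

These helpers run the full analysis path — normalize the well table, fit
the reference dose response, form saturation-corrected ΔF_ON points, and
fit the barrier power law — exactly as the analysis drivers do, so
recovery studies measure the whole pipeline rather than a single fit.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .quant import (barrier_points, fit_barrier_model, fit_dose_response,
                    normalize)
from .synth import DEFAULT_CONCENTRATIONS, GroundTruth, make_recovery_suite


def barrier_estimate(table: pd.DataFrame, manifest: pd.DataFrame,
                     reference_id: str = "perfect", on_conc: float = 1.0
                     ) -> tuple[float, float]:
    """Run the full pipeline on one dataset.

    Returns (B_hat, ec50_hat): the reference EC50 is fitted from its dose
    series and used to rescale the finite-concentration ΔF_ON points onto
    the saturation scale before the closed-form power-law fit.
    """
    out = normalize(table)
    ref = out[out["construct_id"] == reference_id]
    ref_fit = fit_dose_response(ref[["ligand_conc", "value"]].to_numpy())
    pts = barrier_points(out, manifest, reference_id, on_conc=on_conc,
                         ec50=ref_fit.ec50)
    merged = [p for cls_pts in pts.values() for p in cls_pts]
    return fit_barrier_model(merged).B, ref_fit.ec50


def truth_manifest(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame([
        {"construct_id": cid, "mutation_class": bt.mutation_class, "r": bt.r}
        for cid, bt in truth.barrier.items()])


def stochastic_recovery(b_values=(100.0, 400.0, 1200.0),
                        r_values=(1, 2, 3, 4, 5, 6),
                        n_replicates: int = 20,
                        seed: int = 0,
                        concentrations=DEFAULT_CONCENTRATIONS
                        ) -> pd.DataFrame:
    """Seeded parameter-recovery study at the assay's default noise.

    For each barrier size B, ``n_replicates`` datasets are generated
    (reference + one mutant per r), each run through the full pipeline.
    Returns one row per B with the mean recovered B and EC50 and their
    relative errors.
    """
    base = GroundTruth(seed=seed)
    rows = []
    for b_val in b_values:
        suite = make_recovery_suite(
            b_values=(b_val,), r_values=r_values,
            n_replicates=n_replicates, base_truth=base,
            concentrations=concentrations)
        b_hats, ec50_hats = [], []
        for table, truth in suite:
            b_hat, ec50_hat = barrier_estimate(table, truth_manifest(truth))
            b_hats.append(b_hat)
            ec50_hats.append(ec50_hat)
        b_mean = sum(b_hats) / len(b_hats)
        e_mean = sum(ec50_hats) / len(ec50_hats)
        rows.append({
            "B_true": b_val,
            "B_mean": b_mean,
            "B_rel_err": abs(b_mean - b_val) / b_val,
            "ec50_true": base.ec50,
            "ec50_mean": e_mean,
            "ec50_rel_err": abs(e_mean - base.ec50) / base.ec50,
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows)


def noiseless_identity(seed: int = 0, b_value: float = 450.0,
                       r_values=(1, 2, 3, 4, 5, 6)) -> dict:
    """Noiseless full-pipeline identity: generated truth should be
    recovered to numerical precision."""
    from .synth import BarrierTruth, generate

    truth = GroundTruth(seed=seed, barrier={
        f"mut_r{r}": BarrierTruth("BULGE1", int(r), b_value)
        for r in r_values}).noiseless()
    table = generate(truth, ["perfect", *truth.barrier.keys()])
    out = normalize(table)
    ref = out[out["construct_id"] == "perfect"]
    ref_fit = fit_dose_response(ref[["ligand_conc", "value"]].to_numpy())
    b_hat, ec50_hat = barrier_estimate(table, truth_manifest(truth))
    return {
        "a_true": truth.a, "a_hat": ref_fit.a,
        "b_true": truth.b, "b_hat": ref_fit.b,
        "ec50_true": truth.ec50, "ec50_hat": ec50_hat,
        "B_true": b_value, "B_hat": b_hat,
    }
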