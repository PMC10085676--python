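"""Quantitative analysis of reporter-assay measurements.

Normalization follows the bulk-fluorescence protocol: subtract the plate's
mean blank fluorescence and OD600 from every sample well, then divide
corrected fluorescence by corrected OD. Dose response is the single-site
saturation curve

    normalized fluorescence = a + b [Z] / (EC50 + [Z])

(Hill coefficient fixed at 1), and the position dependence of kinetic
barrier mutants is summarized by the one-parameter power law

    ΔF_ON(r) = B / r²

where r is the barrier's distance in nucleotides from the strand-
displacement nucleation site and B is the fitted barrier size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import DomainError, validate_measurements


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries optimizer diagnostics."""


# ---------------------------------------------------------------------------
# normalization


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Blank-correct and OD-normalize a well-level measurement table.

    Returns non-blank rows with a ``value`` column equal to
    (F_raw - mean blank F) / (OD_raw - mean blank OD). Rows whose corrected
    OD is <= 0 are flagged invalid and excluded with a warning.
    """
    df = validate_measurements(table)
    blanks = df[df["is_blank"]]
    if blanks.empty:
        raise DomainError("measurement table has no blank wells")
    blank_f = blanks["fluorescence_raw"].mean()
    blank_od = blanks["od600_raw"].mean()

    samples = df[~df["is_blank"]].copy()
    samples["value"] = ((samples["fluorescence_raw"] - blank_f)
                        / (samples["od600_raw"] - blank_od))
    bad = samples["od600_raw"] - blank_od <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} well(s) with corrected OD <= 0 excluded",
            stacklevel=2)
        samples = samples[~bad]
    return samples.drop(columns=["is_blank"]).reset_index(drop=True)


def fold_change(values_high, values_low) -> float:
    """mean(high) / mean(low); the dynamic range between saturating-ligand
    and no-ligand conditions."""
    hi, lo = np.asarray(values_high, float), np.asarray(values_low, float)
    if hi.size == 0 or lo.size == 0:
        raise DomainError("fold_change requires nonempty groups")
    mh, ml = hi.mean(), lo.mean()
    if mh <= 0 or ml <= 0:
        raise DomainError("fold_change requires positive group means")
    return float(mh / ml)


def delta_f_on(mutant_values, reference_values) -> float:
    """Increase in ON-state signal of a mutant over the perfectly
    complementary reference: mean(mutant) - mean(reference). May be
    negative (wobble-to-WC direction)."""
    mut = np.asarray(mutant_values, float)
    ref = np.asarray(reference_values, float)
    if mut.size == 0 or ref.size == 0:
        raise DomainError("delta_f_on requires nonempty groups")
    return float(mut.mean() - ref.mean())


# ---------------------------------------------------------------------------
# replicate statistics

_TIER_ALPHAS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class StatResult:
    t: float
    df: float
    p: float
    p_adj: float
    tier: str

    def with_adjusted(self, p_adj: float) -> "StatResult":
        return StatResult(self.t, self.df, self.p, p_adj, self.tier)


def _tier(p: float) -> str:
    for alpha, stars in _TIER_ALPHAS:
        if p < alpha:
            return stars
    return "ns"


def welch_test(group_a, group_b) -> StatResult:
    """Two-tailed heteroscedastic (Welch) t-test with Welch-Satterthwaite
    degrees of freedom. Significance tiers are assigned from the
    pre-correction p value at alpha = 0.05/0.01/0.001/0.0001."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise DomainError("welch_test requires n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        t, df = 0.0, float(na + nb - 2)
    else:
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df) if se2 > 0 else 1.0
    return StatResult(float(t), float(df), float(p), float(p), _tier(p))


def bonferroni(results: list[StatResult], m: int | None = None
               ) -> list[StatResult]:
    """p_adj = min(1, p * m); tiers stay keyed to the unadjusted p, matching
    how the assay's significance was reported."""
    m = len(results) if m is None else m
    return [res.with_adjusted(min(1.0, res.p * m)) for res in results]


# ---------------------------------------------------------------------------
# dose response


@dataclass(frozen=True)
class DoseResponseFit:
    a: float
    b: float
    ec50: float
    se_a: float
    se_b: float
    se_ec50: float
    rss: float
    n: int

    def predict(self, conc) -> np.ndarray:
        z = np.asarray(conc, float)
        return self.a + self.b * z / (self.ec50 + z)


def fit_dose_response(points) -> DoseResponseFit:
    """Least-squares fit of a + b*Z/(EC50+Z) to (concentration, value)
    pairs.

    Initialization: a0 = min value, b0 = max - min, EC50_0 = geometric mean
    of the nonzero concentrations. Bounds: a >= 0, b unconstrained, EC50 > 0.
    Standard errors come from the covariance of the fit.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("points must be (conc, value) pairs")
    z, y = pts[:, 0], pts[:, 1]
    concs = np.unique(z)
    if concs.size < 3:
        raise DomainError("need >= 3 distinct concentrations")
    if 0.0 not in concs:
        raise DomainError("dose series must include the zero-ligand condition")

    nonzero = concs[concs > 0]
    p0 = [max(float(y.min()), 0.0),
          float(y.max() - y.min()),
          float(np.exp(np.log(nonzero).mean()))]

    def model(zz, a, b, ec50):
        return a + b * zz / (ec50 + zz)

    tiny = np.finfo(float).tiny
    try:
        popt, pcov = optimize.curve_fit(
            model, z, y, p0=p0,
            bounds=([0.0, -np.inf, tiny], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"dose-response fit did not converge: {exc}") from exc

    resid = y - model(z, *popt)
    rss = float(resid @ resid)
    se = np.sqrt(np.diag(pcov))
    return DoseResponseFit(float(popt[0]), float(popt[1]), float(popt[2]),
                           float(se[0]), float(se[1]), float(se[2]),
                           rss, int(y.size))


# ---------------------------------------------------------------------------
# kinetic-barrier power law


class MutationClass(Enum):
    BULGE1 = "BULGE1"
    BULGE2 = "BULGE2"
    BULGE3 = "BULGE3"
    MISMATCH = "MISMATCH"
    DELETION = "DELETION"
    WOBBLE = "WOBBLE"


@dataclass(frozen=True)
class BarrierFit:
    mutation_class: MutationClass | None
    B: float
    se_B: float
    rss: float
    points: tuple[tuple[float, float], ...]
    negative_B: bool = False


def fit_barrier_model(points,
                      mutation_class: MutationClass | None = None
                      ) -> BarrierFit:
    """Least-squares fit of ΔF_ON(r) = B / r².

    The single-parameter model has the closed form
    B = Σ ΔF_i r_i^-2 / Σ r_i^-4; SE(B) comes from the residual variance.
    B may come out negative (wobble-to-WC direction); such fits are flagged.
    """
    pts = [(float(r), float(df)) for r, df in points]
    if not pts:
        raise DomainError("fit_barrier_model requires >= 1 point")
    if any(r < 1 for r, _ in pts):
        raise DomainError("barrier positions r must be >= 1")
    r = np.array([p[0] for p in pts])
    dfv = np.array([p[1] for p in pts])
    x = r ** -2.0
    B = float((dfv * x).sum() / (x * x).sum())
    resid = dfv - B * x
    rss = float(resid @ resid)
    n = len(pts)
    if n > 1:
        se = math.sqrt(rss / (n - 1) / float((x * x).sum()))
    else:
        se = float("nan")
    return BarrierFit(mutation_class, B, se, rss, tuple(pts),
                      negative_B=B < 0)


# ---------------------------------------------------------------------------
# grouped pipeline helpers


def condition_means(normalized: pd.DataFrame,
                    per_replicate: bool = False) -> pd.DataFrame:
    """Mean and SD of normalized values per (construct, concentration).

    With ``per_replicate`` the means are taken per experimental replicate
    first (the alternative pooling the assay's replicate design admits).
    """
    keys = ["construct_id", "ligand_conc"]
    if per_replicate:
        reps = (normalized.groupby(keys + ["experimental_rep"])["value"]
                .mean().reset_index())
        grouped = reps.groupby(keys)["value"]
    else:
        grouped = normalized.groupby(keys)["value"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "value_mean", "std": "value_sd",
                               "count": "n"})


def values_at(normalized: pd.DataFrame, construct_id: str,
              conc: float) -> np.ndarray:
    sel = normalized[(normalized["construct_id"] == construct_id)
                     & (normalized["ligand_conc"] == conc)]
    return sel["value"].to_numpy()


def barrier_points(normalized: pd.DataFrame, manifest: pd.DataFrame,
                   reference_id: str, on_conc: float = 1.0,
                   pool_replicates: bool = False,
                   ec50: float | None = None
                   ) -> dict[str, list[tuple[float, float]]]:
    """Assemble (r, ΔF_ON) points per mutation class.

    ``manifest`` maps construct ids to (mutation_class, r). By default each
    mutant contributes its mean ΔF_ON (one point per mutant); with
    ``pool_replicates`` every replicate yields a point.

    ΔF_ON measured at a finite ligand concentration underestimates the
    saturation amplitude by the occupancy factor Z/(EC50+Z); passing an
    EC50 estimate (e.g. from the reference dose-response fit) rescales the
    points onto the saturation scale so the fitted B is concentration-free.
    """
    ref_vals = values_at(normalized, reference_id, on_conc)
    if ref_vals.size == 0:
        raise DomainError(f"no ON-state values for reference {reference_id!r}")
    scale = 1.0 if ec50 is None else (ec50 + on_conc) / on_conc
    out: dict[str, list[tuple[float, float]]] = {}
    for row in manifest.itertuples(index=False):
        vals = values_at(normalized, row.construct_id, on_conc)
        if vals.size == 0:
            continue
        cls = str(row.mutation_class)
        if pool_replicates:
            pts = [(float(row.r), scale * float(v - ref_vals.mean()))
                   for v in vals]
        else:
            pts = [(float(row.r), scale * delta_f_on(vals, ref_vals))]
        out.setdefault(cls, []).extend(pts)
    return out


# ---------------------------------------------------------------------------
# in vitro readthrough


def fraction_readthrough(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lane fraction readthrough AT / (AT + T) from a gel band table
    with columns lane, terminated, antiterminated."""
    required = {"lane", "terminated", "antiterminated"}
    if not required.issubset(table.columns):
        raise DomainError(f"gel band table needs columns {sorted(required)}")
    t = table["terminated"].astype(float)
    at = table["antiterminated"].astype(float)
    if (t < 0).any() or (at < 0).any():
        raise DomainError("band intensities must be >= 0")
    if ((t == 0) & (at == 0)).any():
        raise DomainError("lane with both band intensities zero")
    out = table[["lane"]].copy()
    out["fraction_readthrough"] = at / (at + t)
    return out
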