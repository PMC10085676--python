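"""Synthetic reporter-assay generator with known ground truth.

Emulates the statistical structure of the bulk-fluorescence assay: for each
construct and ligand concentration, three experimental replicates (each with
its own multiplicative batch factor, mimicking separately prepared media
stocks) of three biological replicates (well-level multiplicative noise)
give the assay's n = 9 wells per condition, plus blank wells per plate.

The expression model composes the dose-response curve with the
kinetic-barrier power law: a construct with a barrier of class size B at
position r has its ON-state amplitude raised by B/r², and may carry an
additive leak shift:

    true value(Z) = (a + leak_shift) + (b + B/r²) · Z / (EC50 + Z)

Raw wells are synthesized by re-applying the plate physics the analysis
undoes: F_raw = value · OD_true + blank-F draw, OD_raw = OD_true + blank-OD
draw, so that noiseless generation followed by normalization is an exact
identity.

What this generator does NOT emulate: growth dynamics (OD_true is a fixed
exponential-phase 0.4), plasmid copy-number variation, detector saturation,
or any real calibration of biological vs experimental variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import MEASUREMENT_COLUMNS, DomainError, validate_measurements


@dataclass(frozen=True)
class BarrierTruth:
    """Ground-truth barrier for one construct: ΔF_ON = B / r²."""

    mutation_class: str
    r: int
    B: float

    def delta_f_on(self) -> float:
        return self.B / self.r ** 2


@dataclass(frozen=True)
class GroundTruth:
    """Parameters from which wells are synthesized.

    Units: concentrations mM, fluorescence arbitrary units, OD600
    dimensionless. Defaults give a ~10-fold reference dynamic range, within
    the 2.4-34-fold band the barrier scans span; barrier sizes of a few
    hundred units are then comparable to the reference amplitude, as the
    larger barrier classes are.
    """

    a: float = 100.0              # baseline (leak) normalized fluorescence
    b: float = 900.0              # reference amplitude
    ec50: float = 0.01            # mM
    leak_shift: dict[str, float] = field(default_factory=dict)
    barrier: dict[str, BarrierTruth] = field(default_factory=dict)
    biological_cv: float = 0.05   # well-level multiplicative noise
    batch_sd: float = 0.05        # log-normal sigma per experimental rep
    blank_f_mean: float = 100.0
    blank_f_sd: float = 5.0
    blank_od_mean: float = 0.05
    blank_od_sd: float = 0.005
    od_true: float = 0.4          # exponential-phase culture OD
    n_experimental: int = 3
    n_biological: int = 3
    n_blanks: int = 3             # blank wells per experimental replicate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.ec50 <= 0:
            raise DomainError("a and EC50 must be positive")
        if min(self.biological_cv, self.batch_sd, self.blank_f_sd,
               self.blank_od_sd) < 0:
            raise DomainError("noise parameters must be >= 0")
        if self.n_experimental < 1 or self.n_biological < 1:
            raise DomainError("replicate design must be >= 1 x 1")

    def true_value(self, construct_id: str, conc: float) -> float:
        amp = self.b
        if construct_id in self.barrier:
            amp += self.barrier[construct_id].delta_f_on()
        base = self.a + self.leak_shift.get(construct_id, 0.0)
        return base + amp * conc / (self.ec50 + conc)

    def noiseless(self) -> "GroundTruth":
        return replace(self, biological_cv=0.0, batch_sd=0.0,
                       blank_f_sd=0.0, blank_od_sd=0.0)


DEFAULT_CONCENTRATIONS = (0.0, 0.001, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0)


def generate(truth: GroundTruth, constructs: list[str],
             concentrations=DEFAULT_CONCENTRATIONS) -> pd.DataFrame:
    """Synthesize a well-level measurement table.

    Fully reproducible from ``truth.seed``; identical truths give
    byte-identical tables.
    """
    concs = [float(c) for c in concentrations]
    if 0.0 not in concs:
        raise DomainError("concentration series must include 0")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for exp_rep in range(1, truth.n_experimental + 1):
        batch = float(np.exp(rng.normal(0.0, truth.batch_sd)))
        for construct_id in constructs:
            for conc in concs:
                v = truth.true_value(construct_id, conc)
                for bio_rep in range(1, truth.n_biological + 1):
                    well = v * batch * (1.0 + rng.normal(0.0, truth.biological_cv))
                    f_raw = (well * truth.od_true
                             + rng.normal(truth.blank_f_mean, truth.blank_f_sd))
                    od_raw = (truth.od_true
                              + rng.normal(truth.blank_od_mean, truth.blank_od_sd))
                    rows.append((construct_id, conc, exp_rep, bio_rep,
                                 f_raw, od_raw, False))
        for blank_i in range(1, truth.n_blanks + 1):
            f_blank = rng.normal(truth.blank_f_mean, truth.blank_f_sd)
            od_blank = rng.normal(truth.blank_od_mean, truth.blank_od_sd)
            rows.append(("", 0.0, exp_rep, blank_i, f_blank, od_blank, True))
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return validate_measurements(df)


def make_recovery_suite(b_values=(100.0, 400.0, 1200.0),
                        r_values=(1, 2, 3, 4, 5, 6),
                        n_replicates: int = 1,
                        base_truth: GroundTruth | None = None,
                        concentrations=(0.0, 1.0),
                        reference_id: str = "perfect",
                        ) -> list[tuple[pd.DataFrame, GroundTruth]]:
    """Paired (dataset, truth) fixtures for parameter-recovery studies.

    For each B in the grid, one dataset contains the reference construct
    plus one mutant per r position carrying that B; ``n_replicates`` seeded
    repeats are emitted per grid point.
    """
    base = base_truth or GroundTruth()
    suite = []
    for bi, b_val in enumerate(b_values):
        barrier = {
            f"mut_r{r}": BarrierTruth("BULGE1", int(r), float(b_val))
            for r in r_values
        }
        for rep in range(n_replicates):
            truth = replace(base, barrier=barrier,
                            seed=base.seed + 1000 * bi + rep)
            constructs = [reference_id, *barrier.keys()]
            suite.append((generate(truth, constructs, concentrations), truth))
    return suite
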