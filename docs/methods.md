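# Methods

`epbarriers` analyzes how transcriptional ZTP riboswitches tune their
gene-expression decision through the kinetics of an internal strand
displacement. This note documents the models implemented, the conventions
and tunable parameters, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## The physical picture

A transcriptional ZTP riboswitch couples a conserved aptamer domain (P1 —
J1/2 — P2, a linker, a pseudoknot PK, and a short P3 stem-loop) to an
expression platform whose 3' segment — the **invader** — strand-invades the
aptamer's P3 stem and pseudoknot when no ligand is bound. Invasion
nucleates at the base pair closest to the terminator's apical loop
(C100:G108 in the reference numbering used throughout) and branch-migrates
toward the hairpin base, zipping up an intrinsic terminator that aborts
transcription at the downstream poly-U tract. Ligand binding stabilizes the
aptamer against invasion, transcription reads through, and the gene is ON.

Noncomplementary elements in the invader — G:U wobbles, mismatches, and
bulged nucleotides — act as **kinetic barriers** to branch migration. They
do not change which structure ultimately wins at equilibrium; they slow the
displacement race that the expression platform must win within the
seconds-long window of transcription. Their functional effect is therefore
position-dependent: a barrier near the nucleation site gates the whole
displacement pathway, while one near the hairpin base affects mostly the
last steps (and terminator strength, hence leak).

## Coordinates and the barrier index

All coordinates are 1-based closed intervals numbered from the construct's
first transcribed nucleotide, matching residue-style mutation names (A26,
C100, G108). The barrier index of an invader position is

    r = position − invader.start + 1,

anchored so that the nucleating invader nucleotide (G108) has r = 1 and a
bulge "at index 3" is inserted immediately after position 110. Insertions
are indexed by the residue immediately 5' of the inserted bases; mutation
names always use reference numbering, never renumbered mutant coordinates.

## Duplex annotation

The invader is aligned antiparallel against a substrate window ending at
P3's 3' terminus (invasion nucleates there and proceeds through the
pseudoknot), of length `len(invader) + slack` (slack default 4 nt). The
alignment is a global-in-invader dynamic program anchored at the nucleation
corner, with the distal (5') substrate overhang unscored and trimmed.
Scoring defaults are package conventions, not measured quantities:
WC +3, wobble +1, mismatch −2, gap −4 per bulged nucleotide; all are
overridable. Ties are broken deterministically: pairing beats gapping, and
bulges are placed as close to the nucleation end as possible. An exhaustive
enumeration oracle over all antiparallel gapped alignments verifies the DP
on random pairs up to 8 nt in the test suite.

Noncomplementary columns are grouped into elements. Adjacent MISMATCH or
BULGE columns of the same kind coalesce (physically one internal loop or
one multi-nucleotide bulge); **wobble columns are never merged** — a G:U
wobble is still a base pair, and adjacent wobbles are distinct pairs. This
is what makes the reference invader's annotation come out as five elements
(three wobbles, two single-nucleotide bulges) rather than four. Each
element carries the r of its 5'-most invader-side column; substrate bulges
borrow the nucleation-side flanking invader position. Elements additionally
carry a phenomenological band label — "ON-state tunebox" for r ≤ 5, "leak
tunebox" within 6 nt of the hairpin base, "variable region" between —
used for reporting only, never in any computation.

Architecture classification calls a construct `LOOP_PLUS_INVADER` when the
duplex has ≥ 8 paired columns, the apical loop is 3–12 nt, and the poly-U
tract starts within 2 nt of the invader's 3' end; anything else is `OTHER`.

### Hairpin stability

`hairpin_delta_g` is a reduced nearest-neighbor model: Watson–Crick stack
free energies (37 °C, kcal/mol) from the standard parameter set; any stack
containing a G:U wobble is assigned one representative stabilizing value
(−1.2 kcal/mol) rather than the resolved wobble table; hairpin-loop,
bulge and internal-loop initiation penalties from small size tables with
Jacobson–Stockmayer log extrapolation beyond; single bulges retain the
flanking stack; a terminal A:U or G:U pair pays +0.45. This is deliberately
coarse: the package's conclusions rest on kinetic position dependence, not
equilibrium stability, so the model only needs a sane ranking (every added
defect weakly increases ΔG — a tested invariant), not NUPACK-grade
resolution.

## The synthetic reference construct

The published construct sequences live in supplementary files that are not
redistributed here, so the package ships a **synthetic** 134-nt stand-in
(`epbarriers.reference`, labelled as such) engineered to reproduce every
printed structural property of the wildtype expression platform: the
C100:G108 nucleating pair; invader 108–126 followed directly by an 8-U
tract; wobbles at U111 (vs G97) and G112 (vs U96) plus a third distal
wobble; single-nucleotide bulges U115 and C118; a 7-nt apical loop; A at
position 26 (the pseudoknot-breaking OFF control); and a perfect-invader
correction of exactly 3 substitutions + 2 deletions. The third wobble's
true position is not printed anywhere; it was placed at G121, distal to
both bulges, where the alignment optimum is unambiguous. Everything
upstream of the substrate span is filler. Structural tests are exact on
this stand-in; nothing in the package treats it as genomic truth.

## Mutant libraries

* **Mismatch scan** — each paired invader position substituted with the
  complement of the invader base itself (G↔C, A↔U), which breaks the pair
  whatever the substrate base is; this single deterministic rule reproduces
  every named mismatch mutant (G108C, C118G, ...).
* **Deletion scan** — every invader position; **bulge scans** — poly-A
  insertions of length 1–3 after every index position; **wobble scan** —
  C→U on G:C pairs and A→G on U:A pairs. The A→G direction replaces a
  Watson–Crick pair with a U:G wobble that empirically *favors* strand
  displacement; such entries are flagged (`wobble-to-WC direction
  reversed`) and can be excluded.
* Libraries are deduplicated: deleting either C of a CC repeat (or
  inserting A next to an A run) yields the same molecule, and the 5'-most
  placement is kept as canonical. `diff_constructs` left-aligns edits for
  the same reason, so recovering each mutant's edit by diffing against the
  reference reproduces the generating edit exactly.
* **Perfect invader** — wobbles corrected to the WC complement of the
  substrate base, invader bulges deleted; the result provably has zero
  noncomplementary elements and the operation is idempotent.

A caveat found while testing: a mismatch introduced next to a natural bulge
can let the duplex *re-register* (strand slippage), relocating the defect
instead of leaving a mismatch at exactly that r. The library manifest
records the designed element; re-annotation reflects the optimal alignment.

## Curation, chimeras, flip designs

Candidate expression platforms are filtered by (i) a poly-U tract of ≥ 5 Us
anywhere 3' of P3, (ii) exact string identity of the P3 region to the
reference (gapped near-identity is rejected), and (iii) the
loop + invader architecture. Chimeras splice a foreign invader between the
reference aptamer (through the apical loop) and the reference poly-U.

The flip design inserts a `domain_len` (default 8) nt **flipping domain**
between the terminator hairpin's 3' end and the poly-U tract. Apo, it is a
spacer that decouples hairpin from poly-U (flagged "termination ablated"
when the spacer is ≥ 8 nt — a reporting heuristic, never used in fits).
Holo, it pairs with the invader suffix left single-stranded by failed
aptamer invasion, forming a synthetic terminator flush against the poly-U:
the switch's logic inverts. The default domain sequence is the reverse
complement of the invader's 3' `domain_len`-mer (so the holo stem is a
perfect duplex); an explicit sequence can be supplied instead. Barrier
tuning (`tune_flip`) applies a mutation to the parent invader *before*
insertion and recomputes the design; barriers inside the flipping domain
are rejected.

## Quantitative models

* **Normalization** — per well: (F_raw − mean blank F)/(OD_raw − mean
  blank OD); blanks excluded from output; wells with corrected OD ≤ 0
  flagged and dropped with a warning.
* **Dose response** — normalized fluorescence = a + b·[Z]/(EC50 + [Z]),
  Hill coefficient fixed at 1. Fit by nonlinear least squares
  (`scipy.optimize.curve_fit`, trust-region reflective) with a₀ = min
  value, b₀ = max − min, EC50₀ = geometric mean of the nonzero
  concentrations; bounds a ≥ 0, b free, EC50 > 0; standard errors from the
  fit covariance. Requires ≥ 3 distinct concentrations including 0.
* **ΔF_ON** — mean(mutant) − mean(reference) at the ON concentration
  (group means, matching mean ± SD bar-chart reporting); negative values
  allowed (the wobble-to-WC direction). Because a finite concentration
  reaches only the fraction Z/(EC50+Z) of saturation, ΔF_ON points can be
  rescaled by (EC50+Z)/Z using an EC50 estimate (typically the reference
  fit) — with this correction the noiseless pipeline recovers B exactly.
* **Barrier power law** — ΔF_ON(r) = B/r². The single-parameter
  least-squares problem is solved in closed form,
  B̂ = Σ ΔFᵢ rᵢ⁻² / Σ rᵢ⁻⁴, with SE(B) from residual variance; a numerical
  optimizer agrees to 1e-9 in the tests. B may be negative and is then
  flagged; no nonnegativity constraint is imposed. Fits default to one
  point per mutant (the per-mutant mean); pooling all replicates as points
  is available via a flag.
* **Statistics** — two-tailed heteroscedastic (Welch) t-tests with
  Welch–Satterthwaite degrees of freedom; Bonferroni p_adj = min(1, p·m).
  Significance tiers (*, **, ***, **** at α = 0.05/0.01/0.001/0.0001) are
  keyed to the *pre-correction* p, matching how the assay's figures report
  them, while the corrected value is also exposed.
* **Fraction readthrough** — AT/(AT+T) per gel lane from a band-intensity
  table; always in [0,1]; image quantification is upstream of this package.

## The synthetic assay generator

`GroundTruth` composes the two models: a construct with barrier (class, r,
B) and leak shift δ has true value

    v(Z) = (a + δ) + (b + B/r²)·Z/(EC50 + Z).

Defaults a = 100, b = 900 (arbitrary units), EC50 = 0.01 mM — a ~10-fold
reference dynamic range, with the B grid {100, 400, 1200} spanning barriers
from small perturbations to amplitude-doubling, inside the 2.4–34-fold
band the barrier scans span.

Wells are synthesized by re-applying the plate physics the analysis undoes:
each of 3 experimental replicates draws a multiplicative batch factor
LogNormal(0, 0.05) (separately prepared media stocks); each of 3 biological
replicates draws well noise ×(1 + N(0, CV)) with CV = 5%;
F_raw = value·OD_true + blank-F draw and OD_raw = OD_true + blank-OD draw
with OD_true fixed at 0.4 (exponential phase) and blanks N(100, 5) /
N(0.05, 0.005); blank wells are emitted per experimental replicate. The
noise magnitudes are an assumption — the real assay reports only 9-point
standard deviations, and the biological:experimental variance split is not
reported — so all of them are exposed parameters. Everything is
reproducible from a single integer seed.

What the generator does **not** emulate: growth dynamics, plasmid
copy-number variation, detector saturation or gain, position-on-plate
effects, or day-scale drift. Passing recovery tests therefore demonstrate
that the estimators are correct and well-conditioned under the assumed
noise structure, not that the assay itself meets these error bars.

## Recovery studies and problem sizes

The noiseless identity check generates one reference plus six barrier
mutants (r = 1..6) over 8 concentrations and requires exact recovery
(a, b, EC50 to ≤ 1e-6 relative; B to ≤ 1e-9 after saturation correction).
The stochastic study uses the default noise with 20 seeded replicates per
barrier size; each replicate runs the full pipeline (normalize → reference
dose fit → corrected ΔF_ON → closed-form B). The mean recovered B stays
within 10% of truth and the mean EC50 within 15%; the whole study is a few
hundred datasets of ~500 wells and runs in about a second.

## Known limitations

* No folding or kinetic simulation: annotation is static alignment, and the
  "barrier" interpretation is imported from the strand-displacement
  literature, not computed.
* The reference construct is a synthetic stand-in; positions outside the
  expression platform are filler.
* The reduced energy table resolves wobble stacks to one value and ignores
  coaxial stacking, dangles, and special hairpin loops.
* The B/r² law is phenomenological; the exponent is fixed, and class fits
  pool mutants that may deviate individually.
* Curation's P3 filter is exact string matching by design; homologs with a
  single P3 difference are rejected, not scored.
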