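# epbarriers

Kinetic-barrier analysis of riboswitch expression platforms.

Transcriptional ZTP riboswitches decide between termination and
readthrough during the few seconds RNA polymerase spends crossing them:
in the absence of ligand, the expression platform's 3' **invader** strand
strand-invades the aptamer's P3 stem and pseudoknot, nucleating an
intrinsic terminator hairpin; ligand binding blocks the invasion and the
gene stays ON. Noncomplementary elements in the invader — G:U wobbles,
mismatches, bulges — are **kinetic barriers** that slow this branch
migration, and placing or removing them tunes the switch's dynamic range
without touching the aptamer.

`epbarriers` is a toolkit for this analysis, aimed at RNA synthetic
biologists and people studying riboswitch mechanisms. It provides:

* **duplex annotation** — antiparallel alignment of the invader against
  its substrate span, classification of wobble/mismatch/bulge elements
  with their barrier index *r* (nucleotides from the strand-displacement
  nucleation site), architecture classification, and a reduced
  nearest-neighbor hairpin ΔG;
* **mutant libraries** — mismatch, deletion, bulge (A/AA/AAA) and wobble
  scans, the perfectly complementary invader correction, and a mutation
  naming grammar (`G108C`, `A26Δ`, `108insAAA`) with exact round trips;
* **design** — curation of candidate expression platforms (poly-U ≥ 5 Us,
  identical P3, loop + invader architecture), aptamer–invader chimeras,
  and flipped-logic OFF-switch design via an 8-nt "flipping domain" with
  barrier tuning;
* **quantitation** — blank/OD normalization, the dose-response model
  *F* = *a* + *b*·[Z]/(EC50 + [Z]), saturation-corrected ΔF_ON, the
  kinetic-barrier power law **ΔF_ON(r) = B/r²** (closed-form fit), Welch
  t-tests with Bonferroni correction, fold changes, and in vitro fraction
  readthrough from gel band tables;
* **synthetic assays** — a well-level reporter-assay generator (3
  experimental × 3 biological replicates + blanks, n = 9 per condition)
  with known ground truth, so every estimator is testable end to end.

## Worked example

The bundled reference construct (a synthetic stand-in reproducing the
wildtype *Clostridium beijerinckii pfl* expression platform's printed
structural features) annotates like this:

```bash
python analysis/01_annotate_reference.py
```

```
reference construct: Cbe_pfl_WT_synthetic (134 nt)
terminator nucleating pair: C100:G108
noncomplementary elements: 5 (3 wobbles, 2 invader bulges)
  r= 4 WOBBLE         invader (111,) [ON-state tunebox]
  r= 5 WOBBLE         invader (112,) [ON-state tunebox]
  r= 8 BULGE_INVADER  invader (115,) [variable region]
  r=11 BULGE_INVADER  invader (118,) [variable region]
  r=14 WOBBLE         invader (121,) [leak tunebox]
hairpin dG (reduced NN model): -15.70 kcal/mol
```

The invader carries five defects relative to the strand it displaces:
the wobbles closest to the nucleation site (r = 4, 5) are the ones whose
correction most depresses the ON state, while the distal wobble sits in
the leak-determining base of the hairpin. Simulating a bulge scan at known
barrier size and running the full fitting pipeline recovers the truth:

```bash
python analysis/05_simulate_assay.py --seed 0 --barrier-size 400
python analysis/06_fit_models.py
```

```
reference fit: a=95.4 (true 100.0), b=889.0 (true 900.0), EC50=0.0106 mM (true 0.01)
barrier fit [BULGE1]: B=399.7 ± 27.8 (true 400.0)
reference fold change: 10.6; mutant fold changes 10.2-14.5
1/6 mutants significant vs reference after Bonferroni (alpha 0.05): bulge1_r1
```

That is the package's core quantitative claim in miniature: a barrier of
size B at distance r from the nucleation site raises ON-state expression
by B/r², so only the nucleation-proximal mutant (r = 1, ΔF ≈ 400) clears
the significance bar while distal mutants fade into the 1/r² tail.

The numbered scripts under `analysis/` walk the whole study: duplex
annotation (01), mutant libraries (02), curation and chimeras (03),
flip-logic designs with barrier tuning (04), assay simulation (05) and
model fitting (06). Each writes its tables under `results/`. The same
operations are available as a CLI (`epbarriers annotate|scan|curate|flip|
fit|simulate`) for use on your own FASTA + region-config inputs.

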