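# mrmkit

Chromatogram-level processing toolkit for LC-MRM-MS (multiple reaction
monitoring) datasets: compound-library channel annotation, anchor-based
retention-time alignment, MS2-level isotopic-interference discovery with
cascaded chromatogram deisotoping, background-subtracted integration, and
a forward-model simulator for end-to-end testing.

## What it does

In unit-resolution triple-quadrupole MRM data, isotopologues of a lipid
with a lower precursor m/z bleed into the channels of lipids with higher
precursor m/z. `mrmkit` removes these signals at the *chromatogram* level:

1. **`mrmkit.chem`** computes aggregated (nominal-mass) isotopologue
   distributions for precursor ions and, crucially, for MRM *transitions*:
   the factor `f(i, j)` for a transition shifted by `i` nucleons on Q1 and
   `j <= i` nucleons on Q3 is the product of the neutral-fragment ratio at
   order `i - j` and the product-ion ratio at order `j`. Distributions are
   truncated at order 10 (M10) by default; the embedded isotope table uses
   IUPAC/CIAAW 2013 representative abundances for C, H, N, O, P, S.
2. **`mrmkit.annotate`** links compound-library rows (Name, Q1, Q3, CE,
   Polarity, optional precursor/MS2 formulae) to MRM channels within
   ±0.2 Da — possible detection targets, not identifications.
3. **`mrmkit.deiso`** discovers every source→affected interference
   relation in a run (±0.2 Da mass tolerance, ±1.0 V collision-energy
   window, up to M10) and subtracts factor-scaled source chromatograms in
   ascending-Q1 order so that chained interference uses already-corrected
   sources. Redundant channels are collapsed to a single point-by-point
   maximum subtraction to avoid over-subtraction.
4. **`mrmkit.align`** warps each run's time axis through a piecewise-linear
   monotone function built from user-chosen anchor points.
5. **`mrmkit.quant`** integrates ranges (trapezoid, optional linear
   baseline) and produces before/after deisotoping AUC reports.
6. **`mrmkit.synth`** generates synthetic scheduled-MRM datasets with
   forward-modeled interference, RT drift, noise, and detector saturation,
   plus the matching library and ground truth.

Known limitation (by design): subtraction assumes detector linearity, so
deisotoping is insufficient around saturated source peaks; no saturation
compensation is attempted.

## Data formats

- **mzML** (read-only): SRM chromatograms with precursor/product isolation
  m/z; TIC and other non-SRM chromatograms are skipped; missing collision
  energy is recorded as 0 V; seconds are converted to minutes.
- **Dataset interchange TSV** (read/write, the reference format):
  long-format columns `run_id, polarity, q1, q3, ce, time_min, intensity`.
- **Compound library TSV**: columns `Name, Q1, Q3, CE, Polarity, Formula,
  MS2Formula, MS2FormulaType, Tags`; the last five are optional, but
  Formula/MS2Formula/MS2FormulaType are all required for a row to act as a
  deisotoping source. `MS2FormulaType` is `ConstantProduct` (MS2Formula is
  the product ion) or `ConstantNeutralLoss` (MS2Formula is the neutral
  loss).
- **Target TSV** (`.tdf` dialect): `name, polarity, q1, q3, ce,
  rt_start_min, rt_end_min`.
- **Anchor TSV**: `run_id, observed_rt_min, reference_rt_min`.

## CLI

```sh
mrmkit simulate --spec spec.json --seed 17 -o DATA_DIR
mrmkit annotate DATA --library LIB.tsv -o annotations.tsv
mrmkit deisotope DATA --library LIB.tsv -o corrected.tsv   # + corrected.edges.tsv
mrmkit align DATA --anchors ANCHORS.tsv -o aligned.tsv
mrmkit integrate DATA [--targets T.tdf] [--background linear] -o auc.tsv
mrmkit report --before DATA --after corrected.tsv -o changes.tsv
```

`DATA` is either an interchange TSV or an mzML file. The simulation spec
is JSON:

```json
{
  "compounds": [
    {"name": "PC_34:2", "formula": "C42H81O8NP",
     "ms2_formula": "C5H15O4NP", "ms2_formula_type": "ConstantProduct",
     "q1": 758.57, "q3": 184.07, "polarity": "Positive", "ce": 33.0,
     "peaks": [{"apex_rt": 4.0, "sigma": 0.08, "height": 1000.0}]}
  ],
  "n_runs": 2, "sampling_interval": 0.02, "time_end": 8.0,
  "noise_sd": 0.0, "saturation_limit": null, "rt_drift": [0.0, 0.1]
}
```

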