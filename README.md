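# shiftdiscrim

Candidate-structure discrimination from calculated vs experimental NMR
chemical shifts.

When a natural product's spectra are compatible with several closely related
structures — here a ferulic acid derivative whose position-9′ heteroatom could
be oxygen (ester), sulfur (thioester) or nitrogen (amide) — each candidate can
be submitted to DFT shift calculations and judged by how well its calculated
spectrum matches the measured one. `shiftdiscrim` implements the statistical
side of that workflow for chemists doing computational structure elucidation:

* per-position residues RS = |δ_exp − δ_calc| and their mean (MAE);
* the linear adjustment δ_calc = a·δ_exp + b that removes the systematic bias
  of a level of theory, and the corrected error
  CMAE = mean |(δ_calc − b)/a − δ_exp|;
* leave-one-out cross-validation of the shift regression: PRESS = Σ(y_i −
  ŷ_(i))², s_PRESS = √PRESS/(n − k − 1) and Q² = 1 − PRESS/Σ(y_i − ȳ)², where
  ŷ_(i) is the prediction for point i from the line refitted without it;
* ranking of candidates by Q² (ties: lower MAE, then lower s_PRESS) across
  every (nucleus, method) block, with a majority verdict in which ¹³C blocks
  outrank ¹H;
* a light IR check: per-band deviation Δ = scale·ν_theo − ν_exp against the
  experimental absorption bands;
* a seeded synthetic-data generator producing affine-plus-noise candidate
  sets with decoy outliers at heteroatom-adjacent positions, so the whole
  pipeline is testable end to end.

Shieldings can be referenced with δ = σ_ref − σ (TMS defaults: 32.1843 ppm for
¹H, 186.3296 ppm for ¹³C). The complete reference dataset for the ferulamide
heterologous series — candidates O/S/N at B3PW91/DGDZVP and
B3LYP/6-31+G(d,p) for both nuclei, plus ferulic acid as a validation
compound, and the IR band attribution table — ships with the package.

## Worked example

```sh
shiftdiscrim discriminate --fixtures
```

prints one statistic row per candidate table and the verdict (abridged):

```
candidate nucleus            method    a     b   R2  MAE  CMAE      s      PRESS  s_PRESS       F    Q2
        O     C13     B3PW91/DGDZVP 0.93 13.89 0.96 5.51  4.31 6.3770  967.26600     1.94  428.21 94.65
        S     C13     B3PW91/DGDZVP 1.08 -4.21 0.97 5.98  3.53 5.7709  910.04400     1.89  526.41 94.96
        N     C13     B3PW91/DGDZVP 0.98  6.91 0.99 4.58  2.22 3.2706  205.74500     0.90 1672.78 98.86
...
Block winners:
  C13  B3PW91/DGDZVP: N
  C13  B3LYP/6-31+G(d,p): N
  H1   B3PW91/DGDZVP: N
  H1   B3LYP/6-31+G(d,p): O

Verdict (q2): N
```

Reading the numbers: for the carbon spectra the N (amide) candidate has the
smallest MAE (4.58 ppm vs 5.51/5.98), a residual dispersion of 3.27 ppm after
the linear adjustment, and by far the best cross-validated predictivity
(Q² = 98.86% vs ≈95%); it wins three of the four blocks, so the pipeline
assigns the 9′ heteroatom as nitrogen. The large single-position residues
driving the decision (26.9 ppm at C-8′ for the ester, 30.6 ppm at C-9 for the
thioester) appear in the per-position residual output
(`--format json` includes them on request).

The same works on your own data: `--input tables.csv` with columns
`position,nucleus,delta_exp,delta_calc,candidate,method` (and optionally
`compound`). `shiftdiscrim simulate --seed 7 --out sim/` writes a synthetic
candidate set in the identical schema, and
`shiftdiscrim ir-compare --fixtures --candidate N --method "B3LYP/6-31+G(d,p)"`
prints the band-deviation table (carbonyl stretch: 1727 − 1680 = 47 cm⁻¹).

The Python API mirrors the CLI: `load_builtin_fixtures()`,
`evaluate_candidate(table)`, `rank_candidates(scores)`,
`band_deviation_table(...)`, `generate_candidate_set(spec)`.

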