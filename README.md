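# ilextract

Quantitative analysis of ionic-liquid-based heme/hemoglobin depletion from
serum, and of its effect on competitive-ELISA cotinine quantification.

Hemolyzed serum carries free hemoglobin and heme that interfere with
clinical assays: hemoglobin binds nonspecifically to the solid phase of
immunoassays and inflates apparent analyte concentrations.  Shaking serum
with a hydrophobic imidazolium ionic liquid (IL) such as 1-methyl-3-octyl-
imidazolium tetrafluoroborate (OMIM BF4) forms a biphasic system that
selectively extracts heme/hemoglobin into the IL phase.  `ilextract`
implements the full quantitative layer of this workflow for analytical
chemists and assay developers:

- **Spectrophotometry** (`ilextract.spectra`): Soret-band (410 nm)
  quantification via Beer–Lambert proportionality, with extraction
  efficiency `100·(A_before − A_after)/A_before`.
- **Extraction kinetics** (`ilextract.kinetics`): the reversible
  first-order biphasic rate law
  `dC_aq/dt = −k1·C_aq + k2·(q − C_aq·V_aq)/V_IL`, its closed-form
  solution `C_aq(t) = C∞ + (C0 − C∞)·e^(−a·t)` with
  `a = k1 + k2·V_aq/V_IL`, simulation, and least-squares estimation of
  `(k1, k2)` from shaking-time courses.
- **Equilibrium partitioning** (`ilextract.partition`): constant
  separation ratio `S0 = C_IL/C_aq` at low concentration, and an
  empirical hyperbolic saturation relation `S(C_aq) = S0/(1 + C_aq/K)`
  at high concentration; depletion prediction by mass balance.
- **Competitive ELISA** (`ilextract.elisa`): four-parameter-logistic
  (4PL) calibration `A(c) = A_bot + (A_top − A_bot)/(1 + (c/IC50)^h)`,
  analytic inverse prediction, and replicate accuracy/precision
  statistics (mean, sample SD, CV%, signed relative error).
- **Free energies** (`ilextract.freeenergy`): Bennett Acceptance Ratio
  (BAR) estimation of ΔG from forward/reverse work samples, and
  thermodynamic-cycle arithmetic giving water→IL transfer free energies
  `ΔG_transfer = ΔG_decouple(water) − ΔG_decouple(IL)` with propagated
  uncertainty (negative ⇒ the solute prefers the ionic liquid).
- **Synthetic data** (`ilextract.synthetic`): deterministic generators
  for every input the pipeline consumes, parameterized at the reference
  study conditions.

## Worked example

Predict the equilibrium depletion for the reference composition (3 mL of
serum at 0.125 mg/mL hemoglobin + 0.7 g OMIM BF4, density 1.12 g/mL):

```sh
$ ilextract predict --s0 89.14 --k 0.15 --v-aq 3 --il-mass 0.7 --c0 0.125
{
  "schema_version": 1,
  "subcommand": "predict",
  "c_aq_eq_mg_per_ml": 0.00665535,
  "c_il_eq_mg_per_ml": 0.568054,
  "efficiency_percent": 94.6757
}
```

About 94.7% of the hemoglobin partitions into the ionic-liquid phase;
0.0067 mg/mL remains in the serum.

The effect of that depletion on assay quality, from the embedded
reference cotinine dataset (serum spiked at 20 ng/mL, hemoglobin
0.2 mg/mL, triplicate wells):

```python
>>> from ilextract import datasets
>>> from ilextract.elisa import replicate_stats, accuracy_comparison
>>> before = replicate_stats(datasets.cotinine_replicate_set("before", 0.2))
>>> after = replicate_stats(datasets.cotinine_replicate_set("after", 0.2))
>>> before.rendered()
{'condition': 'before extraction, Hb 0.2 mg/mL', 'nominal_ng_per_ml': 20.0,
 'mean_ng_per_ml': 26.436, 'sd_ng_per_ml': 1.548, 'cv_percent': 5.856,
 'relative_error_percent': 32.18, 'abs_relative_error_percent': 32.18, 'n': 3}
>>> accuracy_comparison(before, after)["decrease_points"]
32.27...
```

Before extraction, 0.2 mg/mL hemoglobin biases the measured cotinine
concentration +32.18% above nominal; after IL extraction the bias is
−0.09%, an improvement of 32.27 percentage points, with CV% improving
from 5.86 to 3.15.

## Command-line interface

`ilextract` exposes `quantify`, `fit-kinetics`, `fit-isotherm`,
`predict`, `elisa`, `elisa-compare`, `bar`, `cycle`, and `simulate`.
Each subcommand prints deterministic JSON to stdout (or `--out`) and a
run manifest (input hashes, version, seed, timestamp) to stderr.  See
`docs/methods.md` for the models, assumptions, and parameter choices.
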