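# seqrate

Sequence-based prediction of protein folding kinetics: a two-stage support
vector pipeline that first classifies a protein as a **two-state** or
**multi-state** folder and then predicts its folding rate, log10(k_f / s⁻¹),
with a kinetic-type-specific ε-SVR — using only features computable from the
amino-acid sequence plus upstream per-residue predictions (a residue–residue
contact probability map and a 3-state secondary-structure string).

It is aimed at structural bioinformaticians who have folding-rate
compilations and predictor outputs (e.g. SCRATCH-style contact maps) and
want reproducible kinetic-type classification, rate regression, and the
evaluation protocols that go with them — strict leave-one-out
cross-validation, repeated 90/10 splits, single-feature screens and a
multi-predictor linear baseline.

## The model

From a contact probability map *P* (entries P_ij = predicted probability
that residues i and j lie within 8 Å), two probability-weighted long-range
descriptors are computed over pairs at sequence separation |i−j| ≥ 12:

- long-range contact number  LRCN = Σ_{|i−j|≥12} P_ij / L
- long-range contact order   LRCO = Σ_{|i−j|≥12} P_ij·|i−j| / L²

where L is the chain length. On a binary {0,1} map these reduce exactly to
the classic binary-contact definitions; with a PDB structure the "real"
counterparts rLRCN/rLRCO are computed from Cα–Cα distances at the same
threshold. Feature sets per model:

| model | features |
|---|---|
| kinetic-type classifier (C-SVM, RBF) | L, LRCO, LRCN, helix %, sheet %, 20 AA frequencies (25) |
| two-state rate regressor (ε-SVR, RBF) | LRCO, LRCN, helix %, sheet % (4) |
| multi-state rate regressor (ε-SVR, RBF) | L, LRCO, LRCN, helix %, sheet % (5) |

Hyperparameters (C, γ) are grid-searched under strict LOOCV; regressors use
a two-phase heuristic: grid over (C, γ) at ε = 0.1, then a 1-D ε sweep at
the optimum. Features are min–max scaled inside every fold from training
rows only.

Because the published benchmark compilations and the upstream predictors are
external, the package ships a synthetic benchmark generator
(`seqrate.synthetic_data`) that emulates their structure: toy Cα geometries,
predictor-style corrupted contact maps, class-specific secondary structure
and composition, and planted rates that fall with contact order (two-state)
and with chain length (multi-state).

## Worked example

```sh
seqrate synth --n 30 --seed 11 --out demo/bench
seqrate evaluate --data-dir demo/bench --protocol loocv
```

prints

```json
{
  "protocol": "loocv",
  "n": 30,
  "classification_accuracy": 0.9666666666666667,
  "two_state_pearson_r": 0.8753608100709713,
  "two_state_mad": 0.5400725174730631,
  "multi_state_pearson_r": 0.9025528430725408,
  "multi_state_mad": 0.5070853865649602
}
```

i.e. with every protein predicted by a model trained on the other 29, the
classifier recovers 29/30 planted kinetic types, and within each true class
the predicted log10 rates correlate with the planted ones at r ≈ 0.88/0.90
with a mean absolute difference of ≈ 0.5 log units. Other subcommands:
`seqrate features contacts|sequence` (descriptor tables), `seqrate train` /
`seqrate predict` (model bundles, with `--force-label` for what-if
predictions under an asserted kinetic type), `seqrate tune` (grid surfaces
as TSV for plotting accuracy-vs-(C, γ) profiles).

Library use mirrors the CLI: `generate_benchmark`, `assemble_matrix`,
`grid_search_classifier`, `tune_regressor`, `pipeline_loocv`,
`single_feature_screen`, `linear_baseline`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default 80-protein synthetic benchmark from the given seed,
grid-searches all three models, evaluates the full two-stage pipeline under
strict LOOCV and prints the classification accuracy and per-class Pearson
r / MAD. There are no external reference targets to emit, so the JSON file
it writes is empty.

See `docs/methods.md` for the modelling assumptions, parameter defaults,
what the synthetic generator does and does not emulate, and known
limitations.
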