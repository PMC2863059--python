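# Methods

## Problem and model

Protein folding kinetics has two coupled unknowns: the kinetic order
(two-state folding without populated intermediates vs multi-state folding
through intermediates) and the rate constant k_f. The two classes are known
to respond to different sequence determinants — rates of multi-state folders
track chain length strongly, while rates of two-state folders track native
topology (contact order) — so a single regression model over both classes
blurs both signals. This package therefore predicts in two stages:

1. a soft-margin C-SVM with Gaussian kernel exp(−γ‖u−v‖²) classifies the
   kinetic type from 25 sequence-derived features;
2. the protein is routed to one of two ε-SVR regressors (one per kinetic
   type) that predict log10(k_f / s⁻¹).

All topology features come from a *contact probability map* predicted from
sequence by an upstream tool, not from a solved structure. Rather than
thresholding the map into binary contacts and counting, the descriptors use
the probabilities directly as weights:

- LRCN = Σ_{|i−j|≥12} P_ij / L^c, c = 1 (expected number of long-range
  contacts per residue);
- LRCO = Σ_{|i−j|≥12} P_ij·|i−j| / L^c, c = 2 (probability-weighted
  long-range contact order).

Sums run over unordered pairs, each counted once. On binary maps these
degenerate exactly to the classic counting definitions, and both are linear
in P (scaling every probability by k scales the descriptor by k). The
classic relative contact order CO = Σ P_ij·|i−j| / (L·Σ P_ij) over all
separations ≥ 1 is provided for comparison, defined as 0 on an empty map.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| distance threshold | 8 Å | Cα–Cα contact definition; comparison is closed (d ≤ 8 is a contact) |
| min separation | 12 residues | "long-range" pair qualification |
| LRCN/LRCO exponents | 1 / 2 | standard length normalizations of contact number / order |
| scaling | min–max to [0,1] | RBF kernels mix length ~10² with compositions ~10⁻¹; fitted on training rows only, per fold |
| classifier grid | C ∈ 2⁻⁵..2⁵, γ ∈ 2⁻⁷..2³ | powers of two covering the published operating points (1, 0.25) and (8, 0.125) |
| ε sweep | {0.01, 0.05, 0.1, 0.2, 0.5} | phase 2 of the regressor tuning heuristic; includes the 0.1 incumbent |
| default classifier hp | C=1, γ=0.25 | published operating point, used when no tuning is requested |
| default regressor hp | C=8, γ=0.125, ε=0.1 | published operating point |

Two-phase regressor tuning: phase 1 grids (C, γ) at fixed ε = 0.1 scored by
LOOCV Pearson r; phase 2 sweeps ε at the phase-1 optimum. Because the sweep
contains 0.1, the final score can never fall below the phase-1 score. Ties
on score prefer smaller C, then γ, then ε (simpler models, deterministic).

Feature-set choices: coil content is excluded everywhere (negligible rate
correlation in both classes); the 20-dim amino-acid composition is used by
the classifier only (kept out of the low-n regressions to limit
over-fitting); length is excluded from the two-state regressor (weak
predictor there) and included for multi-state. Whether the multi-state
regressor should also carry helix/sheet content is genuinely ambiguous in
the source literature; the default includes them
(`multistate_features="with_ss"`), and
`multistate_features="length_contacts_only"` exposes the alternative
reading. An optional precomputed geometric-contact scalar can be appended to
any feature set (`use_gc`).

## Evaluation protocols

- **Strict LOOCV**: for each protein, scaling and models are fitted on the
  other n−1 and the held-out protein is predicted; `pipeline_loocv` does
  this for the full two-stage predictor (classifier chooses the regressor).
  Fold models are functions of training rows only — asserted by sentinel
  tests that corrupt held-out rows and verify fitted parameters are
  bit-identical.
- **Repeated 90/10 splits**: 5 repeats by default; test size is
  floor(0.10·n) with a minimum of 2; unstratified by default (a stratify
  option exists); deterministic given the seed. Hyperparameters are fixed
  across repeats by default (the published protocol used one fixed optimal
  set); an optional grid re-tunes on each training portion.
- **Single-feature screen**: per feature and per kinetic class, a 1-feature
  ε-SVR under LOOCV. The reported correlation is |predicted-vs-true r|
  signed by the direction of the raw feature–rate correlation: the
  predicted-vs-true r of any working monotone model is positive, so the
  direction must be attached explicitly for a signed-table reading
  (length then comes out negative for multi-state folders, as expected).
  A within-class constant feature yields an error row, not a crash.
- **Linear baseline**: OLS of log rate on a predictor subset with the
  in-sample fitted-vs-observed correlation, residual RMSE, and the overall
  ANOVA F statistic and p-value (via statsmodels).

## Synthetic benchmark: what it emulates, what it does not

`generate_benchmark` produces a dataset with the statistical structure the
method assumes, at desk scale (default n = 80, ~61:39 two-state:multi-state,
matching the class mix of the standard compilation):

- **Geometry**: each protein is a confined pseudo-self-avoiding random walk
  with 3.8 Å steps; the confinement radius scales as L^(1/3) and with the
  class contact density (two-state 0.08, multi-state 0.045), so two-state
  folders are more compact per residue. The "real" map is the 8 Å Cα
  contact map of this walk.
- **Predicted maps**: the real map corrupted the way a contact predictor
  errs — 85% of true contacts get probabilities ~N(0.75, 0.12), 15% are
  missed, and 2% of non-contacts become low-probability false positives.
  Estimated and structure-derived descriptors therefore correlate strongly
  but imperfectly across the benchmark (asserted r > 0.5).
- **Sequence and secondary structure**: class-tilted residue frequencies and
  segment-sampled H/E/C strings around class profiles (two-state:
  helix 0.28 / sheet 0.32; multi-state: helix 0.46 / sheet 0.12). Length
  ranges overlap (40–110 vs 90–300) so length alone cannot classify.
- **Planted rates**: a class-specific linear-plus-mild-quadratic function of
  the protein's own descriptors (as computed from the *emitted* predicted
  map, so the noiseless world closes exactly over file round-trips —
  probabilities are quantized to the 6-decimal file precision at generation
  time), plus Gaussian noise (default sd 0.3). Coefficients are negative in
  LRCO/LRCN for both classes and steeply negative in length for multi-state
  folders, mirroring the known kinetic biases; the quadratic term keeps the
  true relationship nonlinear so a kernel regressor has honest headroom over
  an ordinary linear fit. Centering constants were frozen from one pilot run
  of the generator (two-state LRCO ≈ 0.44 ± 0.18, multi-state
  L/100 ≈ 1.92 ± 0.56) and intercepts chosen so planted log10 k_f spans
  ≈ 5 log units per class, as in experimental compilations.

What it does **not** emulate: real protein energetics or folding physics;
realistic secondary-structure/contact-map coupling (SS strings and maps are
conditionally independent given the class); predictor error structure beyond
the miss/false-positive model; experimental rate measurement error beyond
i.i.d. Gaussian noise. A green recovery test therefore establishes that the
pipeline recovers structure *of the kind the method assumes*, at desk scale
— it does not establish the published accuracy on real compilations, which
depends on external data and an external contact predictor.

## Numerical choices and degenerate inputs

- Contact at exactly the threshold distance counts (closed comparison);
  binarization uses p ≥ threshold.
- Pairs involving a residue whose Cα is missing from the structure are
  treated as non-contacting ("count only observable contacts").
- Constant feature columns scale to 0 under both min–max and z-score (the
  divisor is guarded to 1).
- Pearson correlation on a constant vector raises, never returns a silent 0;
  LOOCV reports NaN correlation only where predictions collapse to a
  constant, and tuning treats such scores as −∞.
- Rates are exchanged as log10; natural-log inputs are converted on read
  (`rate_base="ln"`), since some published case-study values are quoted in
  natural log.
- 1-based residue indices in all file formats; contact files follow the
  CASP-RR text dialect (`i j p`, i < j, probabilities written with 6
  decimals); unlisted pairs are 0 and symmetry is enforced by mirroring.
- Strict sequence alphabet by default (the 20 canonical codes); lenient mode
  excludes non-canonical residues from composition numerator and
  denominator.

## Known limitations

- Sums over unordered pairs fix one of two conventions that differ by a
  factor of 2; correlations and scaled SVM inputs are unaffected, but raw
  descriptor values may differ by constant factors from other
  implementations.
- Whether features should be scaled before SVM training is not settled by
  the source literature; published (C, γ) optima may be scaling-dependent,
  so they are defaults here, not assertions.
- The two-phase (C, γ, ε) heuristic can miss joint optima a full 3-D grid
  would find; it is kept because it is the documented procedure.
- The geometric-contact feature is consumed as a precomputed scalar only;
  computing it from structures (alpha-shape packing analysis) is out of
  scope.
- mmCIF structures, multi-model NMR ensembles beyond model 1, and running
  the upstream contact/SS predictors are out of scope.
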