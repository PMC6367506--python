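# Methods

## Network model and inference

Each pathway is modelled as a three-layer tree.  The root node is the
pathway's transcription complex (TC), a latent binary variable
(active/inactive) with prior π = `prior_active` (default 0.5, symmetric
ignorance; overridable per model).  Each direct target gene (TG) is a
latent binary node (up/down) with CPT `P(up | TC)`; each probeset (PS) is
an observed binary node (high/low) with CPT `P(high | TG)`.  There are no
edges between genes, so the evidence likelihood factorises over genes and
the posterior `P(TC = active | evidence)` is computed exactly, in log
space (gene-level `logaddexp` over the two TG states).

**Gene-level CPTs.**  The `P(up | TC)` entries express literature-derived
regulation knowledge and are inputs of the model specification, not fitted
quantities.  Defaults are 0.90/0.10 for an up-regulated gene (mirrored for
down-regulated ones); they are deliberately informative-but-soft so that an
occasional discordant gene cannot veto the call.  A direction constraint is
enforced structurally: an up-regulated gene must have
`p_up_given_active > p_up_given_inactive`, and conversely.  Down-regulation
is encoded only through this ordering — probeset CPTs are never flipped —
so every model has a single canonical encoding.

**Soft evidence.**  Microarray intensities are continuous, while the PS
nodes are binary.  A linear-scale intensity I enters as the weight of the
"high" state, `w = logistic((log2(I + 1) − τ)·s)`, with per-probeset
discretisation cut τ (`log2_threshold`) and steepness s (`soft_scale`,
default 1).  As s → ∞ this converges to hard thresholding, which is also
available as an explicit mode (`evidence_mode="hard"`; a value exactly at
the cut counts as low).  Missing probesets contribute a likelihood factor
of 1, i.e. they marginalise out; genes with no observed probesets do the
same, so a sample with no usable measurements scores exactly the prior.

**Score and calls.**  The read-out is `log2odds = log2(P/(1 − P))`; P is
clamped to `[ε, 1 − ε]` with ε = 1e-12, so the score is capped at
±log2((1 − ε)/ε) ≈ ±39.86.  The complement is formed before clamping so the
transform is exactly antisymmetric at the caps.  The additive per-gene
contributions (log2 likelihood ratios) are reported alongside the score;
prior log2odds plus their sum reproduces the score up to the cap.  The
qualitative call is *active* iff the score **strictly** exceeds the
threshold for the chosen context; a score equal to the threshold is called
inactive (conservative, deterministic tie rule).  An affine 0–100 rescaling
between user-chosen anchors is provided for standardisation.

**Correctness oracle.**  `joint_enumeration_oracle` recomputes the
posterior by explicit summation over every joint configuration
(2 × 2^#genes × 2^#probesets states); it exists for testing only and is
capped at 2^20 probeset configurations.  The property suite checks
agreement with the factorised computation to 1e-10 over random models.

## Calibration and freezing

Probeset CPTs are fitted on samples whose pathway state is known.  During
calibration the latent gene state is **hard-assigned** from the sample
label and the gene's direction (active ⇒ up for up-regulated genes, down
for down-regulated ones; inactive ⇒ the reverse); no EM refinement is
attempted — ground-truth labels are the point of a calibration set, and
hard assignment keeps the estimator a transparent, testable count.  With
pseudocount a (Laplace default a = 1, guaranteeing CPTs strictly inside
(0, 1)):

    p_high|up = (n_high_among_up_assigned + a) / (n_up_assigned + 2a)

A sample counts as high when `log2(I + 1)` exceeds the probeset's cut τ.
The cut itself is set from the same data as the midpoint of the two
per-class medians of `log2(I + 1)` — robust to outliers, and collapsing to
an uninformative probeset (likelihood ratio 1) when the classes do not
separate, which is the desired behaviour.

Note the estimand: hard assignment estimates the gene-state-*marginalised*
quantity `P(high | TC)`, not `P(high | TG)`.  The two coincide exactly in
the limit of deterministic gene regulation and differ by
`(1 − p_up|active)·(p_high|up − p_high|down)` otherwise.  This is a
property of the calibration protocol, not a defect; the recovery
experiments below account for it.

After fitting, `freeze` locks all probabilities (mutation attempts raise
`FrozenModelError`); per-context decision thresholds may still be added.
Re-thresholding for a new tissue keeps exactly the same model, preserving
quantitative comparability of scores across datasets.
`recalibrate_threshold` chooses the threshold from labelled scores by
exhaustive scan over the midpoints of adjacent sorted scores (plus one
candidate below and one above all scores), maximising either accuracy or
the Youden index; ties break toward the threshold nearest 0, then toward
the smaller value.

Candidate target genes can be ranked by a weighted evidence score over five
experimental categories (response-element motif, promoter functionality,
in-vivo binding, in-vitro binding, differential expression) plus a
corroboration bonus (default 0.5 per additional cell type or independent
research group).  The functional form is configuration: unit weights by
default, descending order, alphabetical tie-break.

## PI3K read-out and the SOD2 stress rule

The PI3K growth-factor pathway removes FOXO from the nucleus, so measured
FOXO transcriptional activity is inversely related to PI3K activity — the
PI3K score is minus the FOXO score — *unless* the cell is under oxidative
stress, in which case FOXO is alternatively activated and transcribes
protective targets such as SOD2.  A sample is flagged stressed when its
SOD2 expression **strictly** exceeds the reference mean + 2 SD (sample SD,
n − 1 denominator — reference sets are samples of normal tissue; the
boundary itself counts as non-stressed).  For a stressed sample the PI3K
score is withheld and the call is *indeterminate*.  When several probesets
measure SOD2, the sample level is their mean (configurable list of
probeset IDs).  Reference levels per tissue type are configuration inputs.

## Quality control

Of the dozen conventional array QC parameters, five are computable from an
expression matrix and are implemented: no negative intensities, no
intensities above the 16-bit ceiling (65535), mean intensity within a
configured band (default 50–5000), and GAPDH and ACTB 3′/5′ ratios at most
a configured cap (default 3.0; high ratios indicate RNA degradation).  The
remaining checks (spike-in controls, border controls, centre of intensity,
RNA degradation slope) need raw probe-level data; their slots appear in
every report as *not evaluable* and only fail a sample in strict mode.
All numeric thresholds are configuration, not claims about any particular
platform's recommended values.  Failed samples are dropped (order
preserved) before scoring; an all-failing matrix is a valid empty result.

## Synthetic data generator

The generator runs the network forward: the sample label fixes TC; gene
states are drawn from `P(up | TC)`; probeset states from `P(high | TG)`;
the observed intensity is `2^x − 1` with `x ~ Normal(μ_state, σ)`.
Defaults: μ_low = 6, μ_high = 10 (a 16-fold separation, typical of a
responsive probeset on log2 microarray scale) and σ = 0.5, i.e. the two
states sit 8σ apart.  σ was chosen so that the binary probeset state is
essentially recoverable from the intensity: the calibration round-trip
(below) is a statement about count-based CPT estimation, and a generator
whose discretisation layer injects extra state-flip noise would bias that
check by construction rather than test it.  Optional dropout deletes
values at a configured rate; everything derives from one seeded generator,
so a configuration is exactly reproducible.  The example model used across
tests and the acceptance script has 28 target genes × 2 probesets,
matching the typical 25–35 gene signatures such models are built from.

What the generator does **not** emulate: probe-level structure, batch and
lab effects, cross-hybridisation, tissue-specific baseline shifts, or
correlated biological noise between genes.  Passing tests therefore
demonstrate the correctness of inference, calibration and the surrounding
machinery under the model's own assumptions — not clinical performance on
real arrays.

## Validation experiments (tests and `scripts/acceptance.py`)

- **Inference vs enumeration:** 100+ random models (1–6 genes × 1–3
  probesets, random non-degenerate CPTs and soft evidence); the factorised
  posterior matches explicit joint enumeration within 1e-10.
- **Anchor:** `to_log2odds(0.5)` is exactly 0.
- **CPT recovery:** simulate 500 samples/class from a known model and
  refit; every CPT entry lands within ±0.05 of the generating value over
  10 seeds.  The generating model uses near-deterministic gene regulation
  (0.999/0.001) because hard assignment estimates the marginalised CPT
  (see above): with the default 0.90, the systematic gap alone is ~0.04
  and the check would measure the estimand gap, not estimation quality.
- **Round trip:** calibrate on 500/class, freeze, score 50/class held-out
  samples at threshold 0: ≥95% accuracy (in practice ~100%).
- **Permutation control:** refitting after permuting labels collapses all
  probeset likelihood ratios into (0.5, 2).  Note that a *single*
  permutation does not yield 50% accuracy: the mislabelling excess is a
  common factor across probesets, so each shuffled model is a weak copy of
  the true model with a random sign, and per-permutation accuracy lands
  near 0 or 1.  Chance level is therefore asserted on the mean over 100
  permutations (band 35–65%, ≈3σ of a fair coin at that repetition count).
- **Exact rank statistics:** for groups of up to 6 per arm the rank-sum
  p-value is computed by enumeration over all rank assignments (midranks
  under ties) and cross-checked against both a brute-force oracle and
  scipy's independent exact method; e.g. {1,2,3} vs {10,11,12} gives
  two-sided p = 0.1 (2 of 20 assignments).  Larger groups use the normal
  approximation with tie and continuity correction.  The paired signed-rank
  test delegates to scipy; all-zero differences are reported as a
  not-evaluable result.
- **Interpretation grid:** the SOD2 rule (mean + 2 SD, strict inequality)
  and the PI3K = −FOXO inversion are asserted exhaustively on a grid of
  scores, levels and thresholds.
- **Carriers:** model JSON (floats serialised via `repr`, hence bit-exact
  round-trips), expression TSV and GEO series-matrix fixtures round-trip
  exactly; QC flags constructed range violations.

Problem sizes above (500/class calibration, 50/class hold-out, 100 random
models, 100 permutations) are the package's standard experiment sizes; the
whole suite and the acceptance script each run in well under a minute.

## Numerical and design notes

- Probabilities in models are validated to lie strictly inside (0, 1);
  degenerate CPTs are rejected at construction.
- Intensities are treated as linear-scale throughout IO; the `log2(x + 1)`
  transform happens at exactly two sites (evidence construction and
  calibration counting), never at parse time.
- Missing values stay missing end-to-end and become "no observation".
- Unpaired comparisons default to the rank-sum test even where legacy
  figure legends would say "signed-rank"; both are available and the
  result records which was used.  No multiple-testing correction is
  applied by default.
- The series-matrix reader accepts quoted and unquoted identifiers and
  Windows line endings; it reads the expression table and `!Sample_*`
  annotation lines only.

## Known limitations

- Relation-(i) gene CPT defaults are informative stand-ins, not
  literature-derived values for any specific pathway; shipped example
  models are generic skeletons, not reproductions of published signatures.
- Calibration requires ≥1 sample per class per probeset after missing-value
  handling; heavily dropped-out probesets are rejected rather than imputed.
- No EM, no inter-gene edges, no approximate inference: the network is a
  tree by construction.
- CEL-level QC and normalisation (RMA/MAS5) are out of scope; inputs are
  assumed to be normalised expression matrices.
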