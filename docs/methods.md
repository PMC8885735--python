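# Methods

## Scope and data model

`genexpa` analyses balanced RT-qPCR panels: S samples × R biological
replicates × genes, with one **mean Ct** per biological replicate (technical
replicates are assumed averaged upstream). Two inputs drive a run: a Ct
table for all genes and a quantity table for the candidate reference genes.
Quantities are what the stability estimator consumes; they normally come
from a calibration curve, and a documented fallback derives them from Ct as
`efficiency^(−Ct)` with per-gene max-rescaling (perfect efficiency 2 by
default, opt-in from the CLI). Missing cells are rejected rather than
imputed — the variance decomposition below assumes complete, balanced data.
Sample order is taken verbatim from the file and treated as a contract: the
coherence score fixes the orientation of every sample pair.

## Model space

The experimental model is the full ordered sample set; daughter models are
all combinations of ≥ 2 samples, Σ_{r=2..n} C(n, r) = 2^n − n − 1 models in
total (26 for n = 5). Numbering is size-major, lexicographic by sample
position within a size, experimental model last, so exported tables are
stable across runs; the ordering convention beyond the canonical n = 5
design is this package's own choice. Every unordered pair of samples occurs
in exactly 2^(n−2) models. Model count grows exponentially; a warning is
emitted above n = 12 (~4083 models). The intended use case is n ≈ 5.

## Stability estimation

The NormFinder-type estimator works on y = log2(quantity). Base 2 is fixed
for reproducibility; rankings are base-invariant, and ρ values scale with
the log base. Per model and candidate pool of k ≥ 3 genes:

1. z_igj = y_igj − mean over the pool within (sample g, replicate j). This
   removes per-replicate loading effects exactly (per-replicate scaling
   invariance is asserted to 1e−12 in the tests) and makes stability
   *relative to the pool average* — the property that motivates progressive
   removal (below).
2. Intergroup deviations d_ig = z̄_ig − mean_g z̄_ig.
3. Within-sample variances s²_ig (ddof 1), bias-corrected to
   σ̂²_ig = (s²_ig − Ŝ_g/k²)/(1 − 2/k) with Ŝ_g = Σ_i s²_ig/(1 − 1/k);
   negative estimates are clamped to 0 (small-sample artifacts).
4. γ̂² = max(0, Σ d̂²/((G−1)(k−1)) − Σ(σ̂²/n_g)/(G·k)) — the variance of
   true intergroup variation across genes.
5. Shrinkage d̃ = d̂·γ̂²/(γ̂² + σ̂²/n_g), with 0/0 defined as 0;
   v = (σ̂²/n_g)·γ̂²/(γ̂² + σ̂²/n_g).
6. ρ_i = mean_g(|d̃_ig| + √v_ig);
   ρ_ab = mean_g(|(d̃_ag + d̃_bg)/2| + √((v_ag + v_bg)/4)).

Degenerate inputs are well-defined: exactly gene-exchangeable data give
γ̂² = 0 and every ρ = 0; clean within-model pools routinely hit γ̂² = 0 too,
in which case all candidates tie at 0 and tie-breaking decides. Ties are
fixed and documented: selection prefers a single gene over a pair at equal
ρ, then the lexicographically first name(s); removal drops the
lexicographically last among equally worst genes.

Samples play the role of NormFinder "groups" and biological replicates the
within-group observations. The minimum pool of 3 genes is enforced exactly
(the correction in step 3 divides by 1 − 2/k).

**Removal and level selection.** "Remove repetitions" r removes, per model,
the gene with the worst *single-gene* ρ and recomputes, r times ("least
stable gene" is a per-gene notion; pair scores are not used for removal).
Different models may remove different genes. With "select best remove", the
per-model reference comes from whichever level 0..r yielded the lowest
stability, which makes the chosen stability non-increasing in r (asserted).

The stability kernel is also exposed as a scikit-learn style estimator
(`NormFinderSelector`: `fit`, fitted attributes with trailing underscores,
`get_params`/`clone` compatible) for use in library code.

## Relative quantification

RQ = 2^(Ct_ref − Ct_target) per replicate, with the arithmetic mean of the
two Cts for a pair reference (geometric mean on the linear scale).
Efficiency 2 is assumed; no calibrator is divided out by default. Every
downstream quantity — medians' order, rank tests, t-tests within a model —
is invariant to a common positive rescaling of a model's RQ values, so the
calibrator (`--calibrator`) is cosmetic and skipped in models that do not
contain the calibrator sample. RQ is computed from Ct (quantified values
exist only for candidate genes in the intended inputs).

## Statistics

Default: two-sided pooled-variance t-tests on raw RQ for all C(m, 2) sample
pairs of a model, Holm step-down adjusted. The Holm family is all pairs
within one (model, target) analysis; pooling across targets or models would
couple unrelated analyses. Pooled rather than Welch because n = 3 per group
makes Welch degrees of freedom unstable; `--welch` and `--log-rq` switches
exist because both are defensible and are recorded in the run metadata.
Zero variance in both groups yields p = 1 at equal means (no evidence) and
p = 0 otherwise (an exactly reproduced difference). Alternatives:
Mann–Whitney U (exact p for groups ≤ 8 without cross-group ties, tie-
corrected normal approximation otherwise), and Kruskal–Wallis with Dunn's
post-hoc z-tests (Holm-adjusted, gated on the omnibus: all adjusted p are
forced to 1 when the omnibus p ≥ α; two-sample models fall back to
Mann–Whitney). Holm and Dunn are implemented directly from their
definitions (a handful of lines each) and verified against independent
oracles in the tests; normality is not auto-tested — the test choice is the
user's, as in the workflow this package automates.

## Coherence score

Per (target, ordered sample pair, model containing the pair): comparison
value 0 if adjusted p ≥ α, else the sign of median₁ − median₂ (equal
medians under significance map to 0 — unreachable with continuous RQ, kept
as a convention). Partial CS per pair is 0 iff both +1 and −1 occur among
the pair's 2^(n−2) comparisons; CS per target is the mean partial CS over
all C(n, 2) pairs; the run-level average CS is the unweighted mean over
targets. Adjusted p-values are the default significance source; `--raw-p`
exists for sensitivity analysis. With n = 2 there is a single model and
CS ≡ 1. CS is reported to 2 decimals in exports and kept at full precision
internally.

## Synthetic data

The generator emulates the intended input shape (default 5 samples × 3
replicates, 4 candidates, 7 targets) with Gaussian replicate noise on the
Ct scale — the standard qPCR replicate model — and derives candidate
quantities from the same draws as 2^(−Ct), max-rescaled. It does **not**
simulate amplification curves, technical-replicate structure, per-gene
efficiencies, or heavy-tailed outliers; passing tests therefore demonstrate
the machinery's behaviour under its own assumptions, not robustness to
messy real data.

Two scenarios with known ground truth:

* **Coherent**: all candidates stable (equal means, sd 0.1 cycles), target
  means strictly ordered in steps of 2 cycles (separation ≫ noise),
  alternating direction across targets. Any selected reference is unbiased,
  so the pipeline should certify CS = 1; the tests require this in
  ≥ 99/100 seeds.
* **Biased ("incoherent")**: three clean candidates plus one candidate
  shifted +3 cycles in the last 2 of 5 samples. Because stability is
  measured relative to the pool average, the pool-mean subtraction turns a
  +3-cycle bias into a +2.25 deviation for the biased gene and −0.75 for
  each clean gene (k = 4); a {biased, clean} pair then averages to +0.75 —
  the same magnitude as a clean pair's −0.75 — so the two kinds of pair
  reference are statistically tied and replicate noise decides each
  model's winner.
  The biased gene is deliberately *precise* (replicate sd half the clean
  genes'), the profile of a tight, highly expressed but regulated gene;
  its pairs' smaller variance penalty keeps them competitive, so models
  genuinely mix biased and clean references. Target steps (0.4
  cycles/sample) are below the 1.5-cycle bias a biased pair carries, so
  mixed references produce significant contradictory directions and
  CS < 1 at removal level 0 (in ≥ 90/100 seeds in the tests). The biased
  gene has by far the worst single-gene ρ in the experimental model, so
  one removal level deletes it wherever its bias is visible and restores
  coherence — the removal-rescues-coherence progression the workflow is
  built around.

## Problem sizes and numerical choices

Simulation-backed tests use 100 seeds per scenario and a 10,000-replicate
null simulation for the familywise-error check of the Holm family (3 groups
× 3 replicates), sizes chosen to keep the full suite around two minutes on
one core while leaving the binomial error of the estimated rates well below
the margins being asserted. The acceptance script uses 40 seeds per
scenario. Float exports use 6 significant digits (full 17 for data tables,
which must round-trip bit-exactly); reruns on identical inputs produce
byte-identical files.

## Known limitations

* The published stability values of the original five-cell-line melanoma
  panel cannot be recomputed here because the measured input tables are not
  redistributable; the corresponding reproduction test states exactly what
  it needs and fails until those tables are supplied. The estimator itself
  is instead validated against an independent step-by-step implementation
  of the formulas on randomized fixtures (agreement to 1e−6).
* Stability, not identity: NormFinder ranks candidates relative to the pool
  average, so a pool dominated by co-regulated genes can make a biased gene
  look stable; the coherence score detects the consequences but cannot name
  the culprit — the removal loop does that indirectly.
* geNorm/BestKeeper/ΔCt-method comparators, efficiency-corrected (Pfaffl)
  quantification, paired designs, and mixed models are out of scope.
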