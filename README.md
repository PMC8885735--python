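# genexpa

Reference-gene selection and **validation** for RT-qPCR experiments.

Relative quantification of a target transcript stands or falls with the
reference (housekeeping) gene used to normalize it, and the usual practice —
pick the candidate with the best stability value and move on — gives no
warning when that reference is still bad enough to invert a biological
conclusion. `genexpa` implements a workflow that makes normalization
*testable*: it selects references with the NormFinder model-based stability
estimator, repeats the selection in every daughter model (each combination
of ≥ 2 samples from the experiment), progressively removes the least stable
candidate gene, and then scores whether all those independently normalized
analyses tell one consistent story about each target gene. That score — the
coherence score (CS) — is 1 when no two models contradict each other and
drops below 1 the moment two models disagree about the significant direction
of a difference between two samples.

It is written for bench scientists analysing qPCR panels (samples ×
biological replicates × genes, mean Ct values per replicate) and for
methodologists who want the NormFinder machinery as a library.

## The model

For a candidate pool of k genes in a model of G samples with n_g replicates,
log2 expression y_igj (gene i, sample g, replicate j) is centred per
replicate on the pool mean, z_igj = y_igj − ȳ·gj, and decomposed into

* intergroup variation d_ig = z̄_ig − z̄_i· , shrunk toward 0 by the
  empirical-Bayes factor γ²/(γ² + σ²_ig/n_g),
* intragroup variance σ²_ig, a bias-corrected version of the replicate
  scatter s²_ig.

A gene's stability value is ρ_i = mean_g(|d̃_ig| + √v_ig) and a pair's is
ρ_ab = mean_g(|(d̃_ag + d̃_bg)/2| + √((v_ag + v_bg)/4)); lower is more
stable, and a pair can beat both its members when their biases cancel.
The reference for each model is the argmin over all single genes and pairs.

With "remove repetitions" r > 0, the gene with the worst single-gene ρ is
dropped (per model) and selection repeats, down to NormFinder's three-gene
minimum; "select best remove" takes, per model, whichever removal level
produced the lowest stability. Target genes are normalized as
RQ = 2^(Ct_ref − Ct_target), all sample pairs are tested per model
(pairwise pooled t-test with Holm step-down by default; Mann–Whitney or
Kruskal–Wallis + Dunn as alternatives), and each (target, sample-pair)
collects one comparison value in {−1, 0, +1} from every model containing
the pair. A pair's partial CS is 0 iff both +1 and −1 occur; CS is the mean
partial CS over all C(n,2) pairs.

## Worked example

Generate a synthetic 5-sample × 3-replicate panel in which one candidate
gene (`HKGX`) is precisely measured but shifted +3 cycles in two samples,
then analyse it at removal level 0 and again with one removal:

```sh
genexpa synth --scenario incoherent --seed 7 --out demo/data
genexpa run --ct demo/data/ct.csv --quant demo/data/quant.csv \
    --refs HKG1,HKG2,HKG3,HKGX --targets TG1,TG2,TG3,TG4,TG5,TG6,TG7 \
    --out demo/level0
genexpa run --ct demo/data/ct.csv --quant demo/data/quant.csv \
    --refs HKG1,HKG2,HKG3,HKGX --targets TG1,TG2,TG3,TG4,TG5,TG6,TG7 \
    --remove 1 --select-best-remove --out demo/level1
```

The first run prints

```
CS TG1: 0.50
CS TG2: 1.00
CS TG3: 0.60
CS TG4: 1.00
CS TG5: 0.70
CS TG6: 1.00
CS TG7: 0.60
average CS: 0.77
```

— four of the seven targets are *incoherent*: some models picked a
reference pair containing `HKGX` and reached significant conclusions
opposite to the models that picked a clean reference. The second run, which
removes the least stable gene in each model before selecting, prints
`CS 1.00` for every target and `average CS: 1.00`: one removal level
rescued the analysis, exactly the situation the score is designed to
expose. Each run writes `stability.csv`, `rq.csv`, `stats.csv`,
`coherence.csv`, `run_metadata.json`, and (unless `--no-plots`) one
box-plot PNG per model with red bars marking significant pairs.

The same machinery is available as a library, including a scikit-learn
style selector for the stability kernel:

```python
from genexpa import NormFinderSelector, generate_dataset, make_coherent_scenario

ct, quant = generate_dataset(make_coherent_scenario(seed=1))
sel = NormFinderSelector().fit(quant)
sel.reference_, sel.reference_stability_   # ('HKG2', 'HKG4'), 0.0269
sel.single_stability_                      # per-gene rho, most stable first
```

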