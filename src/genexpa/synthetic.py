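"""Synthetic qPCR datasets with known ground truth.

The generator emulates the input shape of the study design this package
targets: S samples (cell lines) x R biological replicates x (candidate
reference + target) genes, one mean Ct per replicate, Gaussian replicate
noise on the Ct scale (the standard qPCR replicate model; one cycle = one
log2 unit).  Quantified values for the candidate genes are derived from the
same Ct draws as efficiency**(-Ct), max-rescaled per gene — consistent with
the quantification fallback in :mod:`genexpa.tables`.

Two ready-made scenarios bracket the method's behaviour:

* :func:`make_coherent_scenario` — every candidate reference is stable and
  target means are strictly ordered with a separation well above the noise,
  so any selected reference is unbiased and the coherence score is 1.
* :func:`make_incoherent_scenario` — one candidate carries a strong
  sample-dependent bias (+3 cycles in 2 of 5 samples by default).  Because
  NormFinder measures stability relative to the pool average, a pair made of
  the biased gene and a clean gene is statistically tied with the clean
  pairs and singles, so replicate noise decides the winner model by model;
  models that adopt a biased pair contradict models that do not, driving
  CS below 1 at removal level 0.  One round of least-stable-gene removal
  deletes the biased gene wherever its bias is visible and restores CS = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import (
    CT_SCALE,
    QUANTITY_SCALE,
    ExpressionTable,
    derive_quantities_from_ct,
)


@dataclass(frozen=True)
class GeneSpec:
    """Ground truth for one gene: per-sample mean Ct and replicate noise."""

    name: str
    base_ct: float
    sample_offsets: tuple[float, ...]  # added to base_ct, one per sample
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0 for {self.name}")
        if not all(np.isfinite(self.sample_offsets)) or not np.isfinite(self.base_ct):
            raise ValidationError(f"non-finite mean Ct for {self.name}")


@dataclass(frozen=True)
class SyntheticSpec:
    samples: tuple[str, ...]
    candidate_genes: tuple[GeneSpec, ...]
    target_genes: tuple[GeneSpec, ...]
    n_replicates: int = 3
    efficiency: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for gene in self.candidate_genes + self.target_genes:
            if len(gene.sample_offsets) != len(self.samples):
                raise ValidationError(
                    f"{gene.name}: {len(gene.sample_offsets)} offsets for "
                    f"{len(self.samples)} samples"
                )
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates")

    @property
    def candidate_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.candidate_genes)

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.target_genes)


def generate_dataset(spec: SyntheticSpec,
                     seed: int | None = None) -> tuple[ExpressionTable, ExpressionTable]:
    """Draw one dataset: a Ct table (all genes) and a quantity table
    (candidate genes only), reproducible from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = spec.candidate_genes + spec.target_genes
    index = pd.MultiIndex.from_product(
        [spec.samples, range(1, spec.n_replicates + 1)],
        names=["sample", "replicate"],
    )
    columns = {}
    for gene in genes:
        means = np.repeat(
            gene.base_ct + np.asarray(gene.sample_offsets), spec.n_replicates
        )
        columns[gene.name] = means + rng.normal(0.0, gene.noise_sd, means.shape)
    ct = ExpressionTable(pd.DataFrame(columns, index=index), CT_SCALE)
    quant = derive_quantities_from_ct(
        ct, efficiency=spec.efficiency, genes=spec.candidate_names
    )
    return ct, quant


def make_coherent_scenario(n_samples: int = 5, n_replicates: int = 3,
                           n_candidates: int = 4, n_targets: int = 7,
                           effect_cycles: float = 2.0, noise_sd: float = 0.1,
                           seed: int = 0) -> SyntheticSpec:
    """Stable references, strictly ordered targets: the pipeline should
    certify CS = 1 for every target when separation >> noise."""
    samples = tuple(f"S{i + 1}" for i in range(n_samples))
    zero = (0.0,) * n_samples
    candidates = tuple(
        GeneSpec(f"HKG{i + 1}", 20.0, zero, noise_sd) for i in range(n_candidates)
    )
    targets = []
    for t in range(n_targets):
        # strictly ordered per-sample means; alternate direction across
        # targets so both comparison signs are exercised
        steps = np.arange(n_samples, dtype=float) * effect_cycles
        if t % 2:
            steps = steps[::-1]
        targets.append(GeneSpec(f"TG{t + 1}", 24.0, tuple(steps), noise_sd))
    return SyntheticSpec(samples, candidates, tuple(targets),
                         n_replicates=n_replicates, seed=seed)


def make_incoherent_scenario(n_samples: int = 5, n_replicates: int = 3,
                             n_clean: int = 3, n_targets: int = 7,
                             bias_cycles: float = 3.0, n_biased_samples: int = 2,
                             target_step_cycles: float = 0.4,
                             noise_sd: float = 0.1,
                             bias_noise_sd: float | None = None,
                             seed: int = 0) -> SyntheticSpec:
    """One candidate with a strong sample-dependent bias among clean ones.

    The biased gene ("HKGX") is shifted by ``bias_cycles`` in the last
    ``n_biased_samples`` samples and is technically *precise* — its
    replicate noise defaults to half the clean genes' (``bias_noise_sd``),
    the profile of a tight, highly expressed housekeeping gene that is
    nevertheless regulated differently in part of the panel.  The precision
    gives {biased, clean} pair references a small variance advantage that
    keeps them competitive with the clean pairs, so which kind wins varies
    from model to model.  Target means step by ``target_step_cycles`` per
    sample — smaller than the bias carried by a {biased, clean} pair
    reference (bias_cycles / 2) — so models that adopt a biased pair flip
    the significant direction of cross-bias sample pairs.
    """
    if n_biased_samples >= n_samples:
        raise ValidationError("some samples must stay unbiased")
    samples = tuple(f"S{i + 1}" for i in range(n_samples))
    zero = (0.0,) * n_samples
    candidates = [
        GeneSpec(f"HKG{i + 1}", 20.0, zero, noise_sd) for i in range(n_clean)
    ]
    bias = np.zeros(n_samples)
    bias[-n_biased_samples:] = bias_cycles
    candidates.append(GeneSpec("HKGX", 20.0, tuple(bias),
                               noise_sd / 2 if bias_noise_sd is None
                               else bias_noise_sd))
    targets = []
    for t in range(n_targets):
        steps = np.arange(n_samples, dtype=float) * target_step_cycles
        if t % 2:
            steps = steps[::-1]
        targets.append(GeneSpec(f"TG{t + 1}", 24.0, tuple(steps), noise_sd))
    return SyntheticSpec(samples, tuple(candidates), tuple(targets),
                         n_replicates=n_replicates, seed=seed)


BIASED_GENE = "HKGX"
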