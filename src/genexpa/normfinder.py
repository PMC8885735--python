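"""Model-based reference-gene stability estimation (NormFinder).

The estimator decomposes log-scale expression of each candidate gene into
intergroup variation (how much the gene's level moves between samples, after
removing the per-replicate average over the candidate pool) and intragroup
variance (replicate scatter).  Samples — cell lines in the original design —
play the role of groups; biological replicates are the within-group
observations.  A gene's stability value rho combines both components; lower
is more stable.  Gene pairs are scored by averaging the two genes' shrunken
intergroup deviations, which lets opposite biases cancel.

Notation (k genes in pool, G samples in model, n_g replicates in sample g):

    y_igj   log2 quantity of gene i, sample g, replicate j
    z_igj   y_igj - mean over pool genes within (g, j)
    d_ig    intergroup deviation: mean_j z_igj - mean_g mean_j z_igj
    s2_ig   raw within-sample variance of z_igj over replicates
    sig2_ig bias-corrected within-sample variance (clamped at 0)
    gamma2  variance of the intergroup deviations across genes and samples
    dt_ig   shrunken deviation d_ig * gamma2 / (gamma2 + sig2_ig / n_g)
    v_ig    (sig2_ig / n_g) * gamma2 / (gamma2 + sig2_ig / n_g)

    rho_i   = mean_g ( |dt_ig| + sqrt(v_ig) )
    rho_ab  = mean_g ( |(dt_ag + dt_bg) / 2| + sqrt((v_ag + v_bg) / 4) )

The per-replicate pool-mean subtraction makes every rho invariant to scaling
all of one replicate's quantities by a positive constant (loading/pipetting
differences), and means stability is always measured *relative to the pool*:
a gene biased like the pool average looks stable.  Progressive removal of
the worst gene (see :func:`remove_least_stable`) counters exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    InsufficientReplicatesError,
    PoolExhaustedError,
    ValidationError,
)
from .models import Model
from .tables import MIN_POOL, QUANTITY_SCALE, ExpressionTable

LOG_BASE = 2.0


@dataclass(frozen=True)
class StabilityTable:
    """All single- and pair-gene stabilities for one model at one level."""

    model_id: int
    removal_level: int
    pool: tuple[str, ...]
    removed_genes: tuple[str, ...]
    single_stability: dict[str, float]
    pair_stability: dict[tuple[str, str], float]


@dataclass(frozen=True)
class ReferenceAssignment:
    """The reference chosen for one model: a gene or an unordered pair."""

    model_id: int
    reference: tuple[str, ...]  # length 1 or 2
    stability: float
    chosen_level: int

    @property
    def label(self) -> str:
        return "/".join(self.reference)


def _log_matrix(quant: ExpressionTable, samples: Sequence[str],
                pool: Sequence[str]) -> list[np.ndarray]:
    """Per-sample (n_g, k) matrices of log2 quantities."""
    out = []
    for sample in samples:
        block = quant.data.loc[sample, list(pool)].to_numpy(dtype=float)
        if block.ndim == 1:
            block = block[None, :]
        if block.shape[0] < 2:
            raise InsufficientReplicatesError(
                f"insufficient replicates: sample {sample!r} has "
                f"{block.shape[0]} (need >= 2)", sample=sample,
            )
        out.append(np.log2(block))
    return out


def _stability_components(blocks: list[np.ndarray]):
    """Shrunken deviations dt (G, k) and variances v (G, k) for the pool."""
    k = blocks[0].shape[1]
    G = len(blocks)
    zbar = np.empty((G, k))
    s2 = np.empty((G, k))
    n = np.empty(G)
    for g, y in enumerate(blocks):
        z = y - y.mean(axis=1, keepdims=True)  # per-replicate pool-mean removal
        zbar[g] = z.mean(axis=0)
        s2[g] = z.var(axis=0, ddof=1)
        n[g] = z.shape[0]
    d = zbar - zbar.mean(axis=0, keepdims=True)

    # bias-corrected within-sample variances (negative estimates clamped)
    S = s2.sum(axis=1) / (1.0 - 1.0 / k)  # per sample
    sig2 = (s2 - (S / k ** 2)[:, None]) / (1.0 - 2.0 / k)
    sig2 = np.clip(sig2, 0.0, None)

    sig2_n = sig2 / n[:, None]
    gamma2 = max(
        0.0,
        float((d ** 2).sum() / ((G - 1) * (k - 1)) - sig2_n.sum() / (G * k)),
    )
    denom = gamma2 + sig2_n
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0.0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
    dt = d * shrink
    v = sig2_n * shrink
    return dt, v


def stability_for_pool(quant: ExpressionTable, model: Model | Sequence[str],
                       pool: Sequence[str], *, removal_level: int = 0,
                       removed_genes: Sequence[str] = ()) -> StabilityTable:
    """Single- and pair-gene stability values for ``pool`` within ``model``."""
    samples, model_id = _model_samples(model)
    pool = tuple(pool)
    if len(pool) < MIN_POOL:
        raise PoolExhaustedError(
            f"pool exhausted: NormFinder needs >= {MIN_POOL} genes, got {len(pool)}"
        )
    if len(samples) < 2:
        raise ValidationError("a model needs >= 2 samples")
    if quant.scale != QUANTITY_SCALE:
        raise ValidationError("stability is computed on quantity-scale data")
    blocks = _log_matrix(quant, samples, pool)
    dt, v = _stability_components(blocks)

    single = {
        gene: float(np.mean(np.abs(dt[:, i]) + np.sqrt(v[:, i])))
        for i, gene in enumerate(pool)
    }
    pair = {
        (pool[i], pool[j]): float(np.mean(
            np.abs((dt[:, i] + dt[:, j]) / 2.0)
            + np.sqrt((v[:, i] + v[:, j]) / 4.0)
        ))
        for i, j in combinations(range(len(pool)), 2)
    }
    return StabilityTable(model_id, removal_level, pool, tuple(removed_genes),
                          single, pair)


def select_reference(stab: StabilityTable) -> ReferenceAssignment:
    """Most stable reference: argmin over single genes and gene pairs.

    Ties prefer a single gene over a pair, then the lexicographically first
    gene name(s).
    """
    candidates: list[tuple[float, int, tuple[str, ...]]] = [
        (rho, 0, (gene,)) for gene, rho in stab.single_stability.items()
    ]
    candidates += [
        (rho, 1, tuple(sorted(pair))) for pair, rho in stab.pair_stability.items()
    ]
    rho, _, reference = min(candidates)
    return ReferenceAssignment(stab.model_id, reference, rho, stab.removal_level)


def remove_least_stable(quant: ExpressionTable, model: Model | Sequence[str],
                        pool: Sequence[str], r: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Iteratively drop the gene with the worst single-gene stability, r times.

    Removal is per model: recomputed on the current pool within this model,
    so different models may shed different genes.  Ties remove the
    lexicographically last gene.
    """
    pool = tuple(pool)
    if len(pool) - r < MIN_POOL:
        raise PoolExhaustedError(
            f"pool exhausted: removing {r} from {len(pool)} genes goes below "
            f"the {MIN_POOL}-gene minimum required for NormFinder selection"
        )
    removed: list[str] = []
    for _ in range(r):
        stab = stability_for_pool(quant, model, pool)
        worst = max(stab.single_stability.items(), key=lambda kv: (kv[1], kv[0]))[0]
        removed.append(worst)
        pool = tuple(g for g in pool if g != worst)
    return pool, tuple(removed)


def select_best_across_levels(
        assignments: Sequence[ReferenceAssignment]) -> ReferenceAssignment:
    """The assignment with the lowest stability across removal levels.

    Ties go to the lowest level (fewest genes removed).
    """
    if not assignments:
        raise ValidationError("no assignments to choose from")
    return min(assignments, key=lambda a: (a.stability, a.chosen_level))


def assign_references(quant: ExpressionTable, model: Model | Sequence[str],
                      candidates: Sequence[str], remove_repetitions: int = 0,
                      select_best_remove: bool = False,
                      ) -> tuple[ReferenceAssignment, list[StabilityTable]]:
    """Run the removal loop for one model and pick its reference.

    Levels 0..remove_repetitions are evaluated; the final assignment is the
    last level's, or the best across levels when ``select_best_remove``.
    """
    pool = tuple(candidates)
    if len(pool) - remove_repetitions < MIN_POOL:
        raise PoolExhaustedError(
            f"pool exhausted: {len(pool)} candidates minus {remove_repetitions} "
            f"removals is below the {MIN_POOL}-gene minimum"
        )
    removed: list[str] = []
    levels: list[StabilityTable] = []
    per_level: list[ReferenceAssignment] = []
    for level in range(remove_repetitions + 1):
        stab = stability_for_pool(quant, model, pool, removal_level=level,
                                  removed_genes=removed)
        levels.append(stab)
        per_level.append(select_reference(stab))
        if level < remove_repetitions:
            worst = max(stab.single_stability.items(),
                        key=lambda kv: (kv[1], kv[0]))[0]
            removed.append(worst)
            pool = tuple(g for g in pool if g != worst)
    final = (select_best_across_levels(per_level) if select_best_remove
             else per_level[-1])
    return final, levels


def _model_samples(model: Model | Sequence[str]) -> tuple[tuple[str, ...], int]:
    if isinstance(model, Model):
        return model.samples, model.model_id
    return tuple(model), 0


class NormFinderSelector(BaseEstimator):
    """Scikit-learn style selector for the most stable reference gene(s).

    Fit on a quantity-scale table (or a DataFrame with a two-level
    ``(sample, replicate)`` row index and one column per candidate gene);
    samples act as groups.

    Parameters
    ----------
    pool : sequence of str, optional
        Candidate genes; defaults to every column.
    remove_repetitions : int, default 0
        Removal level r: drop the least stable gene r times before selecting.
    select_best_remove : bool, default False
        Pick the reference from whichever removal level 0..r gave the lowest
        stability.

    Attributes
    ----------
    single_stability_ : pandas.Series
        rho per gene at the final removal level, ascending (most stable first).
    pair_stability_ : dict[tuple[str, str], float]
        rho per gene pair at the final removal level.
    reference_ : tuple[str, ...]
        Selected reference (one gene or a pair).
    reference_stability_ : float
    removed_genes_ : tuple[str, ...]
        Genes shed by the removal loop, in removal order.
    levels_ : list[StabilityTable]
        Full stability tables for levels 0..r.
    """

    def __init__(self, pool=None, remove_repetitions=0, select_best_remove=False):
        self.pool = pool
        self.remove_repetitions = remove_repetitions
        self.select_best_remove = select_best_remove

    def fit(self, X, y=None):
        table = self._as_table(X)
        pool = tuple(self.pool) if self.pool is not None else table.genes
        assignment, levels = assign_references(
            table, table.samples, pool,
            remove_repetitions=self.remove_repetitions,
            select_best_remove=self.select_best_remove,
        )
        chosen = levels[assignment.chosen_level]
        self.single_stability_ = pd.Series(
            chosen.single_stability, name="stability").sort_values(kind="stable")
        self.pair_stability_ = dict(chosen.pair_stability)
        self.reference_ = assignment.reference
        self.reference_stability_ = assignment.stability
        self.removed_genes_ = levels[-1].removed_genes
        self.levels_ = levels
        return self

    @staticmethod
    def _as_table(X) -> ExpressionTable:
        if isinstance(X, ExpressionTable):
            if X.scale != QUANTITY_SCALE:
                raise ValidationError("fit expects quantity-scale data")
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionTable(X, QUANTITY_SCALE)
        raise ValidationError(
            "X must be an ExpressionTable or a (sample, replicate)-indexed DataFrame"
        )
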