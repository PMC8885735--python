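"""Per-model pairwise significance testing of normalized target expression.

Three options mirror the tool's statistical-model menu:

* pairwise t-test with Holm step-down adjustment (default; normal data),
* Mann-Whitney U (two unmatched samples; applied pairwise with Holm for
  larger models),
* Kruskal-Wallis omnibus with Dunn's post-hoc z-tests, Holm-adjusted
  (three or more unmatched samples).

The Holm family is always the set of sample pairs within one
(model, target gene) analysis: pooling across genes or models would couple
unrelated analyses.  Tests run on raw RQ by default (``log=True`` switches
to log2 RQ for the t-test); medians are always reported on the raw scale,
whose ordering the comparison values downstream depend on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .models import Model


@dataclass(frozen=True)
class PairTestResult:
    """One pairwise comparison of a target gene between two samples."""

    model_id: int
    target_gene: str
    pair: tuple[str, str]  # ordered per universe
    raw_p: float
    adj_p: float
    median_1: float
    median_2: float


def _groups(rq: pd.Series, samples: Sequence[str]) -> dict[str, np.ndarray]:
    return {s: rq.loc[s].to_numpy(dtype=float) for s in samples}


def holm_adjust(raw: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending, multiply the i-th smallest of m by (m - i), enforce
    monotonicity with a running maximum, cap at 1.
    """
    raw = np.asarray(raw, dtype=float)
    m = len(raw)
    order = np.argsort(raw, kind="stable")
    stepped = raw[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


_holm = holm_adjust


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided pooled-variance two-sample t-test p-value."""
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    if sp2 == 0.0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return float(2.0 * sps.t.sf(abs(t), df))


def _finish(model_id: int, target: str, pairs, raw, medians,
            adj=None) -> list[PairTestResult]:
    adj = _holm(raw) if adj is None else adj
    return [
        PairTestResult(model_id, target, pair, float(p), float(min(a, 1.0)),
                       medians[pair[0]], medians[pair[1]])
        for pair, p, a in zip(pairs, raw, adj)
    ]


def _model_info(model: Model | Sequence[str]) -> tuple[tuple[str, ...], int]:
    if isinstance(model, Model):
        return model.samples, model.model_id
    return tuple(model), 0


def pairwise_t_holm(rq: pd.Series, model: Model | Sequence[str], target: str,
                    *, welch: bool = False, log: bool = False) -> list[PairTestResult]:
    """Two-sided two-sample t-tests for all sample pairs, Holm-adjusted.

    Pooled-variance by default (``welch=True`` switches).  Zero variance in
    both groups yields p = 1 for equal means (no evidence of a difference)
    and p = 0 otherwise (an exactly reproduced difference).
    """
    samples, model_id = _model_info(model)
    groups = _groups(rq, samples)
    medians = {s: float(np.median(g)) for s, g in groups.items()}
    data = {s: np.log2(g) for s, g in groups.items()} if log else groups
    pairs = list(combinations(samples, 2))
    raw = []
    for a, b in pairs:
        x, y = data[a], data[b]
        if np.var(x) == 0.0 and np.var(y) == 0.0:
            raw.append(1.0 if np.mean(x) == np.mean(y) else 0.0)
            continue
        if welch:
            p = sps.ttest_ind(x, y, equal_var=False).pvalue
            raw.append(1.0 if np.isnan(p) else float(p))
        else:
            raw.append(_pooled_t(x, y))
    return _finish(model_id, target, pairs, raw, medians)


def mann_whitney(rq: pd.Series, model: Model | Sequence[str],
                 target: str) -> list[PairTestResult]:
    """Two-sided Mann-Whitney U for all sample pairs, Holm-adjusted.

    Exact p-values when both groups have <= 8 observations and no ties span
    the groups; the tie-corrected normal approximation otherwise.
    """
    samples, model_id = _model_info(model)
    groups = _groups(rq, samples)
    medians = {s: float(np.median(g)) for s, g in groups.items()}
    pairs = list(combinations(samples, 2))
    raw = []
    for a, b in pairs:
        x, y = groups[a], groups[b]
        if np.array_equal(np.sort(x), np.sort(y)):
            raw.append(1.0)
            continue
        pooled = np.concatenate([x, y])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
        p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        raw.append(float(min(p, 1.0)))
    return _finish(model_id, target, pairs, raw, medians)


def kruskal_omnibus(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn(rq: pd.Series, model: Model | Sequence[str], target: str,
                 *, alpha: float = 0.05) -> list[PairTestResult]:
    """Kruskal-Wallis omnibus + Dunn's pairwise z-tests (Holm-adjusted).

    Requires >= 3 samples.  A non-significant omnibus (p >= alpha) forces
    every pairwise adjusted p to 1: post-hoc contrasts are only read when
    the omnibus rejects.
    """
    samples, model_id = _model_info(model)
    if len(samples) < 3:
        raise ValidationError(
            "kruskal_dunn needs >= 3 samples; use mann_whitney for 2"
        )
    groups = _groups(rq, samples)
    medians = {s: float(np.median(g)) for s, g in groups.items()}
    pairs = list(combinations(samples, 2))
    arrays = [groups[s] for s in samples]
    if all(np.array_equal(np.sort(a), np.sort(arrays[0])) for a in arrays[1:]) \
            and all(np.var(a) == 0 for a in arrays):
        raw = [1.0] * len(pairs)
        return _finish(model_id, target, pairs, raw, medians,
                       adj=np.ones(len(pairs)))
    _, omnibus_p = kruskal_omnibus(arrays)

    # Dunn's z statistics from pooled mid-ranks with tie correction
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    sizes = {s: len(groups[s]) for s in samples}
    offsets = np.cumsum([0] + [sizes[s] for s in samples[:-1]])
    mean_rank = {
        s: float(ranks[o:o + sizes[s]].mean()) for s, o in zip(samples, offsets)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    raw = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        raw.append(float(2.0 * sps.norm.sf(abs(z))))
    adj = _holm(raw)
    if omnibus_p >= alpha:
        adj = np.ones(len(pairs))
    return _finish(model_id, target, pairs, raw, medians, adj=adj)


def run_tests(rq: pd.Series, model: Model | Sequence[str], target: str,
              method: str, *, alpha: float = 0.05, welch: bool = False,
              log: bool = False) -> list[PairTestResult]:
    """Dispatch on the configured statistical model.

    ``kruskal_dunn`` falls back to Mann-Whitney for two-sample models, the
    recommended test at that size.
    """
    samples, _ = _model_info(model)
    if method == "pairwise_t_holm":
        return pairwise_t_holm(rq, model, target, welch=welch, log=log)
    if method == "mann_whitney":
        return mann_whitney(rq, model, target)
    if method == "kruskal_dunn":
        if len(samples) < 3:
            return mann_whitney(rq, model, target)
        return kruskal_dunn(rq, model, target, alpha=alpha)
    raise ValidationError(f"unknown stat method {method!r}")
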