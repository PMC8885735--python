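"""Coherence score (CS): does normalization support one biological story?

For a target gene and an ordered sample pair (a, b), every model containing
both samples contributes a comparison value: 0 when the pair's adjusted
p-value is not significant, +1 when significant with median RQ(a) above
median RQ(b), -1 when below.  A pair is coherent (partial CS = 1) unless
both +1 and -1 occur among its models — a direct contradiction between
models that differ only in which other samples (and hence which reference)
they carry.  The CS of a target gene is the arithmetic mean of partial CS
over all C(n, 2) sample pairs, and the run-level average CS is the
unweighted mean over target genes.  CS = 1 certifies the analysis; CS < 1
says the chosen references do not support a consistent conclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .models import ModelSpace
from .stats import PairTestResult


@dataclass(frozen=True)
class ComparisonRecord:
    target_gene: str
    pair: tuple[str, str]
    model_id: int
    comparison: int  # -1, 0, +1


@dataclass(frozen=True)
class CoherenceReport:
    target_gene: str
    partial_cs: dict[tuple[str, str], int]
    cs: float
    comparisons: tuple[ComparisonRecord, ...]


def comparison_value(result: PairTestResult, alpha: float) -> int:
    """Signed significance of a pairwise comparison.

    Not significant (adj_p >= alpha) -> 0; otherwise the sign of
    median_1 - median_2 with the pair's fixed sample order (exactly equal
    medians map to 0; unreachable with continuous RQ, kept as a convention).
    """
    if result.adj_p >= alpha:
        return 0
    if result.median_1 > result.median_2:
        return 1
    if result.median_1 < result.median_2:
        return -1
    return 0


def partial_cs(comparisons: Iterable[int]) -> int:
    """1 unless the comparisons contain both +1 and -1 (a contradiction)."""
    values = set(comparisons)
    if not values:
        raise ValidationError("partial_cs of an empty comparison set")
    return 0 if (1 in values and -1 in values) else 1


def coherence_score(partials: Mapping[tuple[str, str], int]) -> float:
    """Arithmetic mean of partial CS over all sample pairs."""
    if not partials:
        raise ValidationError("coherence_score needs at least one pair")
    return float(np.mean(list(partials.values())))


def average_cs(per_gene_cs: Sequence[float]) -> float:
    """Unweighted mean CS over target genes."""
    if not len(per_gene_cs):
        raise ValidationError("average_cs of no target genes")
    return float(np.mean(per_gene_cs))


def build_report(space: ModelSpace, target: str,
                 results: Mapping[int, Sequence[PairTestResult]],
                 alpha: float, *, use_adjusted_p: bool = True) -> CoherenceReport:
    """Assemble comparison values, partial CS, and CS for one target gene.

    ``results`` maps model_id to that model's pairwise test results for this
    target.  Each universe pair draws one comparison from every model
    containing it — 2^(n-2) values per pair.
    """
    records: list[ComparisonRecord] = []
    partials: dict[tuple[str, str], int] = {}
    for pair, model_ids in space.pair_index.items():
        values = []
        for mid in model_ids:
            match = [r for r in results[mid] if r.pair == pair]
            if len(match) != 1:
                raise ValidationError(
                    f"expected one test result for pair {pair} in model {mid}, "
                    f"got {len(match)}"
                )
            result = match[0]
            if not use_adjusted_p:
                result = PairTestResult(result.model_id, result.target_gene,
                                        result.pair, result.raw_p, result.raw_p,
                                        result.median_1, result.median_2)
            value = comparison_value(result, alpha)
            values.append(value)
            records.append(ComparisonRecord(target, pair, mid, value))
        partials[pair] = partial_cs(values)
    return CoherenceReport(target, partials, coherence_score(partials),
                           tuple(records))
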