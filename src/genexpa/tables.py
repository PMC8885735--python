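"""Input tables for the analysis: replicate-level expression measurements.

Two tables drive a run: mean Ct values per biological replicate for every
candidate-reference and target gene, and calibration-curve quantified values
for the candidate reference genes.  Both share one layout — a wide CSV with
header ``sample,replicate,<gene1>,<gene2>,...`` and one row per biological
replicate — and both are held in an :class:`ExpressionTable`.

Sample order is the file's first-appearance order and is preserved verbatim:
downstream, the coherence score fixes the order of samples, so the order a
user uploads is a contract, not a cosmetic detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateReplicateError,
    IncompleteTableError,
    NonPositiveQuantityError,
    PoolExhaustedError,
    TableFormatError,
    ValidationError,
)

CT_SCALE = "ct"
QUANTITY_SCALE = "quantity"

#: NormFinder's variance correction divides by (1 - 2/k); three genes is the
#: hard minimum pool size.
MIN_POOL = 3


@dataclass(frozen=True)
class ExpressionTable:
    """Replicate-level measurements indexed by (sample, replicate) x gene.

    Parameters
    ----------
    data
        DataFrame with a two-level ``(sample, replicate)`` MultiIndex and one
        column per gene.  Row order encodes sample order.
    scale
        ``"ct"`` (cycle thresholds) or ``"quantity"`` (calibration-curve
        quantities, strictly positive).
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self):
        if self.scale not in (CT_SCALE, QUANTITY_SCALE):
            raise TableFormatError(f"unknown scale {self.scale!r}", scale=self.scale)
        validate_table_frame(self.data, self.scale)

    # -- structure ---------------------------------------------------------

    @property
    def samples(self) -> tuple[str, ...]:
        """Samples in first-appearance order."""
        return tuple(pd.unique(self.data.index.get_level_values(0)))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def replicates_per_sample(self) -> dict[str, int]:
        counts = self.data.groupby(level=0, sort=False).size()
        return dict(counts.items())

    def values(self, sample: str, gene: str) -> np.ndarray:
        """All replicate values for one (sample, gene), replicate-ordered."""
        return self.data.loc[sample, gene].to_numpy(dtype=float)

    def subset(self, samples: Sequence[str] | None = None,
               genes: Sequence[str] | None = None) -> "ExpressionTable":
        frame = self.data
        if samples is not None:
            frame = frame.loc[list(samples)]
        if genes is not None:
            frame = frame[list(genes)]
        return ExpressionTable(frame, self.scale)


def validate_table_frame(frame: pd.DataFrame, scale: str) -> None:
    if frame.index.nlevels != 2:
        raise TableFormatError("expected a (sample, replicate) row index")
    if frame.index.duplicated().any():
        sample, rep = frame.index[frame.index.duplicated()][0]
        raise DuplicateReplicateError(
            f"duplicate replicate: sample {sample!r} replicate {rep!r}",
            sample=sample, replicate=rep,
        )
    if frame.empty or not len(frame.columns):
        raise TableFormatError("table has no data")
    values = frame.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        sample, rep = frame.index[i]
        raise IncompleteTableError(
            f"incomplete table: missing value at sample {sample!r} "
            f"replicate {rep!r} gene {frame.columns[j]!r}",
            sample=sample, replicate=rep, gene=frame.columns[j],
        )
    if scale == QUANTITY_SCALE and (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        sample, rep = frame.index[i]
        raise NonPositiveQuantityError(
            f"non-positive quantity at sample {sample!r} replicate {rep!r} "
            f"gene {frame.columns[j]!r}",
            sample=sample, replicate=rep, gene=frame.columns[j],
        )


def table_from_mapping(values: Mapping[tuple[str, int, str], float],
                       scale: str) -> ExpressionTable:
    """Build a table from a ``(sample, replicate, gene) -> value`` mapping."""
    records: dict[tuple[str, int], dict[str, float]] = {}
    genes: list[str] = []
    for (sample, rep, gene), value in values.items():
        records.setdefault((sample, rep), {})[gene] = value
        if gene not in genes:
            genes.append(gene)
    index = pd.MultiIndex.from_tuples(records.keys(), names=["sample", "replicate"])
    frame = pd.DataFrame([records[key] for key in records], index=index)[genes]
    return ExpressionTable(frame, scale)


def read_expression_table(path: str | Path, scale: str) -> ExpressionTable:
    """Read a wide CSV (``sample,replicate,gene...``) into a table.

    Sample order is first-appearance order; replicate indices must be unique
    per sample (they are reported as read; contiguity from 1 is the expected
    convention but any unique labels are accepted).
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = list(frame.columns)
    if len(cols) < 3 or cols[0] != "sample" or cols[1] != "replicate":
        raise TableFormatError(
            f"{path}: header must be 'sample,replicate,<genes...>', got {cols[:3]}",
            path=str(path),
        )
    frame["sample"] = frame["sample"].astype(str)
    frame = frame.set_index(["sample", "replicate"])
    return ExpressionTable(frame, scale)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write the CSV layout read by :func:`read_expression_table`.

    Floats are written with 17 significant digits so write-then-read is
    bit-exact.
    """
    frame = table.data.reset_index()
    frame.to_csv(path, index=False, float_format="%.17g")


def derive_quantities_from_ct(ct: ExpressionTable, efficiency: float = 2.0,
                              genes: Sequence[str] | None = None) -> ExpressionTable:
    """Fallback quantification when no calibration curve is available.

    quantity(s, r, g) = efficiency ** (-Ct(s, r, g)), rescaled per gene so the
    gene's maximum quantity is 1.  With perfect efficiency 2 this is the usual
    one-cycle-per-doubling model.  The per-gene rescaling makes the result
    exactly invariant to adding a per-gene constant to Ct.
    """
    if ct.scale != CT_SCALE:
        raise ValidationError("derive_quantities_from_ct expects a Ct-scale table")
    if not (1.0 < efficiency <= 2.0):
        raise ValidationError(
            f"efficiency must be in (1, 2], got {efficiency}", efficiency=efficiency
        )
    frame = ct.data if genes is None else ct.data[list(genes)]
    # exponentiate relative to the per-gene minimum Ct for numerical safety;
    # this is identical to eff**(-Ct) followed by max-rescaling.
    min_ct = frame.min(axis=0)
    quant = np.power(efficiency, -(frame - min_ct))
    return ExpressionTable(quant, QUANTITY_SCALE)


@dataclass
class RunConfig:
    """Settings of one analysis run (mirrors the tool's setting mode)."""

    candidate_genes: tuple[str, ...]
    target_genes: tuple[str, ...]
    remove_repetitions: int = 0
    select_best_remove: bool = False
    alpha: float = 0.05
    stat_method: str = "pairwise_t_holm"  # | "mann_whitney" | "kruskal_dunn"
    use_adjusted_p: bool = True
    log_rq: bool = False
    welch: bool = False
    calibrator: str | None = None
    ct_path: str | None = None
    quant_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        self.candidate_genes = tuple(self.candidate_genes)
        self.target_genes = tuple(self.target_genes)
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.remove_repetitions < 0:
            raise ValidationError("remove_repetitions must be >= 0")
        if self.stat_method not in ("pairwise_t_holm", "mann_whitney", "kruskal_dunn"):
            raise ValidationError(f"unknown stat_method {self.stat_method!r}")
        overlap = set(self.candidate_genes) & set(self.target_genes)
        if overlap:
            raise ValidationError(
                f"candidate and target genes overlap: {sorted(overlap)}"
            )
        if len(self.candidate_genes) - self.remove_repetitions < MIN_POOL:
            raise PoolExhaustedError(
                f"pool exhausted: {len(self.candidate_genes)} candidates minus "
                f"{self.remove_repetitions} removals is below the {MIN_POOL}-gene "
                "minimum required for NormFinder selection"
            )


def validate_run(ct: ExpressionTable, quant: ExpressionTable,
                 config: RunConfig) -> tuple[ExpressionTable, ExpressionTable, RunConfig]:
    """Cross-check the two tables against each other and the configuration."""
    if ct.samples != quant.samples:
        raise ValidationError(
            f"sample set mismatch between Ct and quantity tables: "
            f"{ct.samples} vs {quant.samples}"
        )
    if ct.replicates_per_sample != quant.replicates_per_sample:
        raise ValidationError("replicate count mismatch between tables")
    if quant.scale != QUANTITY_SCALE or ct.scale != CT_SCALE:
        raise ValidationError("expected a Ct table and a quantity table")
    missing = [g for g in config.candidate_genes if g not in quant.genes]
    if missing:
        raise ValidationError(
            f"quantity table is missing candidate gene(s) {missing}", genes=missing
        )
    listed = list(config.candidate_genes) + list(config.target_genes)
    missing_ct = [g for g in listed if g not in ct.genes]
    if missing_ct:
        raise ValidationError(
            f"Ct table is missing gene(s) {missing_ct}", genes=missing_ct
        )
    return ct, quant, config
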