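"""Relative quantification (RQ) of target genes against a model's reference.

RQ follows the standard delta-Ct form with assumed efficiency 2:

    RQ = 2 ** (Ct_reference - Ct_target)

For a gene-pair reference the reference Ct is the arithmetic mean of the two
genes' Cts, i.e. geometric-mean normalization on the linear scale.  No
calibrator sample is divided out by default — every downstream comparison
(medians' order, rank tests, t-tests within a model) is invariant to a
common positive rescaling of a model's RQ values — but a calibrator can be
supplied for cosmetic parity with plotted results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import Model
from .normfinder import ReferenceAssignment
from .tables import CT_SCALE, ExpressionTable


def reference_ct(ct: ExpressionTable, reference: Sequence[str],
                 sample: str, replicate) -> float:
    """Reference Ct for one replicate: the gene's Ct, or the pair mean."""
    reference = tuple(reference)
    for gene in reference:
        if gene not in ct.genes:
            raise ValidationError(f"unknown reference gene {gene!r}", gene=gene)
    row = ct.data.loc[(sample, replicate), list(reference)]
    return float(np.mean(row.to_numpy(dtype=float)))


def compute_rq(ct: ExpressionTable, model: Model | Sequence[str], target: str,
               assignment: ReferenceAssignment | Sequence[str],
               calibrator: str | None = None) -> pd.Series:
    """Per-replicate RQ of ``target`` within ``model``.

    Returns a Series indexed by (sample, replicate), strictly positive.
    """
    if ct.scale != CT_SCALE:
        raise ValidationError("RQ is computed from Ct values")
    samples = model.samples if isinstance(model, Model) else tuple(model)
    reference = (assignment.reference if isinstance(assignment, ReferenceAssignment)
                 else tuple(assignment))
    if target not in ct.genes:
        raise ValidationError(f"unknown target gene {target!r}", gene=target)
    sub = ct.data.loc[list(samples)]
    ref_ct = sub[list(reference)].mean(axis=1)
    rq = np.power(2.0, ref_ct - sub[target])
    rq.name = target
    if calibrator is not None:
        if calibrator not in samples:
            raise ValidationError(f"calibrator {calibrator!r} not in model")
        rq = rq / float(rq.loc[calibrator].median())
    return rq


@dataclass(frozen=True)
class RQTable:
    """RQ values for every (model, target): ``entries[(model_id, target)]``
    is a (sample, replicate)-indexed Series; ``reference_used`` maps each
    model to its assignment."""

    entries: Mapping[tuple[int, str], pd.Series]
    reference_used: Mapping[int, ReferenceAssignment]

    def rq(self, model_id: int, target: str) -> pd.Series:
        return self.entries[(model_id, target)]
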