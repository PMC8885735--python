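"""Experimental model and its daughter models.

The experimental model is the full ordered set of samples under study; a
daughter (auxiliary) model is any combination without repetition of >= 2 of
those samples.  For n samples there are sum_{r=2..n} C(n, r) models — 26 for
the canonical five-sample design — and every unordered sample pair occurs in
exactly 2^(n-2) of them.

Model numbering is deterministic: size-major (all 2-sample models first),
lexicographic by sample position within a size, experimental model last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .errors import UniverseTooSmallError, ValidationError

#: model count is 2^n - n - 1; warn above this universe size.
MAX_RECOMMENDED_SAMPLES = 12


@dataclass(frozen=True)
class Model:
    """One combination of samples (universe order preserved)."""

    model_id: int
    samples: tuple[str, ...]

    def __contains__(self, sample: str) -> bool:
        return sample in self.samples

    @property
    def size(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ModelSpace:
    universe: tuple[str, ...]
    models: tuple[Model, ...]
    pair_index: dict[tuple[str, str], tuple[int, ...]]

    @property
    def experimental_model(self) -> Model:
        return self.models[-1]

    def __getitem__(self, model_id: int) -> Model:
        model = self.models[model_id - 1]
        assert model.model_id == model_id
        return model


def enumerate_pairs(universe: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n, 2) sample pairs, each ordered by universe position.

    The list order (lexicographic by position) is fixed: the coherence score
    contract "the order of samples is fixed" rests on it.
    """
    universe = _check_universe(universe)
    return list(combinations(universe, 2))


def generate_models(universe: Sequence[str]) -> ModelSpace:
    """Enumerate the experimental model and all daughter models."""
    universe = _check_universe(universe)
    n = len(universe)
    if n > MAX_RECOMMENDED_SAMPLES:
        warnings.warn(
            f"{n} samples generate {2 ** n - n - 1} models; "
            "runtime grows exponentially", stacklevel=2,
        )
    models = []
    model_id = 0
    for size in range(2, n + 1):
        for combo in combinations(universe, size):
            model_id += 1
            models.append(Model(model_id, combo))
    pair_index: dict[tuple[str, str], tuple[int, ...]] = {}
    for pair in combinations(universe, 2):
        ids = tuple(
            m.model_id for m in models
            if pair[0] in m.samples and pair[1] in m.samples
        )
        pair_index[pair] = ids
    return ModelSpace(tuple(universe), tuple(models), pair_index)


def models_containing_pair(space: ModelSpace,
                           pair: tuple[str, str]) -> tuple[int, ...]:
    """Model ids whose sample set contains both members of ``pair``."""
    a, b = pair
    if a == b:
        raise ValidationError(f"pair members must differ, got {a!r} twice")
    for sample in (a, b):
        if sample not in space.universe:
            raise ValidationError(f"unknown sample {sample!r}")
    key = (a, b) if space.universe.index(a) < space.universe.index(b) else (b, a)
    return space.pair_index[key]


def _check_universe(universe: Sequence[str]) -> tuple[str, ...]:
    universe = tuple(universe)
    if len(universe) < 2:
        raise UniverseTooSmallError(
            f"universe too small: need >= 2 samples, got {len(universe)}"
        )
    if len(set(universe)) != len(universe):
        raise ValidationError("duplicate samples in universe")
    return universe
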