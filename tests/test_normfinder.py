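"""NormFinder stability estimation, reference selection, and removal.

The independent oracle below is a literal, loop-based transcription of the
variance-decomposition formulas (log transform, pool-mean subtraction,
intergroup deviations, corrected intragroup variances, shrinkage, rho),
kept deliberately separate from the vectorized implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np
import pytest

import genexpa as g
from genexpa.errors import InsufficientReplicatesError, PoolExhaustedError
from genexpa.normfinder import NormFinderSelector
from genexpa.tables import QUANTITY_SCALE

from conftest import make_table, random_quantity_table


# ---------------------------------------------------------------------------
# independent oracle

def oracle_stability(table, samples, pool):
    """Single and pair stabilities via plain-python loops."""
    k = len(pool)
    G = len(samples)
    y = {}  # (sample, gene) -> list over replicates
    reps = {}
    for s in samples:
        block = table.data.loc[s]
        reps[s] = list(block.index)
        for gene in pool:
            y[(s, gene)] = [math.log2(block.loc[r, gene]) for r in reps[s]]

    # z: subtract the pool mean within each (sample, replicate)
    z = {}
    for s in samples:
        for j, r in enumerate(reps[s]):
            row_mean = sum(y[(s, gene)][j] for gene in pool) / k
            for gene in pool:
                z.setdefault((s, gene), []).append(y[(s, gene)][j] - row_mean)

    zbar = {key: sum(v) / len(v) for key, v in z.items()}
    d = {}
    for gene in pool:
        gene_mean = sum(zbar[(s, gene)] for s in samples) / G
        for s in samples:
            d[(s, gene)] = zbar[(s, gene)] - gene_mean

    s2 = {}
    for (s, gene), vals in z.items():
        m = sum(vals) / len(vals)
        s2[(s, gene)] = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)

    sig2 = {}
    for s in samples:
        S = sum(s2[(s, gene)] for gene in pool) / (1 - 1 / k)
        for gene in pool:
            sig2[(s, gene)] = max(
                0.0, (s2[(s, gene)] - S / k ** 2) / (1 - 2 / k))

    sig2_n = {(s, gene): sig2[(s, gene)] / len(z[(s, gene)])
              for s in samples for gene in pool}
    gamma2 = max(
        0.0,
        sum(v ** 2 for v in d.values()) / ((G - 1) * (k - 1))
        - sum(sig2_n.values()) / (G * k),
    )

    dt, v = {}, {}
    for key in d:
        denom = gamma2 + sig2_n[key]
        shrink = 0.0 if denom == 0 else gamma2 / denom
        dt[key] = d[key] * shrink
        v[key] = sig2_n[key] * shrink

    single = {
        gene: sum(abs(dt[(s, gene)]) + math.sqrt(v[(s, gene)])
                  for s in samples) / G
        for gene in pool
    }
    pair = {
        (a, b): sum(
            abs((dt[(s, a)] + dt[(s, b)]) / 2)
            + math.sqrt((v[(s, a)] + v[(s, b)]) / 4)
            for s in samples
        ) / G
        for a, b in combinations(pool, 2)
    }
    return single, pair


@pytest.mark.parametrize("k,G", [(3, 2), (4, 2), (5, 3), (3, 3), (4, 3)])
def test_matches_loop_oracle_on_random_fixtures(k, G, rng):
    for _ in range(5):
        table = random_quantity_table(rng, n_samples=G, n_genes=k)
        stab = g.stability_for_pool(table, table.samples, table.genes)
        single, pair = oracle_stability(table, table.samples, table.genes)
        for gene, rho in single.items():
            assert stab.single_stability[gene] == pytest.approx(rho, abs=1e-9)
        for key, rho in pair.items():
            assert stab.pair_stability[key] == pytest.approx(rho, abs=1e-9)


def test_degenerate_constant_data_gives_zero_stability():
    table = make_table(np.full((6, 4), 0.5), ["A", "B"],
                       ["g1", "g2", "g3", "g4"], QUANTITY_SCALE)
    stab = g.stability_for_pool(table, table.samples, table.genes)
    assert all(v == 0.0 for v in stab.single_stability.values())
    assert all(v == 0.0 for v in stab.pair_stability.values())


def test_all_stabilities_nonnegative_finite(rng):
    for _ in range(10):
        table = random_quantity_table(rng, n_samples=3, n_genes=5)
        stab = g.stability_for_pool(table, table.samples, table.genes)
        values = list(stab.single_stability.values()) + \
            list(stab.pair_stability.values())
        assert all(np.isfinite(v) and v >= 0 for v in values)


def test_per_replicate_scaling_invariance(rng):
    """Multiplying one replicate's quantities by c > 0 leaves rho unchanged
    (the log-scale pool-mean subtraction removes loading differences)."""
    table = random_quantity_table(rng, n_samples=3, n_genes=4)
    scaled = table.data.copy()
    scaled.loc[("S2", 2)] = scaled.loc[("S2", 2)] * 37.5
    scaled_table = make_table(scaled.to_numpy(), table.samples, table.genes,
                              QUANTITY_SCALE)
    a = g.stability_for_pool(table, table.samples, table.genes)
    b = g.stability_for_pool(scaled_table, table.samples, table.genes)
    for gene in table.genes:
        assert abs(a.single_stability[gene] - b.single_stability[gene]) < 1e-12
    for key in a.pair_stability:
        assert abs(a.pair_stability[key] - b.pair_stability[key]) < 1e-12


def test_gene_permutation_invariance(rng):
    table = random_quantity_table(rng, n_samples=2, n_genes=4)
    reference = g.stability_for_pool(table, table.samples, table.genes)
    for order in list(permutations(table.genes))[:6]:
        stab = g.stability_for_pool(table, table.samples, order)
        for gene in table.genes:
            assert stab.single_stability[gene] == pytest.approx(
                reference.single_stability[gene], abs=1e-12)


class TestSelectReference:
    def test_single_preferred_on_tie(self):
        stab = g.StabilityTable(1, 0, ("A", "B", "C"), (), {"A": 0.2, "B": 0.5,
                                                            "C": 0.6},
                                {("B", "C"): 0.2})
        chosen = g.select_reference(stab)
        assert chosen.reference == ("A",)
        assert chosen.stability == 0.2

    def test_lexicographic_tie_break(self):
        stab = g.StabilityTable(1, 0, ("B", "A", "C"), (),
                                {"B": 0.2, "A": 0.2, "C": 0.9}, {})
        assert g.select_reference(stab).reference == ("A",)

    def test_pair_wins_when_strictly_lower(self, rng):
        table = random_quantity_table(rng, n_samples=3, n_genes=4)
        stab = g.stability_for_pool(table, table.samples, table.genes)
        chosen = g.select_reference(stab)
        best = min(list(stab.single_stability.values())
                   + list(stab.pair_stability.values()))
        assert chosen.stability == best


class TestRemoveLeastStable:
    def test_zero_removals_identity(self, rng):
        table = random_quantity_table(rng, n_genes=4)
        pool, removed = g.remove_least_stable(table, table.samples,
                                              table.genes, 0)
        assert pool == table.genes and removed == ()

    def test_pool_exhausted(self, rng):
        table = random_quantity_table(rng, n_genes=4)
        with pytest.raises(PoolExhaustedError):
            g.remove_least_stable(table, table.samples, table.genes, 2)

    def test_noisy_interacting_gene_removed_first(self):
        """A gene with 10x replicate noise plus a strong sample x gene
        interaction is the first removed in >= 95% of seeded runs."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n_s, n_r = 4, 3
            samples = [f"S{i}" for i in range(n_s)]
            genes = ["g1", "g2", "g3", "gX"]
            log_q = rng.normal(0, 0.1, (n_s, n_r, 4))
            log_q[:, :, 3] += rng.normal(0, 1.0, (n_s, 1))  # interaction
            log_q[:, :, 3] += rng.normal(0, 1.0, (n_s, n_r))  # 10x noise
            table = make_table(2.0 ** log_q.reshape(n_s * n_r, 4), samples,
                               genes, QUANTITY_SCALE)
            _, removed = g.remove_least_stable(table, samples, genes, 1)
            hits += removed == ("gX",)
        assert hits >= 95


class TestSelectBestAcrossLevels:
    def _assignment(self, level, stability):
        return g.ReferenceAssignment(7, ("RPS23",), stability, level)

    def test_lowest_stability_wins(self):
        chosen = g.select_best_across_levels([
            self._assignment(0, 0.091), self._assignment(1, 0.171),
            self._assignment(2, 0.010)])
        assert chosen.chosen_level == 2
        assert chosen.stability == 0.010

    def test_single_level_passthrough(self):
        only = self._assignment(0, 0.3)
        assert g.select_best_across_levels([only]) is only

    def test_tie_prefers_lower_level(self):
        chosen = g.select_best_across_levels(
            [self._assignment(0, 0.2), self._assignment(1, 0.2)])
        assert chosen.chosen_level == 0


def test_best_stability_nonincreasing_in_removal_budget(rng):
    """With select-best-remove, a larger removal budget can only improve
    (or keep) each model's chosen stability."""
    table = random_quantity_table(rng, n_samples=3, n_genes=5)
    previous = None
    for r in (0, 1, 2):
        final, _ = g.assign_references(table, table.samples, table.genes,
                                       remove_repetitions=r,
                                       select_best_remove=True)
        if previous is not None:
            assert final.stability <= previous + 1e-15
        previous = final.stability


class TestErrors:
    def test_pool_below_three(self, rng):
        table = random_quantity_table(rng, n_genes=4)
        with pytest.raises(PoolExhaustedError):
            g.stability_for_pool(table, table.samples, table.genes[:2])

    def test_single_replicate_rejected(self):
        table = make_table(np.full((2, 3), 1.0), ["A", "B"],
                           ["g1", "g2", "g3"], QUANTITY_SCALE, replicates=1)
        with pytest.raises(InsufficientReplicatesError):
            g.stability_for_pool(table, ["A", "B"], table.genes)


class TestNormFinderSelector:
    def test_fit_exposes_ranking_and_reference(self, rng):
        table = random_quantity_table(rng, n_samples=3, n_genes=4)
        sel = NormFinderSelector().fit(table)
        functional, _ = g.assign_references(table, table.samples, table.genes)
        assert sel.reference_ == functional.reference
        assert sel.reference_stability_ == functional.stability
        assert list(sel.single_stability_.index) == sorted(
            table.genes, key=lambda gn: sel.single_stability_[gn])

    def test_accepts_plain_dataframe(self, rng):
        table = random_quantity_table(rng, n_samples=2, n_genes=4)
        sel = NormFinderSelector(remove_repetitions=1).fit(table.data)
        assert len(sel.removed_genes_) == 1
        assert len(sel.levels_) == 2

    def test_sklearn_params_protocol(self):
        from sklearn.base import clone
        sel = NormFinderSelector(remove_repetitions=1, select_best_remove=True)
        params = sel.get_params()
        assert params["remove_repetitions"] == 1
        cloned = clone(sel)
        assert cloned.get_params() == params
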