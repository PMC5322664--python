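"""Copying-model HMM: exact oracles, limits, EM, coancestry, admixture."""

from itertools import product

import numpy as np
import pytest

from andromix.chunk_painting import (
    CoancestryMatrix,
    PaintingError,
    PaintingParams,
    admixture_flags,
    admixture_fractions,
    aggregate_by_lineage,
    coancestry_matrix,
    estimate_painting_params,
    paint_haplotype,
)
from andromix.genotypes_io import HaplotypeMatrix


def brute_force_counts(recipient, donors, positions, params):
    """Exact expected chunk counts by enumerating all donor paths."""
    n_donors, n_sites = donors.shape
    theta = params.miscopy_prob
    switch = 1 - np.exp(-params.recomb_scale * np.diff(positions).astype(float))
    total = 0.0
    counts = np.zeros(n_donors)
    for path in product(range(n_donors), repeat=n_sites):
        prob = 1.0 / n_donors
        for l, state in enumerate(path):
            prob *= (1 - theta) if donors[state, l] == recipient[l] else theta
            if l:
                same = path[l] == path[l - 1]
                s = switch[l - 1]
                prob *= (1 - s) + s / n_donors if same else s / n_donors
        chunk = np.zeros(n_donors)
        chunk[path[0]] = 1
        for l in range(1, n_sites):
            if path[l] != path[l - 1]:
                chunk[path[l]] += 1
        total += prob
        counts += prob * chunk
    return counts / total, np.log(total)


def log_space_loglik(recipient, donors, positions, params):
    """Reference log-space forward pass (no scaling)."""
    n_donors, n_sites = donors.shape
    theta = params.miscopy_prob
    switch = 1 - np.exp(-params.recomb_scale * np.diff(positions).astype(float))
    log_emis = np.where(donors.T == recipient[:, None],
                        np.log1p(-theta), np.log(theta))
    log_a = -np.log(n_donors) + log_emis[0]
    for l in range(1, n_sites):
        s = switch[l - 1]
        m = log_a.max()
        stay = np.log1p(-s) + log_a if s < 1 else np.full_like(log_a, -np.inf)
        hop = np.log(s / n_donors) + m + np.log(np.exp(log_a - m).sum()) \
            if s > 0 else np.full_like(log_a, -np.inf)
        log_a = np.logaddexp(stay, hop) + log_emis[l]
    m = log_a.max()
    return m + np.log(np.exp(log_a - m).sum())


def random_instance(rng, n_donors, n_sites):
    donors = rng.integers(0, 2, (n_donors, n_sites)).astype(np.int8)
    recipient = rng.integers(0, 2, n_sites).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, 50_000), n_sites,
                                   replace=False))
    return recipient, donors, positions


class TestPaintHaplotype:
    @pytest.mark.parametrize("trial", range(6))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        recipient, donors, positions = random_instance(rng, 3, 9)
        params = PaintingParams(recomb_scale=10 ** rng.uniform(-5, -3),
                                miscopy_prob=rng.uniform(0.02, 0.3))
        oracle, oracle_ll = brute_force_counts(recipient, donors, positions,
                                               params)
        res = paint_haplotype(recipient, donors, positions, params)
        np.testing.assert_allclose(res.chunk_counts, oracle, atol=1e-6)
        assert res.loglik == pytest.approx(oracle_ll, abs=1e-9)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_log_space_reference(self, trial):
        rng = np.random.default_rng(100 + trial)
        recipient, donors, positions = random_instance(rng, 5, 40)
        params = PaintingParams(recomb_scale=1e-4, miscopy_prob=0.1)
        ref = log_space_loglik(recipient, donors, positions, params)
        res = paint_haplotype(recipient, donors, positions, params)
        assert res.loglik == pytest.approx(ref, abs=1e-8)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(7)
        recipient, donors, positions = random_instance(rng, 4, 30)
        res = paint_haplotype(recipient, donors, positions,
                              PaintingParams(), return_posteriors=True)
        np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_identical_donor_dominates(self):
        rng = np.random.default_rng(1)
        n_sites = 40
        x = rng.integers(0, 2, n_sites).astype(np.int8)
        donors = np.vstack([x, 1 - x, 1 - x]).astype(np.int8)
        positions = 100 * (1 + np.arange(n_sites))
        res = paint_haplotype(x, donors, positions,
                              PaintingParams(recomb_scale=1e-6,
                                             miscopy_prob=0.01))
        assert res.chunk_counts[0] / res.chunk_counts.sum() >= 0.99

    def test_identical_donors_share_counts(self):
        rng = np.random.default_rng(2)
        n_sites = 25
        x = rng.integers(0, 2, n_sites).astype(np.int8)
        donors = np.vstack([x, x, 1 - x]).astype(np.int8)
        positions = 50 * (1 + np.arange(n_sites))
        res = paint_haplotype(x, donors, positions, PaintingParams())
        assert res.chunk_counts[0] == pytest.approx(res.chunk_counts[1],
                                                    rel=1e-9)

    @pytest.mark.parametrize("recomb_scale", [1e-6, 1e-5, 1e-4])
    def test_half_and_half_mosaic_recovered(self, recomb_scale):
        rng = np.random.default_rng(3)
        n_sites = 12
        x = rng.integers(0, 2, n_sites).astype(np.int8)
        y = 1 - x
        z = np.roll(x, 1).astype(np.int8)
        recipient = np.concatenate([x[:6], y[6:]]).astype(np.int8)
        donors = np.vstack([x, y, z])
        positions = 2000 * (1 + np.arange(n_sites))
        params = PaintingParams(recomb_scale=recomb_scale, miscopy_prob=0.01)
        res = paint_haplotype(recipient, donors, positions, params)
        oracle, _ = brute_force_counts(recipient, donors, positions, params)
        np.testing.assert_allclose(res.chunk_counts, oracle, atol=1e-6)
        assert abs(res.chunk_counts[0] - 1.0) <= 0.2
        assert abs(res.chunk_counts[1] - 1.0) <= 0.2

    def test_recomb_scale_limits(self):
        rng = np.random.default_rng(4)
        recipient, donors, positions = random_instance(rng, 4, 20)
        lo = paint_haplotype(recipient, donors, positions,
                             PaintingParams(recomb_scale=1e-15))
        assert lo.chunk_counts.sum() == pytest.approx(1.0, abs=1e-6)
        # every interval recombines; a switch re-entering the same donor does
        # not open a chunk, so the ceiling is 1 + (L-1)(1 - 1/K)
        same = np.vstack([recipient] * 4)
        hi = paint_haplotype(recipient, same, positions,
                             PaintingParams(recomb_scale=10.0))
        assert hi.chunk_counts.sum() == pytest.approx(1 + 19 * 0.75,
                                                      rel=1e-6)

    def test_input_validation(self):
        params = PaintingParams()
        with pytest.raises(PaintingError):
            paint_haplotype(np.array([0, 1], dtype=np.int8),
                            np.empty((0, 2), dtype=np.int8),
                            np.array([1, 2]), params)
        with pytest.raises(PaintingError):
            paint_haplotype(np.array([0], dtype=np.int8),
                            np.array([[1]], dtype=np.int8),
                            np.array([1]), params)


def three_strain_matrix(columns, lineages=("A", "A", "A")):
    cols = np.asarray(columns, dtype=np.int8)
    n_sites = cols.shape[1]
    return HaplotypeMatrix(
        strains=[f"s{i}" for i in range(cols.shape[0])],
        lineages=list(lineages),
        contigs=np.array(["c1"] * n_sites, dtype=object),
        positions=1000 * (1 + np.arange(n_sites)),
        alleles=cols,
    )


class TestCoancestry:
    def test_identical_strains_symmetric_offdiagonal(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 2, 30)
        m = three_strain_matrix(np.vstack([row, row, row]))
        cm = coancestry_matrix(m, PaintingParams())
        off = cm.values[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, off[0], rtol=1e-9)

    def test_diagonal_is_zero(self, small_panel):
        cm = coancestry_matrix(small_panel, PaintingParams())
        assert np.all(np.diag(cm.values) == 0)
        assert np.all(cm.values >= 0)
        # one chunk minimum per painted contig
        assert np.all(cm.values.sum(axis=1) >= len(small_panel.contig_ids()))

    def test_within_lineage_exceeds_between(self, small_panel):
        cm = coancestry_matrix(small_panel, PaintingParams())
        agg = aggregate_by_lineage(cm)
        assert agg.loc["A", "A"] > agg.loc["A", "B"]
        assert agg.loc["B", "B"] > agg.loc["B", "A"]

    def test_too_few_strains_rejected(self):
        m = three_strain_matrix(np.array([[0, 1], [1, 0]]), ("A", "A"))
        with pytest.raises(PaintingError):
            coancestry_matrix(m, PaintingParams())


class TestEstimateParams:
    @staticmethod
    def copying_model_panel(theta, seed, n_founders=3, n_children=9,
                            n_sites=200, scale=2e-5):
        """Data generated from the copying model itself: divergent founders
        plus children that copy founder mosaics with miscopy noise theta.
        Standing founder variation keeps the polymorphism filter from
        conditioning on miscopied sites."""
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(np.arange(1, 400_000), n_sites,
                                       replace=False))
        founders = [rng.integers(0, 2, n_sites).astype(np.int8)
                    for _ in range(n_founders)]
        switch = 1 - np.exp(-scale * np.diff(positions))
        rows = list(founders)
        for _ in range(n_children):
            child = np.empty(n_sites, dtype=np.int8)
            cur = rng.integers(0, n_founders)
            for l in range(n_sites):
                if l and rng.random() < switch[l - 1]:
                    cur = rng.integers(0, n_founders)
                child[l] = founders[cur][l]
                if rng.random() < theta:
                    child[l] = 1 - child[l]
            rows.append(child)
        m = HaplotypeMatrix(
            strains=[f"s{i}" for i in range(len(rows))],
            lineages=["A"] * len(rows),
            contigs=np.array(["c1"] * n_sites, dtype=object),
            positions=positions,
            alleles=np.vstack(rows),
        )
        return m.drop_monomorphic()

    def test_theta_recovery(self):
        estimates = []
        for seed in range(3):
            m = self.copying_model_panel(theta=0.05, seed=seed)
            p = estimate_painting_params(
                m, PaintingParams(recomb_scale=2e-5, miscopy_prob=0.2,
                                  em_iterations=4))
            estimates.append(p.miscopy_prob)
        assert 0.03 <= np.mean(estimates) <= 0.08

    def test_zero_iterations_returns_initial(self, small_panel):
        init = PaintingParams(recomb_scale=3e-5, miscopy_prob=0.11,
                              em_iterations=0)
        assert estimate_painting_params(small_panel, init) is init

    def test_loglik_trace_nondecreasing(self):
        m = self.copying_model_panel(theta=0.1, seed=9, n_children=4,
                                     n_sites=60)
        p = estimate_painting_params(
            m, PaintingParams(recomb_scale=1e-3, miscopy_prob=0.3,
                              em_iterations=4))
        trace = np.asarray(p.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6)


class TestAggregationAndAdmixture:
    def test_single_lineage_aggregate_is_mean_offdiagonal(self):
        values = np.array([[0.0, 2.0, 4.0],
                           [1.0, 0.0, 3.0],
                           [5.0, 6.0, 0.0]])
        cm = CoancestryMatrix(values, ["a", "b", "c"], ["A", "A", "A"])
        agg = aggregate_by_lineage(cm)
        assert agg.shape == (1, 1)
        assert agg.loc["A", "A"] == pytest.approx(values.sum() / 6)

    def test_aggregation_invariant_to_strain_order(self, small_panel):
        cm = coancestry_matrix(small_panel, PaintingParams())
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_panel.n_strains)
        cm_perm = CoancestryMatrix(cm.values[np.ix_(perm, perm)],
                                   [cm.strains[i] for i in perm],
                                   [cm.lineages[i] for i in perm])
        a = aggregate_by_lineage(cm)
        b = aggregate_by_lineage(cm_perm)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_fractions_sum_to_one(self, small_panel):
        cm = coancestry_matrix(small_panel, PaintingParams())
        for strain in cm.strains[:4]:
            assert admixture_fractions(cm, strain).sum() == pytest.approx(1.0)

    def test_pure_strain_own_fraction_dominates(self, small_panel):
        cm = coancestry_matrix(small_panel, PaintingParams())
        flags = admixture_flags(cm)
        assert (flags["own_fraction"] > 0.7).all()
        assert not flags["admixture_candidate"].any()

    def test_unknown_strain_rejected(self):
        cm = CoancestryMatrix(np.ones((3, 3)) - np.eye(3),
                              ["a", "b", "c"], ["A", "A", "B"])
        with pytest.raises(KeyError):
            admixture_fractions(cm, "zz")
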