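"""CCF computation, Dirichlet-mixture clustering, intervals, pigeonhole."""

import numpy as np
import pytest
from scipy import stats

from twinclock.clustering import (
    ClusterSolution,
    assign_lineages_pigeonhole,
    binomial_ccf_interval,
    build_ccf_records,
    cluster_ccf,
    compute_ccf,
    estimate_multiplicity,
    prune_clusters,
)

from conftest import planted_records_1d, planted_records_2d


class TestMultiplicity:
    @pytest.mark.parametrize("vaf,rho,cn,expected", [
        (0.5, 1.0, 2, 1),    # heterozygous diploid
        (0.9, 1.0, 2, 2),    # round(1.8) = 2
        (0.25, 0.5, 2, 1),   # raw 1.0
        (0.75, 1.0, 2, 2),   # raw 1.5, half-up
        (0.99, 1.0, 3, 3),   # clamp to CN_t
        (0.01, 1.0, 2, 1),   # clamp up to 1
        (0.0, 1.0, 2, 0),    # zero vaf only case returning 0
    ])
    def test_examples(self, vaf, rho, cn, expected):
        assert estimate_multiplicity(vaf, rho, cn) == expected

    def test_homozygous_deletion_unmappable(self):
        with pytest.raises(ValueError, match="unmappable"):
            estimate_multiplicity(0.1, 1.0, 0)


class TestComputeCcf:
    @pytest.mark.parametrize("vaf,rho,cn,m,expected", [
        (0.5, 1.0, 2, 1, 1.0),
        (0.2, 0.8, 3, 1, 0.7),
        (0.25, 0.5, 2, 1, 1.0),
    ])
    def test_examples(self, vaf, rho, cn, m, expected):
        assert compute_ccf(vaf, rho, cn, m) == pytest.approx(expected)

    def test_linear_in_vaf_and_reduces_to_two_vaf(self):
        vafs = np.linspace(0.01, 0.5, 7)
        ccfs = np.array([compute_ccf(v, 1.0, 2, 1) for v in vafs])
        assert np.allclose(ccfs, 2 * vafs)
        assert compute_ccf(0.3, 0.7, 4, 2) == compute_ccf(0.3, 0.7, 4, 1) / 2

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            compute_ccf(0.5, 0.0, 2, 1)


class TestClusterCcf:
    def test_single_planted_cluster(self):
        df = planted_records_1d(0, [(1.0, 300)])
        recs = build_ccf_records(df, (1.0,))
        sol = cluster_ccf(recs, (1.0,), n_dims=1, iters=500, burn_in=120, seed=1)
        sol = prune_clusters(sol, recs, (1.0,))
        assert sol.n_clusters == 1
        assert abs(sol.locations[0, 0] - 1.0) < 0.05

    def test_two_planted_clusters_1d(self):
        df = planted_records_1d(4, [(1.0, 280), (0.4, 120)])
        recs = build_ccf_records(df, (1.0,))
        sol = cluster_ccf(recs, (1.0,), n_dims=1, iters=500, burn_in=120, seed=2)
        sol = prune_clusters(sol, recs, (1.0,))
        assert sol.n_clusters == 2
        locs = sorted(sol.locations[:, 0])
        weights = [w for _, w in sorted(zip(sol.locations[:, 0], sol.weights))]
        assert abs(locs[0] - 0.4) < 0.05 and abs(locs[1] - 1.0) < 0.05
        assert abs(weights[0] - 0.3) < 0.05 and abs(weights[1] - 0.7) < 0.05

    def test_twin_architecture_2d(self):
        df = planted_records_2d(7)
        recs = build_ccf_records(df, (0.95, 0.95))
        sol = cluster_ccf(recs, (0.95, 0.95), n_dims=2, iters=600, burn_in=150,
                          seed=3)
        sol = prune_clusters(sol, recs, (0.95, 0.95))
        assert sol.n_clusters == 3
        targets = {(1, 1), (1, 0), (0, 1)}
        recovered = {tuple(np.round(loc).astype(int)) for loc in sol.locations}
        assert recovered == targets

    def test_too_few_records_rejected(self):
        df = planted_records_1d(0, [(1.0, 4)])
        recs = build_ccf_records(df, (1.0,))
        with pytest.raises(ValueError):
            cluster_ccf(recs, (1.0,), n_dims=1)

    def test_deterministic_under_seed(self):
        df = planted_records_1d(1, [(1.0, 60)])
        recs = build_ccf_records(df, (1.0,))
        a = cluster_ccf(recs, (1.0,), n_dims=1, iters=200, burn_in=50, seed=9)
        b = cluster_ccf(recs, (1.0,), n_dims=1, iters=200, burn_in=50, seed=9)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.allclose(a.locations, b.locations)


class TestPruneClusters:
    def _solution(self, weights, locations, n=200):
        weights = np.asarray(weights, float)
        counts = (weights * n).astype(int)
        counts[0] += n - counts.sum()
        z = np.repeat(np.arange(len(weights)), counts)
        locs = np.asarray(locations, float)[:, None]
        return ClusterSolution(
            locations=locs, weights=counts / n, assignments=z,
            keys=list(range(n)), location_draws=np.tile(locs, (10, 1, 1)),
            n_dims=1), z

    def _records(self, z, locations):
        df = planted_records_1d(0, [(1.0, len(z))])
        recs = build_ccf_records(df, (1.0,))
        for r, k in zip(recs, z):
            loc = locations[k]
            r.alt[0] = int(round(40 * loc / 2))
            r.depth[0] = 40
        return recs

    def test_small_cluster_removed_members_conserved(self):
        sol, z = self._solution([0.745, 0.25, 0.005], [1.0, 0.4, 0.7])
        recs = self._records(z, [1.0, 0.4, 0.7])
        pruned = prune_clusters(sol, recs, (1.0,), min_fraction=0.01)
        assert pruned.n_clusters == 2
        assert len(pruned.assignments) == len(sol.assignments)
        assert set(pruned.assignments) == {0, 1}

    def test_exactly_one_percent_retained(self):
        sol, z = self._solution([0.74, 0.25, 0.01], [1.0, 0.4, 0.7], n=200)
        recs = self._records(z, [1.0, 0.4, 0.7])
        pruned = prune_clusters(sol, recs, (1.0,), min_fraction=0.01)
        assert pruned.n_clusters == 3

    def test_single_full_cluster_unchanged(self):
        sol, z = self._solution([1.0], [1.0])
        recs = self._records(z, [1.0])
        pruned = prune_clusters(sol, recs, (1.0,))
        assert pruned is sol

    def test_all_below_threshold_errors(self):
        sol, z = self._solution([0.5, 0.5], [1.0, 0.4])
        recs = self._records(z, [1.0, 0.4])
        with pytest.raises(ValueError):
            prune_clusters(sol, recs, (1.0,), min_fraction=0.6)


class TestBinomialCcfInterval:
    def test_closed_form_tail_probabilities(self):
        tail, _ = binomial_ccf_interval(0, 10, 0.5)
        assert tail == pytest.approx(0.5 ** 10)
        tail, _ = binomial_ccf_interval(5, 10, 0.5)
        assert tail == pytest.approx(0.623046875)

    def test_full_support_maps_to_maximal_ccf(self):
        _, (lo, hi) = binomial_ccf_interval(40, 40, 0.5, purity=0.8, cn_total=3)
        # alt == depth: upper bound is the CCF of VAF 1 at this CN/purity
        assert hi == pytest.approx((0.8 * 3 + 2 * 0.2) / 0.8)
        assert lo < hi

    def test_interval_coverage_near_nominal(self):
        # Clopper-Pearson is conservative; allow the 2% discreteness margin
        rng = np.random.default_rng(11)
        vaf, depth, n = 0.3, 40, 5000
        alts = rng.binomial(depth, vaf, n)
        lo = stats.beta.ppf(0.025, alts, depth - alts + 1)
        hi = stats.beta.ppf(0.975, alts + 1, depth - alts)
        lo = np.nan_to_num(lo, nan=0.0)
        hi = np.nan_to_num(hi, nan=1.0)
        coverage = np.mean((lo <= vaf) & (vaf <= hi))
        assert coverage >= 0.95 - 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_ccf_interval(5, 10, 1.5)
        with pytest.raises(ValueError):
            binomial_ccf_interval(11, 10, 0.5)


class TestPigeonhole:
    def _solution(self, locations):
        locs = np.asarray(locations, float)
        n = len(locs)
        return ClusterSolution(
            locations=locs, weights=np.full(n, 1 / n),
            assignments=np.arange(n), keys=list(range(n)),
            location_draws=np.tile(locs, (5, 1, 1)), n_dims=locs.shape[1])

    def test_high_ccf_clusters_share_lineage(self):
        labels = assign_lineages_pigeonhole(self._solution([[0.9], [0.6]]))
        assert set(labels["label"]) == {"lineage_a"}

    def test_low_ccf_clusters_indeterminate(self):
        labels = assign_lineages_pigeonhole(self._solution([[0.4], [0.3]]))
        assert set(labels["label"]) == {"indeterminate"}

    def test_twin_nesting_under_ancestral(self):
        labels = assign_lineages_pigeonhole(
            self._solution([[1.0, 1.0], [0.9, 0.0]]))
        assert list(labels["label"]) == ["ancestral", "lineage_a"]

    def test_invariant_to_cluster_order(self):
        fwd = assign_lineages_pigeonhole(
            self._solution([[1.0, 1.0], [0.9, 0.0], [0.0, 0.8]]))
        rev = assign_lineages_pigeonhole(
            self._solution([[0.0, 0.8], [0.9, 0.0], [1.0, 1.0]]))
        assert list(fwd["label"]) == list(reversed(list(rev["label"])))
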