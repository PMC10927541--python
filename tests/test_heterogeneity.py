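"""Window/gene heterogeneity statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from scshape import heterogeneity as het
from scshape.io import RegionAnnotation
from scshape.reactivity import ReactivityProfile
from tests.conftest import make_counts, random_counts


def ols_oracle(x, y):
    """Closed-form normal-equation least squares with intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    r2 = sxy**2 / (sxx * syy)
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return slope, r2, adj


def make_window(depth, mutant, tx="tx", start=0):
    depth = np.asarray(depth)
    cells = [f"c{i}" for i in range(len(depth))]
    return het.WindowCountVector(tx, start, start + 10, cells, depth, np.asarray(mutant))


class TestTiling:
    def test_tiling_arithmetic(self, rng):
        counts = random_counts(rng, n_cells=2, length=25)
        ws = het.tile_windows(counts, "tx1", 25)
        assert [(w.window_start, w.window_end) for w in ws] == [(0, 10), (10, 20)]

    def test_short_transcript_no_windows(self, rng):
        counts = random_counts(rng, n_cells=2, length=9)
        assert het.tile_windows(counts, "tx1", 9) == []

    def test_window_sums_match_position_oracle(self, rng):
        counts = random_counts(rng, n_cells=3, length=30)
        ws = het.tile_windows(counts, "tx1", 30)
        df = counts.subset(transcript_id="tx1", condition="treated")
        for w in ws:
            for ci, cell in enumerate(w.cells):
                sub = df[(df["cell_id"] == cell)
                         & (df["position"] >= w.window_start)
                         & (df["position"] < w.window_end)]
                assert w.depth[ci] == sub["coverage"].sum()
                assert w.mutant[ci] == sub["mutated"].sum()

    def test_bad_window_size(self, rng):
        with pytest.raises(ValueError):
            het.tile_windows(random_counts(rng), "tx1", 30, window_size=0)


class TestFilterWindows:
    def _window_with_total(self, total, n_cells_covered, n_cells=10):
        depth = np.zeros(n_cells, dtype=int)
        per = total // n_cells_covered
        depth[:n_cells_covered] = per
        depth[0] += total - per * n_cells_covered
        return make_window(depth, np.zeros(n_cells, dtype=int))

    def test_600_reads_rejected_601_accepted(self):
        """'More than 600 reads' is strict: 600 fails, 601 passes."""
        w600 = self._window_with_total(600, 5)
        w601 = self._window_with_total(601, 5)
        het.filter_windows([w600, w601], total_cells=10)
        assert not w600.detected
        assert w601.detected

    def test_cell_fraction_boundary(self):
        """Detected in exactly 50% of cells passes; 49% fails."""
        w50 = self._window_with_total(1000, 50, n_cells=100)
        w49 = self._window_with_total(1000, 49, n_cells=100)
        het.filter_windows([w50, w49], total_cells=100)
        assert w50.detected
        assert not w49.detected


class TestWindowHeterogeneity:
    def test_perfect_fit(self):
        depth = np.arange(100, 1100, 100)
        mutant = (0.03 * depth).astype(int)
        rec = het.window_heterogeneity(make_window(depth, mutant))
        assert rec.r_squared == pytest.approx(1.0, abs=1e-6)
        assert rec.adj_r_squared == pytest.approx(1.0, abs=1e-6)
        assert rec.fitted_modification_rate == pytest.approx(0.03, rel=1e-2)

    def test_rate_mixture_scores_low(self):
        """Two interleaved rates at near-equal depths: depth explains nothing."""
        rng = np.random.default_rng(0)
        depth = 1000 + rng.integers(-5, 6, size=20)  # jitter independent of rate
        rates = np.where(np.arange(20) % 2 == 0, 0.01, 0.30)
        mutant = (rates * depth).astype(int)
        rec = het.window_heterogeneity(make_window(depth, mutant))
        slope, r2, adj = ols_oracle(depth, mutant)
        assert rec.adj_r_squared == pytest.approx(adj, abs=1e-10)
        assert rec.adj_r_squared < 0.1

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            depth = rng.integers(50, 2000, size=n)
            mutant = rng.binomial(depth, rng.uniform(0.005, 0.1))
            if np.ptp(depth) == 0 or np.ptp(mutant) == 0:
                continue
            rec = het.window_heterogeneity(make_window(depth, mutant))
            slope, r2, adj = ols_oracle(depth, mutant)
            assert rec.fitted_modification_rate == pytest.approx(slope, abs=1e-10)
            assert rec.r_squared == pytest.approx(r2, abs=1e-10)
            assert rec.adj_r_squared == pytest.approx(adj, abs=1e-10)

    def test_too_few_cells_flagged_undefined(self):
        rec = het.window_heterogeneity(make_window([10, 20, 30], [1, 2, 3]))
        assert not rec.defined
        assert np.isnan(rec.adj_r_squared)

    def test_zero_depth_variance_flagged(self):
        rec = het.window_heterogeneity(make_window([100] * 6, [1, 5, 2, 8, 3, 9]))
        assert not rec.defined

    def test_permutation_invariance(self, rng):
        depth = rng.integers(100, 1000, size=8)
        mutant = rng.binomial(depth, 0.05)
        perm = rng.permutation(8)
        r1 = het.window_heterogeneity(make_window(depth, mutant))
        r2 = het.window_heterogeneity(make_window(depth[perm], mutant[perm]))
        assert r1.adj_r_squared == pytest.approx(r2.adj_r_squared, abs=1e-12)

    def test_scale_equivariance(self, rng):
        """Scaling depth and mutant by a common integer leaves R² unchanged."""
        depth = rng.integers(100, 1000, size=8)
        mutant = rng.binomial(depth, 0.05)
        r1 = het.window_heterogeneity(make_window(depth, mutant))
        r2 = het.window_heterogeneity(make_window(depth * 3, mutant * 3))
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-12)


class TestGeneHeterogeneity:
    def _profile(self, values, source="c", mask=None):
        values = np.asarray(values, float)
        mask = np.ones(len(values), bool) if mask is None else np.asarray(mask, bool)
        return ReactivityProfile("tx", source, values, mask)

    def test_all_cells_equal_pseudobulk(self, rng):
        pb_values = rng.random(20)
        pb = self._profile(pb_values, "pseudobulk")
        profiles = [self._profile(pb_values, f"c{i}") for i in range(5)]
        rec = het.gene_heterogeneity(profiles, pb)
        assert rec.heterogeneity == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_plus_identical_closed_form(self):
        """D = {1, 0} gives heterogeneity sqrt(1/2)."""
        pb = self._profile([1.0] * 6 + [0.0] * 6, "pseudobulk")
        identical = self._profile([1.0] * 6 + [0.0] * 6, "a")
        orthogonal = self._profile([0.0] * 6 + [1.0] * 6, "b")
        rec = het.gene_heterogeneity([identical, orthogonal], pb)
        assert sorted(rec.cosine_distances) == pytest.approx([0.0, 1.0], abs=1e-12)
        assert rec.heterogeneity == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_matches_dot_product_oracle(self, rng):
        pb = self._profile(rng.random(40), "pseudobulk")
        profiles, expected = [], []
        for i in range(20):
            mask = rng.random(40) > 0.2
            values = rng.normal(0.2, 0.1, 40)
            profiles.append(self._profile(values, f"c{i}", mask))
            a, b = values[mask], pb.reactivity[mask]
            expected.append(
                1 - float(a @ b) / (math.sqrt(a @ a) * math.sqrt(b @ b))
            )
        rec = het.gene_heterogeneity(profiles, pb)
        assert np.allclose(rec.cosine_distances, expected, atol=1e-12)
        assert rec.heterogeneity == pytest.approx(
            math.sqrt(np.mean(np.square(expected))), abs=1e-12
        )

    def test_matches_sklearn_cosine(self, rng):
        """Cross-check against the library the statistic was defined with."""
        from sklearn.metrics.pairwise import cosine_distances

        pb = self._profile(rng.random(30), "pseudobulk")
        profiles = [self._profile(rng.random(30), f"c{i}") for i in range(5)]
        rec = het.gene_heterogeneity(profiles, pb)
        expected = [
            cosine_distances(p.reactivity.reshape(1, -1),
                             pb.reactivity.reshape(1, -1))[0, 0]
            for p in profiles
        ]
        assert np.allclose(rec.cosine_distances, expected, atol=1e-10)

    def test_scale_invariance(self, rng):
        pb = self._profile(rng.random(25), "pseudobulk")
        profiles = [self._profile(rng.random(25), f"c{i}") for i in range(4)]
        scaled = [self._profile(p.reactivity * 11.0, p.source) for p in profiles]
        r1 = het.gene_heterogeneity(profiles, pb)
        r2 = het.gene_heterogeneity(scaled, pb)
        assert r1.heterogeneity == pytest.approx(r2.heterogeneity, abs=1e-12)

    def test_zero_norm_excluded(self, rng):
        pb = self._profile(rng.random(15), "pseudobulk")
        good = [self._profile(rng.random(15), f"c{i}") for i in range(2)]
        zero = self._profile(np.zeros(15), "z")
        with pytest.warns(UserWarning, match="zero-norm"):
            rec = het.gene_heterogeneity(good + [zero], pb)
        assert rec.n == 2

    def test_too_few_usable_cells(self, rng):
        pb = self._profile(rng.random(15), "pseudobulk")
        with pytest.raises(ValueError, match="fewer than 2"):
            het.gene_heterogeneity([self._profile(rng.random(15))], pb)


class TestClassifyQuantiles:
    def test_uniform_ranks(self):
        values = np.arange(1, 101, dtype=float)
        classes = het.classify_quantiles(values)
        assert all(c == het.HeterogeneityClass.HOMOGENEOUS for c in classes[:25])
        assert all(c == het.HeterogeneityClass.HETEROGENEOUS for c in classes[75:])
        assert all(c == het.HeterogeneityClass.INTERMEDIATE for c in classes[25:75])

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="degenerate"):
            classes = het.classify_quantiles(np.ones(10))
        assert all(c == het.HeterogeneityClass.INTERMEDIATE for c in classes)

    def test_matches_percentile_oracle(self, rng):
        values = rng.random(57)
        q25, q75 = np.percentile(values, [25, 75])
        classes = het.classify_quantiles(values)
        for v, c in zip(values, classes):
            if v <= q25:
                assert c == het.HeterogeneityClass.HOMOGENEOUS
            elif v >= q75:
                assert c == het.HeterogeneityClass.HETEROGENEOUS
            else:
                assert c == het.HeterogeneityClass.INTERMEDIATE

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            het.classify_quantiles(np.array([1.0, 2.0, 3.0]))


class TestAssignRegion:
    ann = RegionAnnotation("tx", 100, 30, 70)

    def test_utr5(self):
        assert het.assign_region(0, 10, self.ann) == het.Region.FIVE_PRIME_UTR

    def test_midpoint_at_cds_start_is_cds(self):
        # window [25, 35): midpoint 30 == cds_start -> CDS (half-open)
        assert het.assign_region(25, 35, self.ann) == het.Region.CDS

    @pytest.mark.parametrize(
        "start,expected",
        [
            (60, het.Region.CDS),              # midpoint 65 < cds_end
            (64, het.Region.CDS),              # midpoint 69
            (65, het.Region.THREE_PRIME_UTR),  # midpoint 70 == cds_end
            (70, het.Region.THREE_PRIME_UTR),  # midpoint 75
        ],
    )
    def test_straddle_cases_follow_midpoint(self, start, expected):
        assert het.assign_region(start, start + 10, self.ann) == expected

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            het.assign_region(95, 110, self.ann)


def exact_hypergeom_tail(k, N, K, n):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestMetagene:
    def _annotations(self):
        return {"tx": RegionAnnotation("tx", 1000, 300, 700)}

    def test_interest_equals_all_gives_p_one(self):
        anns = self._annotations()
        windows = [("tx", s, s + 10) for s in range(0, 600, 10)]
        table = het.metagene_enrichment(windows, windows, anns, "start_codon")
        assert np.allclose(table["p_value"].to_numpy(), 1.0)

    def test_concentrated_interest_matches_enumeration(self):
        anns = {"tx": RegionAnnotation("tx", 2000, 1000, 1500)}
        # 100 background windows spread over bins, 10 interest in one bin
        all_windows = [("tx", 700 + 6 * i, 710 + 6 * i) for i in range(100)]
        interest = all_windows[:10]
        table = het.metagene_enrichment(
            interest, all_windows, anns, "start_codon", n_bins=10, span=300
        )
        for row in table.itertuples():
            if row.n_background == 0:
                assert row.p_value == 1.0
                continue
            expected = exact_hypergeom_tail(
                row.n_interest, 100, row.n_background, 10
            )
            assert row.p_value == pytest.approx(expected, rel=1e-9)

    def test_empty_inputs(self):
        with pytest.raises(ValueError):
            het.metagene_enrichment([], [("tx", 0, 10)], self._annotations())


def dtw_oracle(a, b):
    """Exhaustive enumeration of all monotone alignment paths."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += (a[i] - b[j]) ** 2
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return math.sqrt(best[0])


class TestDTW:
    def test_identical_series_zero(self, rng):
        x = rng.random(6)
        assert het.dtw_distance(x, x) == 0.0

    def test_matches_exhaustive_path_oracle(self, rng):
        for _ in range(30):
            a = rng.normal(size=int(rng.integers(2, 5)))
            b = rng.normal(size=int(rng.integers(2, 5)))
            assert het.dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b), abs=1e-12)

    def test_warping_beats_euclidean_on_shift(self):
        a = np.array([0.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 0.0])
        assert het.dtw_distance(a, b) < np.linalg.norm(a - b)


class TestClusterTrajectories:
    def test_single_cluster_is_barycenter(self, rng):
        series = rng.random((5, 4))
        labels, centers, inertia = het.cluster_trajectories(series, k=1, seed=0)
        assert (labels == 0).all()
        assert np.allclose(centers[0], het.dtw_barycenter(series))

    def test_recovers_separated_shapes(self, rng):
        up = np.linspace(0, 1, 4) + rng.normal(0, 0.02, (10, 4))
        down = np.linspace(1, 0, 4) + rng.normal(0, 0.02, (10, 4))
        series = np.vstack([up, down])
        labels, _, _ = het.cluster_trajectories(series, k=2, seed=1, n_restarts=3)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_deterministic_under_seed(self, rng):
        series = rng.random((12, 4))
        out1 = het.cluster_trajectories(series, k=3, seed=5, n_restarts=2)
        out2 = het.cluster_trajectories(series, k=3, seed=5, n_restarts=2)
        assert np.array_equal(out1[0], out2[0])
        assert out1[2] == out2[2]

    def test_k_exceeds_windows(self, rng):
        with pytest.raises(ValueError):
            het.cluster_trajectories(rng.random((3, 4)), k=5, seed=0)


class TestClusterCells:
    def _profiles(self, rng, centers, n_per, noise=0.02):
        out = []
        for g, center in enumerate(centers):
            for i in range(n_per):
                vals = center + rng.normal(0, noise, len(center))
                out.append(
                    ReactivityProfile("tx", f"g{g}c{i}", vals, np.ones(len(center), bool))
                )
        return out

    def test_recovers_conformation_groups(self, rng):
        from sklearn.metrics import adjusted_rand_score

        c1 = np.r_[np.full(10, 0.5), np.full(10, 0.0)]
        c2 = np.r_[np.full(10, 0.0), np.full(10, 0.5)]
        profiles = self._profiles(rng, [c1, c2], 15)
        labels = het.cluster_cells_by_reactivity(profiles, k=2, seed=0)
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_k_one_single_cluster(self, rng):
        profiles = self._profiles(rng, [np.full(12, 0.3)], 5)
        assert set(het.cluster_cells_by_reactivity(profiles, k=1, seed=0)) == {0}

    def test_deterministic(self, rng):
        profiles = self._profiles(rng, [np.full(12, 0.3), np.full(12, 0.6)], 6)
        l1 = het.cluster_cells_by_reactivity(profiles, k=2, seed=3)
        l2 = het.cluster_cells_by_reactivity(profiles, k=2, seed=3)
        assert np.array_equal(l1, l2)

    def test_k_exceeds_cells(self, rng):
        profiles = self._profiles(rng, [np.full(12, 0.3)], 2)
        with pytest.raises(ValueError):
            het.cluster_cells_by_reactivity(profiles, k=5, seed=0)


class TestWindowCorrelates:
    def test_gc_extremes(self):
        w = make_window([10, 10, 10, 10], [0, 0, 0, 0])
        gc, _, cov = het.window_correlates(w, "GCGCGCGCGC")
        assert gc == 1.0 and cov == 40
        gc, _, _ = het.window_correlates(w, "ATATATATAT")
        assert gc == 0.0

    def test_matches_recomputation_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 30))
        w = make_window([5] * 4, [0] * 4, start=10)
        react = rng.normal(0, 0.1, 30)
        mask = rng.random(30) > 0.3
        gc, mean_react, cov = het.window_correlates(w, seq, react, mask)
        sub = seq[10:20]
        assert gc == pytest.approx(sum(c in "GC" for c in sub) / 10)
        m = mask[10:20]
        if m.any():
            assert mean_react == pytest.approx(react[10:20][m].mean())
        assert cov == 20

    def test_short_sequence(self):
        w = make_window([5] * 4, [0] * 4)
        with pytest.raises(ValueError, match="shorter"):
            het.window_correlates(w, "ACGT")
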