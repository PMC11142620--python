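import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lexnets.networks import ChildVocabulary, build_network, mean_degree_by_pos, \
    shared_feature_matrix
from lexnets.normalize import (
    DegreeHistogram3D,
    NormalizationStateError,
    assemble_histograms,
    build_null_histograms,
    enumerate_space,
    interpolate_space,
    median_column_sd_bins,
    normalize_children,
    percentile_rank,
    sample_space,
    simulate_random_networks,
    simulate_space,
    smooth_histograms,
)


def _child(i, nn, nv, lexicon):
    nouns = sorted(lexicon.keys("noun"))[:nn]
    verbs = sorted(lexicon.keys("verb"))[:nv]
    return ChildVocabulary(f"c{i}", 24, frozenset(nouns + verbs))


class TestEnumerateSpace:
    def test_duplicates_collapse(self, default_lexicon):
        children = [
            _child(0, 10, 3, default_lexicon),
            _child(1, 10, 3, default_lexicon),
            _child(2, 5, 1, default_lexicon),
        ]
        assert enumerate_space(children) == [(5, 1), (10, 3)]

    def test_single_child(self, default_lexicon):
        assert enumerate_space([_child(0, 4, 2, default_lexicon)]) == [(4, 2)]

    def test_matches_set_oracle(self, default_lexicon):
        rng = np.random.default_rng(0)
        children = [
            _child(i, int(rng.integers(1, 50)), int(rng.integers(0, 20)),
                   default_lexicon)
            for i in range(500)
        ]
        expected = sorted({(c.n_nouns, c.n_verbs) for c in children})
        assert enumerate_space(children) == expected


class TestSampleSpace:
    def test_square_all_interior_sample_is_all_edges(self):
        points = [(0, 0), (0, 2), (2, 0), (2, 2)]
        space = sample_space(points, seed=1)
        assert sorted(space.points) == sorted(points)
        assert set(space.tags) <= {"edge", "interior"}

    def test_collinear_points_degenerate_branch(self):
        points = [(i, 2 * i) for i in range(6)]
        space = sample_space(points, seed=1)
        assert sorted(space.points) == sorted(points)
        assert set(space.tags) == {"all"}

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            sample_space([(0, 0), (1, 1), (2, 0)], interior_frac=0.0)

    def test_every_exterior_point_sampled(self):
        rng = np.random.default_rng(3)
        pts = {(int(x), int(y))
               for x, y in zip(rng.normal(50, 12, 1000), rng.normal(20, 5, 1000))}
        pts = sorted(pts)
        space = sample_space(pts, seed=4)
        # brute-force membership in the 2-SD PCA region
        arr = np.asarray(pts, float)
        centered = arr - arr.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(np.cov(centered.T))
        scores = centered @ eigvecs.T[::-1].T
        sds = scores.std(axis=0, ddof=1)
        exterior = {
            tuple(map(int, p))
            for p, s in zip(pts, scores)
            if np.any(np.abs(s) > 2.0 * sds)
        }
        assert exterior <= set(space.points)
        for p, tag in zip(space.points, space.tags):
            if p in exterior:
                assert tag == "exterior"

    def test_edges_of_space_sampled(self):
        rng = np.random.default_rng(5)
        pts = sorted({(int(x), int(y)) for x, y in
                      zip(rng.integers(0, 40, 300), rng.integers(0, 15, 300))})
        space = sample_space(pts, seed=6)
        arr = np.asarray(pts)
        sampled = set(space.points)
        for x in np.unique(arr[:, 0]):
            ys = arr[arr[:, 0] == x, 1]
            assert (int(x), int(ys.min())) in sampled
            assert (int(x), int(ys.max())) in sampled

    def test_interior_fraction_size(self):
        rng = np.random.default_rng(7)
        pts = sorted({(int(x), int(y)) for x, y in
                      zip(rng.normal(100, 10, 2000), rng.normal(40, 6, 2000))})
        space = sample_space(pts, interior_frac=0.15, seed=8)
        n_interior_sampled = sum(t == "interior" for t in space.tags)
        # interior-tagged sampled points are at most the 15% quota
        arr = np.asarray(pts, float)
        centered = arr - arr.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(np.cov(centered.T))
        scores = centered @ eigvecs.T[::-1].T
        sds = scores.std(axis=0, ddof=1)
        n_interior = int(np.sum(np.all(np.abs(scores) <= 2 * sds, axis=1)))
        assert n_interior_sampled <= int(np.ceil(0.15 * n_interior))


class TestSimulateRandomNetworks:
    def test_single_noun_always_isolated(self, default_lexicon):
        noun_means, verb_means = simulate_random_networks(
            (1, 0), default_lexicon, "all", reps=20, seed=1
        )
        assert np.all(noun_means == 0)
        assert verb_means is None

    def test_forced_topology_two_nouns(self):
        from lexnets.norms import Lexicon, LexiconEntry

        # every noun pair shares exactly one perceptual feature
        lex = Lexicon([
            LexiconEntry(f"n{i}", "noun",
                         frozenset([("<shared>", "perceptual"),
                                    (f"<own{i}>", "encyclopedic")]))
            for i in range(6)
        ] + [
            LexiconEntry("v0", "verb", frozenset([("<v>", "functional")]))
        ])
        noun_means, _ = simulate_random_networks((2, 0), lex, "perceptual",
                                                 reps=30, seed=2)
        assert np.all(noun_means == 1.0)

    def test_capacity_error(self, default_lexicon):
        with pytest.raises(ValueError, match="capacity"):
            simulate_random_networks((1000, 0), default_lexicon, "all", reps=1)

    def test_distribution_matches_brute_force_oracle(self, default_lexicon):
        """Matrix-based simulation agrees in distribution with an
        independent per-replicate network construction."""
        rng = np.random.default_rng(11)
        noun_means, verb_means = simulate_random_networks(
            (5, 2), default_lexicon, "perceptual", reps=200, seed=12
        )
        nouns = sorted(default_lexicon.keys("noun"))
        verbs = sorted(default_lexicon.keys("verb"))
        oracle = []
        for _ in range(200):
            vocab = [nouns[i] for i in rng.choice(len(nouns), 5, replace=False)]
            vocab += [verbs[i] for i in rng.choice(len(verbs), 2, replace=False)]
            g = build_network(vocab, default_lexicon, "perceptual")
            oracle.append(mean_degree_by_pos(g, "perceptual").noun_mean)
        ks = stats.ks_2samp(noun_means, oracle)
        assert ks.pvalue > 0.01


class TestAssembleHistograms:
    def _samples(self, default_lexicon, points, reps=100, seed=3):
        return simulate_space(points, shared_feature_matrix(default_lexicon, "all"),
                              "all", reps=reps, seed=seed)

    def test_columns_sum_to_one(self, default_lexicon):
        samples = self._samples(default_lexicon, [(5, 2), (20, 6), (40, 10)])
        hists = assemble_histograms(samples, "all", n_bins=16)
        for hist in hists.values():
            for mass in hist.columns.values():
                assert mass.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all(mass >= 0)

    def test_too_few_bins_rejected(self, default_lexicon):
        samples = self._samples(default_lexicon, [(5, 2)])
        with pytest.raises(ValueError):
            assemble_histograms(samples, "all", n_bins=4)

    def test_degenerate_all_zero_degrees(self):
        samples = {(1, 0): (np.zeros(50), None)}
        hists = assemble_histograms(samples, "all", n_bins=8)
        col = hists["noun"].column((1, 0))
        assert col[0] == pytest.approx(1.0)

    def test_histogram_mean_matches_sample_mean(self, default_lexicon):
        samples = self._samples(default_lexicon, [(30, 8)], reps=300)
        hists = assemble_histograms(samples, "all", n_bins=64)
        hist = hists["noun"]
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        width = hist.bin_edges[1] - hist.bin_edges[0]
        hist_mean = float(hist.column((30, 8)) @ centers)
        assert abs(hist_mean - samples[(30, 8)][0].mean()) < width

    def test_round_trip_save_load(self, tmp_path, default_lexicon):
        samples = self._samples(default_lexicon, [(5, 2), (9, 3)])
        hist = assemble_histograms(samples, "all", n_bins=16)["noun"]
        path = tmp_path / "hist.npz"
        hist.save(path)
        again = DegreeHistogram3D.load(path)
        assert again.restriction == hist.restriction
        assert np.array_equal(again.bin_edges, hist.bin_edges)
        assert set(again.columns) == set(hist.columns)
        for p in hist.columns:
            assert np.array_equal(again.columns[p], hist.columns[p])


def _delta_hist(points_to_bin, n_bins=16):
    columns = {}
    for point, b in points_to_bin.items():
        mass = np.zeros(n_bins)
        mass[b] = 1.0
        columns[point] = mass
    return DegreeHistogram3D(
        restriction="all", pos="noun",
        bin_edges=np.linspace(0.0, float(n_bins), n_bins + 1),
        columns=columns, reps=100, seed=0,
    )


class TestInterpolateSpace:
    def test_identity_at_sampled_point(self, default_lexicon):
        samples = simulate_space(
            [(5, 2), (20, 5), (10, 8)],
            shared_feature_matrix(default_lexicon, "all"), "all",
            reps=100, seed=4,
        )
        hist = assemble_histograms(samples, "all", n_bins=16)["noun"]
        out = interpolate_space(hist, [(20, 5)])
        assert np.allclose(out.column((20, 5)), hist.column((20, 5)), atol=1e-9)

    def test_midpoint_mixes_linearly(self):
        hist = _delta_hist({(0, 0): 3, (2, 0): 5, (0, 2): 3, (2, 2): 5})
        out = interpolate_space(hist, [(1, 0)])
        col = out.column((1, 0))
        assert col[3] == pytest.approx(0.5, abs=1e-9)
        assert col[5] == pytest.approx(0.5, abs=1e-9)

    def test_outside_hull_falls_back_to_nearest(self):
        hist = _delta_hist({(0, 0): 3, (2, 0): 5, (0, 2): 7, (2, 2): 9})
        out = interpolate_space(hist, [(10, 10)])
        assert out.column((10, 10))[9] == pytest.approx(1.0)

    def test_no_columns_is_state_error(self):
        hist = _delta_hist({})
        with pytest.raises(NormalizationStateError):
            interpolate_space(hist, [(1, 1)])

    def test_interpolated_means_vary_smoothly(self, default_lexicon):
        pts = [(nn, nv) for nn in (5, 15, 25, 35) for nv in (2, 6, 10)]
        samples = simulate_space(
            pts, shared_feature_matrix(default_lexicon, "all"), "all",
            reps=150, seed=5,
        )
        hist = assemble_histograms(samples, "all", n_bins=32)["noun"]
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        grid = [(nn, nv) for nn in range(5, 36) for nv in (2, 6, 10)]
        out = interpolate_space(hist, grid)
        sampled_means = {p: float(hist.column(p) @ centers) for p in pts}
        max_adjacent = max(
            abs(sampled_means[(a, v)] - sampled_means[(b, v)])
            for a, b in [(5, 15), (15, 25), (25, 35)] for v in (2, 6, 10)
        )
        for v in (2, 6, 10):
            means = [float(out.column((nn, v)) @ centers) for nn in range(5, 36)]
            jumps = np.abs(np.diff(means))
            assert jumps.max() <= max_adjacent + 1e-9


class TestSmoothHistograms:
    def test_delta_becomes_symmetric_unimodal(self):
        hist = _delta_hist({(1, 1): 8})
        out = smooth_histograms(hist, bandwidth_bins=2.0)
        col = out.column((1, 1))
        assert col.argmax() == 8
        assert np.allclose(col[8 - 3:8], col[8 + 3:8:-1], atol=1e-12)

    def test_uniform_column_is_invariant(self):
        columns = {(1, 1): np.full(16, 1.0 / 16)}
        hist = DegreeHistogram3D("all", "noun", np.linspace(0, 16, 17),
                                 columns, 10, 0)
        out = smooth_histograms(hist, bandwidth_bins=2.0)
        assert np.allclose(out.column((1, 1)), 1.0 / 16, atol=1e-6)

    def test_mean_preserved_within_half_bin(self, default_lexicon):
        samples = simulate_space(
            [(25, 8)], shared_feature_matrix(default_lexicon, "all"), "all",
            reps=200, seed=6,
        )
        hist = assemble_histograms(samples, "all", n_bins=64)["noun"]
        out = smooth_histograms(hist, bandwidth_bins=2.0)
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        width = hist.bin_edges[1] - hist.bin_edges[0]
        before = float(hist.column((25, 8)) @ centers)
        after = float(out.column((25, 8)) @ centers)
        assert abs(after - before) <= width / 2

    def test_bad_bandwidth_rejected(self):
        hist = _delta_hist({(1, 1): 3})
        with pytest.raises(ValueError):
            smooth_histograms(hist, bandwidth_bins=0.0)


class TestPercentileRank:
    edges = np.linspace(0.0, 10.0, 11)

    def test_below_first_edge_is_zero(self):
        col = np.full(10, 0.1)
        assert percentile_rank(-1.0, col, self.edges) == 0.0

    def test_above_last_edge_is_hundred(self):
        col = np.full(10, 0.1)
        assert percentile_rank(11.0, col, self.edges) == 100.0

    def test_uniform_column_linear(self):
        col = np.full(10, 0.1)
        assert percentile_rank(5.0, col, self.edges) == pytest.approx(50.0)
        assert percentile_rank(2.5, col, self.edges) == pytest.approx(25.0)

    def test_empty_column_is_state_error(self):
        with pytest.raises(NormalizationStateError):
            percentile_rank(5.0, np.zeros(10), self.edges)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        raws=st.tuples(st.floats(0, 10), st.floats(0, 10)),
        seed=st.integers(0, 1000),
    )
    def test_monotone_in_raw_degree(self, raws, seed):
        rng = np.random.default_rng(seed)
        col = rng.dirichlet(np.ones(10))
        lo, hi = min(raws), max(raws)
        assert (percentile_rank(lo, col, self.edges)
                <= percentile_rank(hi, col, self.edges))

    def test_probability_integral_transform_at_sampled_point(
        self, default_lexicon
    ):
        """At an exactly sampled point with smoothing off, the average
        percentile of each replicate's own degree is ~50."""
        point = (30, 10)
        noun_means, _ = simulate_random_networks(
            point, default_lexicon, "all", reps=1000, seed=13
        )
        hists = assemble_histograms({point: (noun_means, None)}, "all", n_bins=64)
        hist = hists["noun"]
        pcts = [percentile_rank(v, hist.column(point), hist.bin_edges)
                for v in noun_means]
        assert abs(np.mean(pcts) - 50.0) <= 3.0


class TestNormalizeChildren:
    def test_identical_vocabularies_identical_records(self, default_lexicon):
        kids = [_child(0, 30, 8, default_lexicon), _child(1, 30, 8, default_lexicon)]
        hists, _ = build_null_histograms(default_lexicon, kids, ["all"],
                                         reps=50, seed=3)
        rec = normalize_children(kids, default_lexicon, hists)
        piv = rec.pivot(index="child_id", columns="pos",
                        values="normalized_degree")
        assert np.allclose(piv.loc["c0"], piv.loc["c1"])

    def test_zero_verbs_yields_no_verb_records(self, default_lexicon):
        kids = [_child(0, 20, 0, default_lexicon), _child(1, 20, 5, default_lexicon)]
        hists, _ = build_null_histograms(default_lexicon, kids, ["all"],
                                         reps=50, seed=4)
        rec = normalize_children(kids, default_lexicon, hists)
        assert rec[(rec.child_id == "c0") & (rec.pos == "verb")].empty
        assert not rec[(rec.child_id == "c0") & (rec.pos == "noun")].empty

    def test_normalized_degree_bounds(self, null_calibration):
        v = null_calibration["records"]["normalized_degree"]
        assert (v >= 0).all() and (v <= 100).all()

    def test_all_columns_sum_to_one(self, null_calibration):
        for hist in null_calibration["hists"].values():
            for mass in hist.columns.values():
                assert mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_auto_smoothing_applies_only_when_slight(default_lexicon):
    """The end-to-end builder smooths at fine degree resolution (where a
    2-bin kernel is slight) and skips it at coarse resolution (where the
    kernel would dominate the column spread and bias percentiles)."""
    rng = np.random.default_rng(21)
    kids = [
        _child(i, int(rng.integers(10, 300)), int(rng.integers(2, 90)),
               default_lexicon)
        for i in range(25)
    ]
    from lexnets.normalize import assemble_histograms as _ah  # noqa: F401
    coarse, _ = build_null_histograms(default_lexicon, kids, ["all"],
                                      reps=80, n_bins=64, seed=5, smooth="auto")
    forced, _ = build_null_histograms(default_lexicon, kids, ["all"],
                                      reps=80, n_bins=64, seed=5, smooth=False)
    point = next(iter(coarse[("all", "noun")].columns))
    assert np.allclose(coarse[("all", "noun")].column(point),
                       forced[("all", "noun")].column(point))
    fine, _ = build_null_histograms(default_lexicon, kids, ["all"],
                                    reps=80, n_bins=1024, seed=5, smooth="auto")
    unsmoothed_fine, _ = build_null_histograms(default_lexicon, kids, ["all"],
                                               reps=80, n_bins=1024, seed=5,
                                               smooth=False)
    assert not np.allclose(fine[("all", "noun")].column(point),
                           unsmoothed_fine[("all", "noun")].column(point))
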