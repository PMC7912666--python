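"""Selection procedures against brute-force oracles and partition laws."""

import itertools

import numpy as np
import pytest

from nirselect.selection import (
    Dendrogram,
    cut_dendrogram,
    group_by_nh,
    hc_pick,
    pick_center,
    pick_sqrt_n,
    select_by_count,
    ward_dendrogram,
)
from nirselect.spectral_space import ScoreMatrix


def _scores(pts, k=None):
    pts = np.asarray(pts, dtype=float)
    return ScoreMatrix(sample_ids=list(range(len(pts))), scores=pts, k=k or pts.shape[1])


def _nh_from_points(pts):
    pts = np.asarray(pts, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    return (diff**2).sum(axis=-1) / pts.shape[1]


def _ess(points):
    c = points.mean(axis=0)
    return float(((points - c) ** 2).sum())


def ward_oracle(X):
    """Exhaustive Ward: merge the pair with the minimal ESS increase; record
    (height = 2 * delta-ESS, partition after the merge) at every step."""
    clusters = [frozenset([i]) for i in range(len(X))]
    steps = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            merged = clusters[a] | clusters[b]
            cost = (
                _ess(X[sorted(merged)])
                - _ess(X[sorted(clusters[a])])
                - _ess(X[sorted(clusters[b])])
            )
            if best is None or cost < best[0]:
                best = (cost, a, b)
        cost, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        steps.append((2.0 * cost, frozenset(clusters)))
    return steps


class TestGroupByNH:
    def test_all_far_apart_gives_singletons(self):
        nh = np.full((5, 5), 10.0)
        np.fill_diagonal(nh, 0.0)
        g = group_by_nh(nh, 0.6)
        assert g.n_groups == 5
        assert all(len(grp.member_indices) == 1 for grp in g.groups)

    def test_two_identical_samples_one_group(self):
        nh = np.array([[0.0, 0.0], [0.0, 0.0]])
        g = group_by_nh(nh, 0.6)
        assert g.n_groups == 1
        assert sorted(g.groups[0].member_indices) == [0, 1]

    def test_two_separated_blobs(self, rng):
        # 6 + 4 points, tight within blobs, far between
        pts = np.vstack(
            [rng.normal(0, 0.05, size=(6, 2)), rng.normal(10, 0.05, size=(4, 2))]
        )
        nh = _nh_from_points(pts)
        g = group_by_nh(nh, 0.5)
        assert g.n_groups == 2
        assert sorted(len(grp.member_indices) for grp in g.groups) == [4, 6]

    def test_partition_property(self, small_scores):
        from nirselect.spectral_space import nh_matrix

        _, scores = small_scores
        nh = nh_matrix(scores)
        for thr in (0.2, 0.6, 0.9, 2.0):
            g = group_by_nh(nh, thr)
            all_members = sorted(
                i for grp in g.groups for i in grp.member_indices
            )
            assert all_members == list(range(nh.shape[0]))
            # members within threshold of the formation seed
            for grp in g.groups:
                assert all(nh[grp.seed_index, m] <= thr for m in grp.member_indices)

    def test_group_count_non_increasing_in_threshold(self, small_scores):
        from nirselect.spectral_space import nh_matrix

        _, scores = small_scores
        nh = nh_matrix(scores)
        counts = [group_by_nh(nh, t).n_groups for t in (0.1, 0.3, 0.6, 0.9, 1.5, 3.0)]
        assert counts == sorted(counts, reverse=True)

    def test_non_symmetric_rejected(self):
        nh = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            group_by_nh(nh, 0.6)


class TestPicks:
    def test_center_one_per_group(self, small_scores):
        from nirselect.spectral_space import nh_matrix

        _, scores = small_scores
        nh = nh_matrix(scores)
        g = group_by_nh(nh, 0.6)
        res = pick_center(g)
        assert res.n_selected == g.n_groups
        assert len(set(res.selected_ids)) == res.n_selected

    def test_singleton_groups_select_themselves(self):
        nh = np.full((4, 4), 9.0)
        np.fill_diagonal(nh, 0.0)
        res = pick_center(group_by_nh(nh, 0.5))
        assert sorted(res.selected_ids) == [0, 1, 2, 3]

    def test_center_minimizes_summed_nh(self, rng):
        pts = rng.normal(size=(8, 2))
        nh = _nh_from_points(pts)
        g = group_by_nh(nh, 1e6)  # one big group
        assert g.n_groups == 1
        center = g.groups[0].center_index
        sums = nh.sum(axis=1)
        assert center == int(np.argmin(sums))

    @pytest.mark.parametrize("m,expected", [(1, 1), (4, 2), (9, 3), (30, 5), (2, 1)])
    def test_sqrt_n_pick_counts(self, m, expected, rng):
        pts = rng.normal(0, 0.01, size=(m, 2))
        nh = _nh_from_points(pts)
        g = group_by_nh(nh, 1e6)
        res = pick_sqrt_n(g, nh)
        assert res.n_selected == expected

    def test_sqrt_n_total_is_sum_over_groups(self, small_scores):
        from nirselect.spectral_space import nh_matrix
        from nirselect.synthetic import round_half_up

        _, scores = small_scores
        nh = nh_matrix(scores)
        g = group_by_nh(nh, 0.6)
        res = pick_sqrt_n(g, nh)
        expected = sum(
            round_half_up(np.sqrt(len(grp.member_indices))) for grp in g.groups
        )
        assert res.n_selected == expected

    def test_maximin_on_line_picks_extremes_and_center(self):
        pts = np.column_stack([np.arange(9.0), np.zeros(9)])
        nh = _nh_from_points(pts)
        g = group_by_nh(nh, 1e6)
        res = pick_sqrt_n(g, nh)  # round(sqrt(9)) = 3 picks
        assert res.n_selected == 3
        assert set(res.selected_ids) == {0, 4, 8}  # center first, then both ends


class TestWardDendrogram:
    def test_two_samples_merge_at_squared_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = ward_dendrogram(_scores(pts))
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(25.0)

    def test_duplicate_points_merge_at_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        pts[2] = pts[0]
        dend = ward_dendrogram(_scores(pts))
        assert dend.merges[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_non_decreasing(self, small_scores):
        _, scores = small_scores
        dend = ward_dendrogram(scores)
        assert np.all(np.diff(dend.merges[:, 2]) >= -1e-9)
        assert dend.d_max == pytest.approx(dend.merges[:, 2].max())

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_matches_exhaustive_ess_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        dend = ward_dendrogram(_scores(X))
        oracle = ward_oracle(X)
        from nirselect.selection import _cluster_members, _labels_after_merges

        for step, (height, partition) in enumerate(oracle):
            assert dend.merges[step, 2] == pytest.approx(height, rel=1e-8)
            labels = _labels_after_merges(dend, step + 1)
            got = frozenset(
                frozenset(np.flatnonzero(labels == g)) for g in np.unique(labels)
            )
            assert got == partition


class TestCutDendrogram:
    def test_full_cut_is_one_group(self, small_scores):
        _, scores = small_scores
        dend = ward_dendrogram(scores)
        labels = cut_dendrogram(dend, 100.0)
        assert len(np.unique(labels)) == 1

    def test_cut_below_first_merge_gives_singletons(self, rng):
        X = rng.normal(size=(10, 2))
        dend = ward_dendrogram(_scores(X))
        tiny = 100.0 * dend.merges[0, 2] / dend.d_max / 2.0
        labels = cut_dendrogram(dend, tiny)
        assert len(np.unique(labels)) == 10

    def test_group_count_monotone_in_cut(self, small_scores):
        _, scores = small_scores
        dend = ward_dendrogram(scores)
        n_at = lambda p: len(np.unique(cut_dendrogram(dend, p)))
        assert n_at(0.5) >= n_at(1.0) >= n_at(5.0) >= n_at(100.0)

    def test_percent_out_of_range_rejected(self, small_scores):
        _, scores = small_scores
        dend = ward_dendrogram(scores)
        for p in (0.0, -1.0, 101.0):
            with pytest.raises(ValueError):
                cut_dendrogram(dend, p)


class TestHCPick:
    def test_one_pick_per_group(self, small_scores):
        _, scores = small_scores
        dend = ward_dendrogram(scores)
        labels = cut_dendrogram(dend, 5.0)
        res = hc_pick(dend, labels, "one", seed=0)
        assert res.n_selected == len(np.unique(labels))
        # each pick belongs to its own group
        pos = {s: i for i, s in enumerate(res.sample_ids)}
        assert len({labels[pos[s]] for s in res.selected_ids}) == res.n_selected

    def test_singleton_group_sqrt_n_returns_it(self):
        pts = np.array([[0.0], [10.0], [10.1]])
        dend = ward_dendrogram(_scores(pts))
        labels = cut_dendrogram(dend, 1.0)
        res = hc_pick(dend, labels, "sqrt_n", seed=1)
        assert 0 in res.selected_ids

    def test_three_separated_triplets_one_pick_each(self, rng):
        # one group of nine = three tight, well-separated triplets:
        # the sqrt-subcluster cut must take one sample per triplet
        pts = np.vstack(
            [rng.normal(c, 0.01, size=(3, 2)) for c in ((0, 0), (50, 0), (0, 50))]
        )
        dend = ward_dendrogram(_scores(pts))
        labels = np.zeros(9, dtype=int)  # a single group
        res = hc_pick(dend, labels, "sqrt_n", seed=2)
        assert res.n_selected == 3
        triplet = [set(range(0, 3)), set(range(3, 6)), set(range(6, 9))]
        hit = [any(s in t for s in res.selected_ids) for t in triplet]
        assert all(hit)

    def test_seed_contract(self, small_scores):
        _, scores = small_scores
        dend = ward_dendrogram(scores)
        labels = cut_dendrogram(dend, 5.0)
        a = hc_pick(dend, labels, "one", seed=7)
        b = hc_pick(dend, labels, "one", seed=7)
        assert a.selected_ids == b.selected_ids


class TestSelectByCount:
    def test_hc_target_n_gives_singletons(self, small_scores):
        _, scores = small_scores
        n = scores.scores.shape[0]
        res = select_by_count("HC", n, scores=scores)
        assert res.n_selected == n

    def test_hc_exact_target_on_142_sample_set(self):
        from nirselect import spectral_space, synthetic

        ds = synthetic.generate_population(
            synthetic.SimulationConfig(n_samples=142, seed=0)
        ).to_absorbance()
        pca = spectral_space.fit_pca(ds.spectra, target_explained=0.99)
        scores = pca.transform(ds.spectra, ds.sample_ids)
        res = select_by_count("HC", 47, scores=scores)
        assert res.n_selected == 47
        assert set(res.selected_ids) <= set(ds.sample_ids)

    def test_nh_target_one_covers_all(self, small_scores):
        from nirselect.spectral_space import nh_matrix

        _, scores = small_scores
        nh = nh_matrix(scores)
        res = select_by_count("NH", 1, nh=nh)
        assert res.n_selected == 1
        assert len(np.unique(res.group_labels)) == 1

    def test_nh_smallest_threshold_achieving_target(self, rng):
        pts = rng.normal(size=(12, 2))
        nh = _nh_from_points(pts)
        res = select_by_count("NH", 4, nh=nh)
        thr = res.params["threshold"]
        assert group_by_nh(nh, thr).n_groups == 4
        # any strictly smaller observed threshold yields more groups
        smaller = np.unique(nh)[np.unique(nh) < thr]
        if len(smaller):
            assert group_by_nh(nh, smaller[-1]).n_groups > 4

    def test_partition_and_selection_subset_invariants(self, small_scores):
        from nirselect.spectral_space import nh_matrix

        _, scores = small_scores
        nh = nh_matrix(scores)
        for res in (
            select_by_count("NH", 5, nh=nh),
            select_by_count("HC", 9, scores=scores),
        ):
            assert len(res.group_labels) == len(res.sample_ids)
            assert set(res.selected_ids) <= set(res.sample_ids)
            assert res.n_selected == len(np.unique(res.group_labels))

    def test_target_out_of_range_rejected(self, small_scores):
        _, scores = small_scores
        with pytest.raises(ValueError):
            select_by_count("HC", 0, scores=scores)
        with pytest.raises(ValueError):
            select_by_count("HC", scores.scores.shape[0] + 1, scores=scores)


def test_selection_frame_round_trip(small_scores):
    from nirselect.spectral_space import nh_matrix

    _, scores = small_scores
    nh = nh_matrix(scores)
    res = pick_center(group_by_nh(nh, 0.6))
    df = res.to_frame()
    assert df["selected"].sum() == res.n_selected
    assert list(df.columns) == ["id", "group", "selected"]
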