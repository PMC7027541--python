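import numpy as np
import pytest
from hypothesis import given, strategies as st

import vplatelet as vp
from vplatelet.errors import ConfigurationError
from vplatelet.smlm import NOISE, read_localizations


def make_table(coords, photons=None):
    coords = np.asarray(coords, float).reshape(-1, 2)
    if photons is None:
        photons = np.full(coords.shape[0], 1000.0)
    return vp.LocalizationTable(x=coords[:, 0], y=coords[:, 1], photons=photons)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_dbscan(coords, eps, min_pts):
    """O(n^2) textbook DBSCAN: returns (core_mask, core_labels).

    Core labels partition only core points (connected components of the
    eps-graph restricted to cores); border handling is left to the
    implementation under test.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    nbrs = d <= eps
    core = nbrs.sum(axis=1) >= min_pts  # self-distance 0 counts the point
    labels = np.full(n, -1)
    current = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(nbrs[j] & core):
                if labels[k] == -1:
                    labels[k] = current
                    stack.append(k)
        current += 1
    return core, labels


def monotone_chain_hull_area(points):
    """Shoelace area of an independently computed (Andrew) convex hull."""
    pts = sorted(map(tuple, np.asarray(points, float)))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def partitions_equal(labels_a, labels_b, mask):
    """Same grouping of the masked points, ignoring label numbering."""
    pairs_a = {}
    for la, lb in zip(labels_a[mask], labels_b[mask]):
        if la in pairs_a and pairs_a[la] != lb:
            return False
        pairs_a[la] = lb
    return len(set(pairs_a.values())) == len(pairs_a)


# ---------------------------------------------------------------------------
# photon filter
# ---------------------------------------------------------------------------

class TestFilterPhotons:
    def test_strictly_greater_than(self):
        table = make_table([[0, 0], [1, 0], [2, 0], [3, 0]],
                           photons=np.array([400.0, 500.0, 501.0, 900.0]))
        kept = vp.filter_photons(table, 500.0)
        np.testing.assert_array_equal(kept.photons, [501.0, 900.0])
        np.testing.assert_array_equal(kept.x, [2.0, 3.0])  # order preserved

    def test_empty_table_passes_through(self):
        empty = vp.LocalizationTable(x=np.empty(0), y=np.empty(0),
                                     photons=np.empty(0))
        assert len(vp.filter_photons(empty, 500.0)) == 0

    def test_zero_threshold_keeps_positive_counts(self):
        table = make_table([[0, 0], [1, 0]], photons=np.array([0.0, 1.0]))
        kept = vp.filter_photons(table, 0.0)
        np.testing.assert_array_equal(kept.photons, [1.0])


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

class TestDbscan:
    def test_disc_plus_isolated_points(self, rng):
        # 12 points inside a disc of radius 10 plus 5 isolated points far
        # away: one cluster of 12, five noise points at eps 25 / min_pts 10
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        disc = np.column_stack([8 * np.cos(theta), 8 * np.sin(theta)])
        isolated = np.array([[200, 0], [0, 300], [-250, 0], [0, -400], [350, 350]])
        table = make_table(np.vstack([disc, isolated]))
        result = vp.dbscan(table, vp.ClusterParams(eps_nm=25.0, min_pts=10))
        assert result.n_clusters == 1
        assert (result.labels[:12] == 0).all()
        assert (result.labels[12:] == NOISE).all()
        # agree with the independent brute-force oracle
        core, ref_labels = brute_force_dbscan(table.coords, 25.0, 10)
        np.testing.assert_array_equal(result.core_mask, core)
        assert partitions_equal(result.labels, ref_labels, core)

    def test_empty_input(self):
        empty = vp.LocalizationTable(x=np.empty(0), y=np.empty(0),
                                     photons=np.empty(0))
        result = vp.dbscan(empty, vp.ClusterParams())
        assert result.n_clusters == 0 and result.n_noise == 0

    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_on_random_sets(self, seed):
        r = np.random.default_rng(seed)
        coords = r.uniform(0, 200, size=(r.integers(5, 80), 2))
        table = make_table(coords)
        params = vp.ClusterParams(eps_nm=25.0, min_pts=4)
        result = vp.dbscan(table, params)
        core, ref_labels = brute_force_dbscan(coords, 25.0, 4)
        np.testing.assert_array_equal(result.core_mask, core)
        assert partitions_equal(result.labels, ref_labels, core)

    def test_border_points_join_lowest_index_core(self, rng):
        coords = rng.uniform(0, 150, size=(60, 2))
        table = make_table(coords)
        params = vp.ClusterParams(eps_nm=30.0, min_pts=5)
        result = vp.dbscan(table, params)
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        for i in np.flatnonzero(~result.core_mask):
            reachable = np.flatnonzero(result.core_mask & (d[i] <= params.eps_nm))
            if reachable.size:
                assert result.labels[i] == result.labels[reachable.min()]
            else:
                assert result.labels[i] == NOISE

    def test_exclude_edge_points_leaves_borders_noise(self, rng):
        coords = rng.uniform(0, 150, size=(80, 2))
        table = make_table(coords)
        incl = vp.dbscan(table, vp.ClusterParams(eps_nm=30, min_pts=5))
        excl = vp.dbscan(
            table, vp.ClusterParams(eps_nm=30, min_pts=5, include_edge_points=False)
        )
        border = ~incl.core_mask & (incl.labels != NOISE)
        assert (excl.labels[border] == NOISE).all()
        np.testing.assert_array_equal(incl.labels[incl.core_mask],
                                      excl.labels[excl.core_mask])

    def test_permutation_invariance_of_cluster_sets(self, rng):
        coords = rng.uniform(0, 120, size=(70, 2))
        perm = rng.permutation(70)
        params = vp.ClusterParams(eps_nm=25, min_pts=5)
        a = vp.dbscan(make_table(coords), params)
        b = vp.dbscan(make_table(coords[perm]), params)
        clusters_a = {frozenset(map(tuple, a.cluster_points(c)))
                      for c in range(a.n_clusters)}
        clusters_b = {frozenset(map(tuple, b.cluster_points(c)))
                      for c in range(b.n_clusters)}
        assert clusters_a == clusters_b

    def test_coclustering_preserved_under_larger_eps(self, rng):
        coords = rng.uniform(0, 100, size=(60, 2))
        table = make_table(coords)
        small = vp.dbscan(table, vp.ClusterParams(eps_nm=15, min_pts=4))
        large = vp.dbscan(table, vp.ClusterParams(eps_nm=30, min_pts=4))
        for i in range(len(table)):
            for j in range(i + 1, len(table)):
                if small.labels[i] == small.labels[j] != NOISE:
                    assert large.labels[i] == large.labels[j] != NOISE

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            vp.ClusterParams(eps_nm=0.0)
        with pytest.raises(ConfigurationError):
            vp.ClusterParams(min_pts=0)


# ---------------------------------------------------------------------------
# hull area
# ---------------------------------------------------------------------------

class TestHullArea:
    def test_unit_square(self):
        assert vp.hull_area([[0, 0], [0, 1], [1, 0], [1, 1]]) == pytest.approx(1.0)

    def test_collinear_and_tiny_inputs_are_flat(self):
        assert vp.hull_area([[0, 0], [1, 1], [2, 2]]) == 0.0
        assert vp.hull_area([[0, 0], [1, 1]]) == 0.0
        assert vp.hull_area([[5, 5]]) == 0.0

    @given(seed=st.integers(0, 10_000))
    def test_matches_shoelace_oracle(self, seed):
        r = np.random.default_rng(seed)
        pts = r.normal(0, 50, size=(r.integers(3, 50), 2))
        assert vp.hull_area(pts) == pytest.approx(
            monotone_chain_hull_area(pts), rel=1e-9, abs=1e-12
        )

    def test_scaling_squares_the_area(self, rng):
        pts = rng.normal(0, 20, size=(40, 2))
        s = 3.7
        assert vp.hull_area(pts * s) == pytest.approx(
            s**2 * vp.hull_area(pts), rel=1e-9
        )


# ---------------------------------------------------------------------------
# metrics and replicate grouping
# ---------------------------------------------------------------------------

def _summary_for(coords_list, roi_area, fov):
    table = make_table(np.vstack(coords_list))
    result = vp.dbscan(table, vp.ClusterParams(eps_nm=25, min_pts=5))
    summary = vp.cluster_metrics(result, roi_area)
    summary["fov"] = fov
    return summary


class TestClusterMetrics:
    def test_density_and_per_roi_count(self, rng):
        blob = rng.normal([100, 100], 5, size=(100, 2))
        table = make_table(blob)
        result = vp.dbscan(table, vp.ClusterParams(eps_nm=25, min_pts=10))
        assert result.n_clusters == 1
        out = vp.cluster_metrics(result, roi_area_um2=10.0)
        row = out["per_cluster"].iloc[0]
        assert row["n_detections"] == 100
        assert row["density_per_nm2"] == pytest.approx(
            100 / row["hull_area_nm2"]
        )
        assert out["clusters_per_um2"] == pytest.approx(0.1)

    def test_division_examples(self):
        # 27 clusters in 10 um^2 -> 2.7 clusters/um^2; density 100/2000
        assert 100 / 2000.0 == pytest.approx(0.05)
        blobs = [np.random.default_rng(i).normal([200 * i, 0], 4, size=(30, 2))
                 for i in range(1, 28)]
        table = make_table(np.vstack(blobs))
        result = vp.dbscan(table, vp.ClusterParams(eps_nm=25, min_pts=10))
        assert result.n_clusters == 27
        out = vp.cluster_metrics(result, roi_area_um2=10.0)
        assert out["clusters_per_um2"] == pytest.approx(2.7)

    def test_zero_area_cluster_excluded_from_density(self):
        # 10 coincident points form a zero-area cluster
        coords = np.zeros((10, 2))
        table = make_table(coords)
        result = vp.dbscan(table, vp.ClusterParams(eps_nm=25, min_pts=10))
        out = vp.cluster_metrics(result, roi_area_um2=1.0)
        assert out["n_clusters"] == 1
        assert np.isnan(out["per_cluster"]["density_per_nm2"].iloc[0])

    def test_density_scale_invariance(self, rng):
        blob = rng.normal([100, 100], 6, size=(80, 2))
        s = 2.0
        r1 = vp.dbscan(make_table(blob), vp.ClusterParams(eps_nm=25, min_pts=10))
        r2 = vp.dbscan(make_table(blob * s),
                       vp.ClusterParams(eps_nm=25 * s, min_pts=10))
        a1 = vp.cluster_metrics(r1, 1.0)["per_cluster"]
        a2 = vp.cluster_metrics(r2, 1.0)["per_cluster"]
        assert a2["hull_area_nm2"].iloc[0] == pytest.approx(
            s**2 * a1["hull_area_nm2"].iloc[0], rel=1e-9
        )
        assert a2["density_per_nm2"].iloc[0] == pytest.approx(
            a1["density_per_nm2"].iloc[0] / s**2, rel=1e-9
        )

    def test_nonpositive_roi_rejected(self, rng):
        table = make_table(rng.uniform(0, 10, size=(5, 2)))
        result = vp.dbscan(table, vp.ClusterParams())
        with pytest.raises(ConfigurationError):
            vp.cluster_metrics(result, roi_area_um2=0.0)


class TestGroupReplicates:
    def _fovs(self, rng, n_fovs):
        summaries = []
        for f in range(n_fovs):
            blobs = [rng.normal([300 * (i + 1), 0], 5, size=(40, 2))
                     for i in range(3)]
            summaries.append(_summary_for(blobs, roi_area=12.0, fov=f"fov{f}"))
        return summaries

    def test_five_fovs_three_replicates(self, rng):
        summaries = self._fovs(rng, 15)
        mapping = {f"fov{i}": f"rep{i // 5}" for i in range(15)}
        out = vp.group_replicates(summaries, mapping)
        assert len(out["per_replicate"]) == 3
        assert out["condition"]["n_replicates"] == 3
        assert out["condition"]["clusters_per_um2"]["sd"] is not None

    def test_single_replicate_has_no_sd(self, rng):
        summaries = self._fovs(rng, 1)
        out = vp.group_replicates(summaries, {"fov0": "rep0"})
        assert out["condition"]["n_replicates"] == 1
        assert out["condition"]["clusters_per_um2"]["sd"] is None

    def test_identical_replicates_have_zero_sd(self, rng):
        base = self._fovs(rng, 1)[0]
        a = dict(base); a["fov"] = "f0"
        b = dict(base); b["fov"] = "f1"
        out = vp.group_replicates([a, b], {"f0": "r0", "f1": "r1"})
        assert out["condition"]["clusters_per_um2"]["sd"] == pytest.approx(0.0)

    def test_unmapped_fov_rejected(self, rng):
        summaries = self._fovs(rng, 1)
        with pytest.raises(ConfigurationError):
            vp.group_replicates(summaries, {"other": "rep0"})


class TestIO:
    def test_read_localizations(self, tmp_path):
        path = tmp_path / "locs.csv"
        path.write_text(
            "x_nm,y_nm,photons,extra\n1.5,2.5,600,a\n10,20,400,b\n"
        )
        table = read_localizations(path)
        assert len(table) == 2
        np.testing.assert_array_equal(table.x, [1.5, 10.0])
        bad = tmp_path / "bad.csv"
        bad.write_text("x_nm,photons\n1,600\n")
        with pytest.raises(ConfigurationError):
            read_localizations(bad)
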