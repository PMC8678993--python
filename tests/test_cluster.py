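"""Cumulative seizure features and Ward hierarchical clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hippospec import cluster, io
from hippospec.synthetic import SeizureSimConfig, TierSpec, make_seizure_logs


# ---------------------------------------------------------------------------
# independent oracle: Ward merges via the centroid formula
# d(A, B) = 2 |A||B| / (|A|+|B|) * ||mean_A - mean_B||^2
# (equal to the Lance-Williams recursion on squared Euclidean distances)


def centroid_ward_oracle(X):
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma = X[clusters[a]].mean(axis=0)
            mb = X[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            d = 2.0 * na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
            if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and (a, b) < best[1:]):
                best = (d, a, b)
        d, a, b = best
        new = n + step
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d, len(clusters[new])))
    return np.array(merges).reshape(-1, 4)


def exhaustive_two_partition_wss(X):
    """Minimum within-cluster sum of squares over all 2-partitions."""
    n = X.shape[0]
    best = np.inf
    for code in range(1, 1 << (n - 1)):  # fix point 0 in cluster 0
        sel = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        wss = 0.0
        for part in (X[sel], X[~sel]):
            if len(part):
                wss += float(((part - part.mean(axis=0)) ** 2).sum())
        best = min(best, wss)
    return best


def wss_of(X, labels):
    return sum(
        float(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum())
        for c in np.unique(labels)
    )


def _log(animal_id, clonic_i, clonic_d, tonic_i=0, tonic_d=0.0, days=21):
    rec = pd.DataFrame(
        {
            "day": np.arange(1, days + 1),
            "clonic_intensity": clonic_i,
            "clonic_duration_s": clonic_d,
            "tonic_intensity": tonic_i,
            "tonic_duration_s": tonic_d,
        }
    )
    return io.SeizureLog(animal_id, rec, n_days=days)


class TestCumulativeFeatures:
    def test_all_zero_log(self):
        f = cluster.cumulative_features(_log("K01", 0, 0.0), "clonic")
        assert (f.cumulative_intensity, f.cumulative_duration) == (0.0, 0.0)

    def test_daily_intensity_three_totals_sixty_three(self):
        f = cluster.cumulative_features(_log("K01", 3, 10.0), "clonic")
        assert f.cumulative_intensity == 63.0
        assert f.cumulative_duration == 210.0

    def test_single_nonzero_day(self):
        rec_i = np.zeros(21, dtype=int)
        rec_d = np.zeros(21)
        rec_i[4], rec_d[4] = 2, 30.0
        f = cluster.cumulative_features(_log("K01", rec_i, rec_d), "clonic")
        assert (f.cumulative_intensity, f.cumulative_duration) == (2.0, 30.0)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            cluster.cumulative_features(_log("K01", 0, 0.0), "absence")


class TestWardLinkage:
    def test_one_dimensional_example(self):
        """Points {0, 1, 10}: the close pair merges first."""
        Z = cluster.ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        assert (Z[0, 0], Z[0, 1]) == (0, 1)
        assert Z[0, 2] == pytest.approx(1.0)  # squared distance
        labels = cluster.Dendrogram(Z, ("a", "b", "c"), "ward.d").cut(2)
        assert labels[0] == labels[1] != labels[2]

    def test_merge_sequence_matches_centroid_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 7))
            X = rng.normal(size=(n, 2))
            Z = cluster.ward_linkage(X)
            W = centroid_ward_oracle(X)
            np.testing.assert_array_equal(Z[:, :2], W[:, :2])
            np.testing.assert_allclose(Z[:, 2], W[:, 2], rtol=1e-9)
            np.testing.assert_array_equal(Z[:, 3], W[:, 3])

    def test_heights_non_decreasing(self, rng):
        for _ in range(50):
            X = rng.normal(size=(int(rng.integers(2, 12)), 3))
            Z = cluster.ward_linkage(X)
            assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_permutation_invariance_up_to_relabeling(self, rng):
        X = rng.normal(size=(8, 2))
        base = cluster.Dendrogram(cluster.ward_linkage(X), tuple("abcdefgh"), "d").cut(3)
        for _ in range(10):
            perm = rng.permutation(8)
            lab = cluster.Dendrogram(
                cluster.ward_linkage(X[perm]), tuple("abcdefgh"), "d"
            ).cut(3)
            unperm = np.empty(8, dtype=int)
            unperm[perm] = lab
            # same partition regardless of cluster numbering
            assert len({(a, b) for a, b in zip(base, unperm)}) == len(set(base))

    def test_ward_d2_matches_scipy(self, rng):
        from scipy.cluster.hierarchy import linkage

        X = rng.normal(size=(10, 2))
        Z = cluster.ward_linkage(X, dialect="ward.d2")
        S = linkage(X, method="ward")
        np.testing.assert_allclose(Z[:, 2], S[:, 2], rtol=1e-8)
        assert {frozenset(r) for r in Z[:, :2]} == {frozenset(r) for r in S[:, :2]}

    def test_greedy_k2_cut_against_exhaustive_partitions(self, rng):
        """The k=2 Ward cut never beats, and usually attains, the optimum."""
        attained = 0
        for _ in range(60):
            X = rng.normal(size=(6, 2))
            labels = cluster.Dendrogram(
                cluster.ward_linkage(X), tuple("abcdef"), "d"
            ).cut(2)
            greedy = wss_of(X, labels)
            optimum = exhaustive_two_partition_wss(X)
            assert greedy >= optimum - 1e-9
            if greedy <= optimum + 1e-9:
                attained += 1
        assert attained >= 45  # greedy Ward finds the optimal 2-split most of the time

    def test_k_equals_n(self, rng):
        X = rng.normal(size=(5, 2))
        labels = cluster.Dendrogram(cluster.ward_linkage(X), tuple("abcde"), "d").cut(5)
        assert sorted(labels) == [0, 1, 2, 3, 4]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster.Dendrogram(cluster.ward_linkage(np.zeros((3, 1))), ("a", "b", "c"), "d").cut(4)


class TestWardCluster:
    def test_planted_tiers_recovered(self):
        cfg = SeizureSimConfig(seed=11)
        logs, truth = make_seizure_logs(cfg)
        _, frame = cluster.ward_cluster(logs, "clonic", 3)
        label_to_tier = {"CS": 0, "ICS": 1, "LCS": 2}
        got = frame["label"].map(label_to_tier).to_numpy()
        np.testing.assert_array_equal(got, truth["clonic_tier"].to_numpy())
        _, frame_t = cluster.ward_cluster(logs, "tonic", 2)
        got_t = frame_t["label"].map({"TS": 0, "LTS": 1}).to_numpy()
        np.testing.assert_array_equal(got_t, truth["tonic_tier"].to_numpy())

    def test_severity_ordering_of_labels(self):
        cfg = SeizureSimConfig(seed=3)
        logs, _ = make_seizure_logs(cfg)
        _, frame = cluster.ward_cluster(logs, "clonic", 3)
        feats = {f.animal_id: f.cumulative_intensity
                 for f in (cluster.cumulative_features(l, "clonic") for l in logs)}
        means = frame.assign(ci=frame["animal_id"].map(feats)).groupby("label")["ci"].mean()
        assert means["CS"] >= means["ICS"] >= means["LCS"]

    def test_identical_features_deterministic_with_warning(self):
        logs = [_log(f"K{i}", 1, 10.0) for i in range(4)]
        with pytest.warns(UserWarning, match="identical"):
            _, frame = cluster.ward_cluster(logs, "clonic", 2)
        assert len(frame) == 4
        with pytest.warns(UserWarning):
            _, frame2 = cluster.ward_cluster(logs, "clonic", 2)
        pd.testing.assert_frame_equal(frame, frame2)

    def test_single_animal_single_cluster(self):
        _, frame = cluster.ward_cluster([_log("K01", 2, 30.0)], "clonic", 1)
        assert frame["cluster"].tolist() == [0]

    def test_newick_and_frame_export(self):
        logs, _ = make_seizure_logs(SeizureSimConfig(seed=5))
        dend, _ = cluster.ward_cluster(logs, "tonic", 2)
        nwk = dend.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == len(logs) - 1
        frame = dend.to_frame()
        assert list(frame.columns) == ["cluster_a", "cluster_b", "height", "size"]
        assert frame["size"].iloc[-1] == len(logs)

    def test_assign_subgroups_joint_frame(self):
        logs, _ = make_seizure_logs(SeizureSimConfig(seed=9))
        merged, dend_c, dend_t = cluster.assign_subgroups(logs)
        assert set(merged["clonic_label"]) == {"CS", "ICS", "LCS"}
        assert set(merged["tonic_label"]) == {"TS", "LTS"}
        assert len(merged) == 16
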