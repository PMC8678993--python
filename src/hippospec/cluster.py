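"""Severity subgrouping of animals by Ward clustering of seizure behavior.

Each animal is reduced, independently per seizure type, to two cumulative
features — total intensity score and total duration over the stimulation
period — and the cohort is partitioned by agglomerative hierarchical
clustering with Ward's criterion.  The default dialect applies the
Lance-Williams Ward update directly to squared Euclidean distances (the
"classic"/Ward.D convention of legacy statistics packages); the Ward.D2
variant (on distances) is available by flag.  Cutting the clonic tree at
k=3 yields CS/ICS/LCS (severe/intermediate/light clonic seizures) and the
tonic tree at k=2 yields TS/LTS, labels ordered by cluster-mean cumulative
intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SeizureLog

CLONIC_LABELS = ("CS", "ICS", "LCS")
TONIC_LABELS = ("TS", "LTS")


@dataclass(frozen=True)
class BehaviorFeatures:
    animal_id: str
    seizure_type: str  # "clonic" | "tonic"
    cumulative_intensity: float
    cumulative_duration: float  # s


@dataclass
class Dendrogram:
    """Merge list in scipy linkage convention.

    ``merges`` has one row per agglomeration step: (cluster a, cluster b,
    merge height, new cluster size), clusters 0..n-1 being the leaves and
    step i creating cluster n+i.  ``leaves`` are the animal ids in input
    order.
    """

    merges: np.ndarray  # (n-1, 4)
    leaves: tuple[str, ...]
    dialect: str

    def cut(self, k: int) -> np.ndarray:
        """Cluster index (0-based, arbitrary order) per leaf at k clusters."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}, got {k}")
        parent = list(range(n + max(0, n - k)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for step in range(n - k):
            a, b = int(self.merges[step, 0]), int(self.merges[step, 1])
            new = n + step
            parent[find(a)] = new
            parent[find(b)] = new
        roots = {find(i) for i in range(n)}
        index = {r: i for i, r in enumerate(sorted(roots))}
        return np.array([index[find(i)] for i in range(n)])

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaves[i] for i in range(n)}
        for step in range(n - 1):
            a, b, h = int(self.merges[step, 0]), int(self.merges[step, 1]), float(self.merges[step, 2])
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + step] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + step] = h
        return node[n + (n - 2)] + ";" if n > 1 else node[0] + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["cluster_a", "cluster_b", "height", "size"])


def cumulative_features(log: SeizureLog, seizure_type: str) -> BehaviorFeatures:
    """Sum of daily intensity scores and durations for one seizure type."""
    if seizure_type not in ("clonic", "tonic"):
        raise ValueError(f"unknown seizure type {seizure_type!r}")
    r = log.records
    return BehaviorFeatures(
        log.animal_id,
        seizure_type,
        float(r[f"{seizure_type}_intensity"].sum()),
        float(r[f"{seizure_type}_duration_s"].sum()),
    )


def feature_matrix(
    logs: Sequence[SeizureLog], seizure_type: str, standardize: bool = True
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """(features, animal ids, raw cumulative intensities) for a cohort.

    Features are z-scored by default: cumulative intensity (score units)
    and duration (seconds) are incommensurate, and raw Euclidean geometry
    would be dominated by whichever has the larger numeric range.  A zero
    spread feature standardizes to zeros.
    """
    feats = [cumulative_features(log, seizure_type) for log in logs]
    ids = [f.animal_id for f in feats]
    X = np.array([[f.cumulative_intensity, f.cumulative_duration] for f in feats], dtype=float)
    raw_intensity = X[:, 0].copy()
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X, ids, raw_intensity


def ward_linkage(X: np.ndarray, dialect: str = "ward.d") -> np.ndarray:
    """Agglomerative Ward linkage by the Lance-Williams recursion.

    ``ward.d`` runs the recursion on squared Euclidean distances (heights
    are in squared-distance units); ``ward.d2`` on distances.  Minimum-
    distance ties are broken by the lexicographically smallest (a, b)
    cluster-id pair, making the merge order fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D (animals x features)")
    if dialect not in ("ward.d", "ward.d2"):
        raise ValueError(f"unknown linkage dialect {dialect!r}")
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one observation")
    diff = X[:, None, :] - X[None, :, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    dist = {
        (i, j): (sq[i, j] if dialect == "ward.d" else float(np.sqrt(sq[i, j])))
        for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for idx_a in range(len(active)):
            for idx_b in range(idx_a + 1, len(active)):
                a, b = active[idx_a], active[idx_b]
                d = dist[(a, b)]
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d_ab, a, b = best
        new = n + step
        merges[step] = (a, b, d_ab, size[a] + size[b])
        na, nb = size[a], size[b]
        for k in active:
            if k in (a, b):
                continue
            nk = size[k]
            dka = dist[(min(a, k), max(a, k))]
            dkb = dist[(min(b, k), max(b, k))]
            if dialect == "ward.d2":
                dka, dkb, d = dka**2, dkb**2, d_ab**2
            else:
                d = d_ab
            upd = ((na + nk) * dka + (nb + nk) * dkb - nk * d) / (na + nb + nk)
            if dialect == "ward.d2":
                upd = float(np.sqrt(max(upd, 0.0)))
            dist[(k, new)] = upd
        size[new] = na + nb
        active = [c for c in active if c not in (a, b)] + [new]
    return merges


def severity_labels(
    assignment: np.ndarray, raw_intensity: np.ndarray, labels: Sequence[str]
) -> dict[int, str]:
    """Map cluster indices to severity labels by mean cumulative intensity.

    The most intense cluster receives the first label (severe); ties are
    broken by the smallest member index for determinism.
    """
    k = int(assignment.max()) + 1
    if k != len(labels):
        raise ValueError(f"{len(labels)} labels for {k} clusters")
    stats = []
    for c in range(k):
        members = np.flatnonzero(assignment == c)
        stats.append((-float(raw_intensity[members].mean()), int(members.min()), c))
    return {c: labels[rank] for rank, (_, _, c) in enumerate(sorted(stats))}


def label_order(seizure_type: str, k: int) -> tuple[str, ...]:
    """Severity labels, most severe first, for a cut of the given scheme."""
    if seizure_type == "clonic" and k == 3:
        return CLONIC_LABELS
    if seizure_type == "tonic" and k == 2:
        return TONIC_LABELS
    return tuple(f"T{i + 1}" for i in range(k))


def ward_cluster(
    logs: Sequence[SeizureLog],
    seizure_type: str,
    k: int,
    standardize: bool = True,
    dialect: str = "ward.d",
) -> tuple[Dendrogram, pd.DataFrame]:
    """Cluster a cohort on cumulative features and label severity subgroups.

    Returns the dendrogram and a frame (animal_id, cluster, label) where
    labels are CS/ICS/LCS (clonic, k=3) or TS/LTS (tonic, k=2); for other
    k the labels are T1 (most severe) .. Tk.
    """
    X, ids, raw = feature_matrix(logs, seizure_type, standardize=standardize)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} animals")
    merges = ward_linkage(X, dialect=dialect)
    dend = Dendrogram(merges, tuple(ids), dialect)
    assignment = dend.cut(k) if len(ids) > 1 else np.zeros(1, dtype=int)
    if len(ids) > 1 and np.ptp(X, axis=0).max() == 0:
        warnings.warn("all feature vectors identical; clusters are index tie-breaks only")
    name = severity_labels(assignment, raw, label_order(seizure_type, k))
    frame = pd.DataFrame(
        {"animal_id": ids, "cluster": assignment, "label": [name[c] for c in assignment]}
    )
    return dend, frame


def assign_subgroups(
    logs: Sequence[SeizureLog],
    k_clonic: int = 3,
    k_tonic: int = 2,
    standardize: bool = True,
    dialect: str = "ward.d",
) -> tuple[pd.DataFrame, Dendrogram, Dendrogram]:
    """Clonic (k=3) and tonic (k=2) subgroup labels for one animal cohort."""
    dend_c, frame_c = ward_cluster(logs, "clonic", k_clonic, standardize, dialect)
    dend_t, frame_t = ward_cluster(logs, "tonic", k_tonic, standardize, dialect)
    if list(frame_c["animal_id"]) != list(frame_t["animal_id"]):
        raise ValueError("clonic and tonic clusterings cover different animal sets")
    merged = frame_c.rename(columns={"cluster": "clonic_cluster", "label": "clonic_label"})
    merged["tonic_cluster"] = frame_t["cluster"]
    merged["tonic_label"] = frame_t["label"]
    return merged, dend_c, dend_t
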