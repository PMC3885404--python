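"""Structural-class derivation and supervised classification.

The class library is built per training area: standardized profile
features are reduced with PCA (keeping components explaining 99% of the
variance), clustered with an iterative migrating-means (ISO) procedure in
which clusters covering less than 1% of the area are dissolved, and
summarized into per-class statistics.  Libraries from several areas are
combined by single-link merging of near-identical centroids.  New scenes
are then classified per cell with a minimum-distance (nearest-centroid)
classifier; agreement with field labels is scored with Cohen's kappa.

Sensor intensity is carried through the feature table but excluded from
the supervised classification by default: across-flight intensity
differences are not radiometrically corrected here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

UNCLASSIFIED = -1


@dataclass
class ClassSummary:
    """Per-class statistics over member cells."""

    class_id: int
    centroid: np.ndarray  # in standardized feature space
    mean_ch: float  # mean canopy height of members (m)
    mean_gc: float  # mean ground cover of members (%)
    area_fraction: float
    n_members: int
    layer_stats: dict = field(default_factory=dict)  # min/max/median per attribute
    label: str = ""


@dataclass
class StructuralClassLibrary:
    """Feature standardization plus the list of class summaries."""

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    classes: list[ClassSummary] = field(default_factory=list)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    @property
    def class_ids(self) -> np.ndarray:
        return np.array([c.class_id for c in self.classes])

    def centroids(self) -> np.ndarray:
        return np.vstack([c.centroid for c in self.classes])

    def class_means(self) -> pd.DataFrame:
        """Mean canopy height / ground cover per class, indexed by id."""
        return pd.DataFrame(
            {
                "mean_ch": [c.mean_ch for c in self.classes],
                "mean_gc": [c.mean_gc for c in self.classes],
            },
            index=self.class_ids,
        )

    def get(self, class_id: int) -> ClassSummary:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(f"no class with id {class_id}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "classes": [
                {
                    "class_id": int(c.class_id),
                    "centroid": c.centroid.tolist(),
                    "mean_ch": c.mean_ch,
                    "mean_gc": c.mean_gc,
                    "area_fraction": c.area_fraction,
                    "n_members": c.n_members,
                    "layer_stats": c.layer_stats,
                    "label": c.label,
                }
                for c in self.classes
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StructuralClassLibrary":
        payload = json.loads(Path(path).read_text())
        lib = cls(
            feature_names=payload["feature_names"],
            mean=np.array(payload["mean"]),
            std=np.array(payload["std"]),
        )
        for c in payload["classes"]:
            lib.classes.append(
                ClassSummary(
                    class_id=c["class_id"],
                    centroid=np.array(c["centroid"]),
                    mean_ch=c["mean_ch"],
                    mean_gc=c["mean_gc"],
                    area_fraction=c["area_fraction"],
                    n_members=c["n_members"],
                    layer_stats=c["layer_stats"],
                    label=c["label"],
                )
            )
        return lib


def standardize_features(X: np.ndarray):
    """Z-score features; zero-variance columns are dropped with a warning.

    Returns ``(Z, mean, std, kept)`` where ``kept`` indexes retained
    columns.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    kept = np.flatnonzero(std > 0)
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"dropped {X.shape[1] - len(kept)} zero-variance feature(s)", stacklevel=2
        )
    Z = (X[:, kept] - mean[kept]) / std[kept]
    return Z, mean[kept], std[kept], kept


def pca_reduce(Z: np.ndarray, variance_kept: float = 0.99):
    """Project standardized features onto the smallest set of principal
    components whose cumulative explained variance reaches the target.

    Returns ``(scores, pca)``; the fitted sklearn PCA carries the loadings
    for projecting new data.
    """
    n_comp = min(Z.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, n_comp)
    pca.components_ = pca.components_[:k]
    pca.explained_variance_ = pca.explained_variance_[:k]
    pca.explained_variance_ratio_ = pca.explained_variance_ratio_[:k]
    pca.n_components_ = k
    return scores[:, :k], pca


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding."""
    n = len(X)
    centroids = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(cdist(X, np.vstack(centroids), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total == 0:
            centroids.append(X[rng.integers(n)])
            continue
        probs = d2 / total
        centroids.append(X[rng.choice(n, p=probs)])
    return np.vstack(centroids)


def iso_cluster(
    scores: np.ndarray,
    k_init: int,
    min_area: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    split_std: float | None = None,
    merge_dist: float | None = None,
):
    """Migrating-means (ISO) clustering with a minimum-area rule.

    Lloyd-style iteration from a seeded k-means++ start: assign each
    sample to its nearest centroid, migrate centroids to member means,
    repeat until the largest centroid shift drops below ``tol`` or
    ``max_iter`` is reached.  Afterwards, clusters holding less than
    ``min_area`` of the samples are dissolved (smallest first) and their
    members reassigned to the nearest surviving centroid, whose position
    is then updated.  Optional ISODATA-style split (member std above
    ``split_std``) and merge (centroid distance below ``merge_dist``)
    steps are off by default.

    Returns ``(labels, centroids)`` with labels indexing rows of
    ``centroids``.
    """
    X = np.asarray(scores, dtype=float)
    n = len(X)
    if n == 0:
        raise ValueError("no samples to cluster")
    rng = np.random.default_rng(seed)
    if np.allclose(X, X[0]):
        warnings.warn("all samples identical; single class returned", stacklevel=2)
        return np.zeros(n, dtype=int), X[:1].copy()
    k = min(k_init, n)
    centroids = _kmeanspp_init(X, k, rng)
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        labels = np.argmin(cdist(X, centroids), axis=1)
        new_centroids = centroids.copy()
        for c in range(len(centroids)):
            members = X[labels == c]
            if len(members):
                new_centroids[c] = members.mean(axis=0)
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        if shift < tol:
            break

    if merge_dist is not None:
        centroids = _merge_close(centroids, merge_dist)
        labels = np.argmin(cdist(X, centroids), axis=1)
    if split_std is not None:
        centroids = _split_wide(X, labels, centroids, split_std)
        labels = np.argmin(cdist(X, centroids), axis=1)

    # dissolve under-area clusters, smallest first
    while True:
        counts = np.bincount(labels, minlength=len(centroids))
        small = np.flatnonzero(counts < min_area * n)
        if len(small) == 0 or len(centroids) - len(np.flatnonzero(counts == 0)) <= 1:
            break
        victim = small[np.argmin(counts[small])]
        keep = np.array([c for c in range(len(centroids)) if c != victim])
        if len(keep) == 0:
            break
        centroids = centroids[keep]
        labels = np.argmin(cdist(X, centroids), axis=1)
        for c in range(len(centroids)):
            members = X[labels == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
    # drop empty clusters and compact labels
    counts = np.bincount(labels, minlength=len(centroids))
    keep = np.flatnonzero(counts > 0)
    remap = {old: new for new, old in enumerate(keep)}
    centroids = centroids[keep]
    labels = np.array([remap[l] for l in labels])
    return labels, centroids


def _merge_close(centroids: np.ndarray, merge_dist: float) -> np.ndarray:
    d = cdist(centroids, centroids)
    np.fill_diagonal(d, np.inf)
    while d.min() < merge_dist and len(centroids) > 1:
        a, b = np.unravel_index(np.argmin(d), d.shape)
        a, b = min(a, b), max(a, b)
        merged = (centroids[a] + centroids[b]) / 2
        centroids = np.vstack([centroids[:b], centroids[b + 1 :]])
        centroids[a] = merged
        d = cdist(centroids, centroids)
        np.fill_diagonal(d, np.inf)
    return centroids


def _split_wide(X, labels, centroids, split_std: float) -> np.ndarray:
    out = []
    for c in range(len(centroids)):
        members = X[labels == c]
        if len(members) > 1 and members.std(axis=0).max() > split_std:
            axis = int(np.argmax(members.std(axis=0)))
            offset = np.zeros(centroids.shape[1])
            offset[axis] = members[:, axis].std()
            out.extend([centroids[c] + offset, centroids[c] - offset])
        else:
            out.append(centroids[c])
    return np.vstack(out)


def summarize_classes(
    labels: np.ndarray,
    features: pd.DataFrame,
    centroids: np.ndarray,
    feature_names: list[str],
    mean: np.ndarray,
    std: np.ndarray,
) -> StructuralClassLibrary:
    """Build a class library from cluster labels and per-cell attributes.

    ``features`` must carry ``canopy_height``, ``cover`` and
    ``crown_thickness`` columns aligned with ``labels``; per-class
    min/max/median of these layer attributes are recorded along with mean
    canopy height (CH) and mean ground cover (GC).  Empty classes are
    excluded with a warning.
    """
    labels = np.asarray(labels)
    lib = StructuralClassLibrary(feature_names=list(feature_names), mean=np.asarray(mean), std=np.asarray(std))
    n = len(labels)
    attrs = ("canopy_height", "cover", "crown_thickness")
    for cid in range(len(centroids)):
        members = features.loc[labels == cid]
        if len(members) == 0:
            warnings.warn(f"class {cid} has no members; excluded", stacklevel=2)
            continue
        stats = {
            a: {
                "min": float(members[a].min()),
                "max": float(members[a].max()),
                "median": float(members[a].median()),
            }
            for a in attrs
        }
        lib.classes.append(
            ClassSummary(
                class_id=cid,
                centroid=np.asarray(centroids[cid], dtype=float),
                mean_ch=float(members["canopy_height"].mean()),
                mean_gc=float(members["cover"].mean()),
                area_fraction=len(members) / n,
                n_members=len(members),
                layer_stats=stats,
            )
        )
    return lib


def merge_libraries(
    libraries: list[StructuralClassLibrary], merge_tol: float = 0.5
) -> StructuralClassLibrary:
    """Combine class libraries from several areas, merging near-duplicates.

    All libraries must share feature space and standardization.  Classes
    whose centroids fall within ``merge_tol`` (standardized Euclidean) are
    merged transitively (single link); the merged centroid and CH/GC means
    are area-weighted, layer stats take the envelope (min of mins, max of
    maxes, weighted mean of medians).  Class ids are reassigned 0..k-1.
    """
    if not libraries:
        raise ValueError("no libraries to merge")
    ref = libraries[0]
    for lib in libraries[1:]:
        if lib.feature_names != ref.feature_names or not (
            np.allclose(lib.mean, ref.mean) and np.allclose(lib.std, ref.std)
        ):
            raise ValueError("libraries have incompatible feature spaces")
    allc = [c for lib in libraries for c in lib.classes]
    cents = np.vstack([c.centroid for c in allc])
    # single-link components under merge_tol
    n = len(allc)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d = cdist(cents, cents)
    for a in range(n):
        for b in range(a + 1, n):
            if d[a, b] < merge_tol:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for idx in range(n):
        groups.setdefault(find(idx), []).append(idx)

    merged = StructuralClassLibrary(
        feature_names=ref.feature_names, mean=ref.mean, std=ref.std
    )
    total_members = sum(c.n_members for c in allc)
    for new_id, members_idx in enumerate(sorted(groups.values(), key=min)):
        members = [allc[i] for i in members_idx]
        w = np.array([c.n_members for c in members], dtype=float)
        w /= w.sum()
        centroid = np.average([c.centroid for c in members], axis=0, weights=w)
        stats = {}
        for a in members[0].layer_stats:
            stats[a] = {
                "min": min(c.layer_stats[a]["min"] for c in members),
                "max": max(c.layer_stats[a]["max"] for c in members),
                "median": float(
                    np.average([c.layer_stats[a]["median"] for c in members], weights=w)
                ),
            }
        merged.classes.append(
            ClassSummary(
                class_id=new_id,
                centroid=centroid,
                mean_ch=float(np.average([c.mean_ch for c in members], weights=w)),
                mean_gc=float(np.average([c.mean_gc for c in members], weights=w)),
                area_fraction=sum(c.n_members for c in members) / total_members,
                n_members=sum(c.n_members for c in members),
                label="+".join(filter(None, (c.label for c in members))),
            )
        )
    return merged


def min_distance_classify(features: np.ndarray, centroids: np.ndarray, class_ids=None) -> np.ndarray:
    """Nearest-centroid (minimum Euclidean distance) classification.

    ``features`` must already be in the library's standardized space.
    Ties go to the smallest class id; rows with non-finite values get the
    ``UNCLASSIFIED`` sentinel.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    ids = np.arange(len(centroids)) if class_ids is None else np.asarray(class_ids)
    order = np.argsort(ids, kind="stable")
    dist = cdist(X, np.asarray(centroids)[order])
    labels = ids[order][np.argmin(dist, axis=1)]  # argmin takes first (smallest id) on ties
    bad = ~np.isfinite(X).all(axis=1)
    labels = labels.astype(int)
    labels[bad] = UNCLASSIFIED
    return labels


def apply_class_mapping(labels: np.ndarray, mapping: pd.DataFrame) -> np.ndarray:
    """Map profile-class ids to broader structural-class ids.

    ``mapping`` is a two-column table (``profile_class``,
    ``structural_class``), the analyst-supplied merge of profile classes
    into named structural vegetation classes.
    """
    lut = dict(
        zip(mapping["profile_class"].astype(int), mapping["structural_class"].astype(int))
    )
    return np.array([lut.get(int(l), UNCLASSIFIED) for l in np.asarray(labels).ravel()]).reshape(
        np.asarray(labels).shape
    )


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square confusion matrix.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = trace/total`` and chance agreement
    ``p_e = sum(row_i * col_i) / total^2``.  Raises on degenerate margins
    (``p_e == 1``).
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (M < 0).any():
        raise ValueError("confusion matrix must be nonnegative")
    total = M.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(M) / total
    p_e = float(M.sum(axis=1) @ M.sum(axis=0)) / total**2
    if np.isclose(p_e, 1.0):
        raise ValueError("degenerate margins: chance agreement is 1, kappa undefined")
    return float((p_o - p_e) / (1 - p_e))
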