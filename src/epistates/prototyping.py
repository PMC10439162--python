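"""Prototype construction: PCA, k-means clustering and centroid labeling.

A prototype set is built from any dataset in three steps: (1) PCA of the
z-normalized 11-feature matrix down to four components, (2) k-means with
k=4 on the PC scores, (3) labeling each cluster centroid by Voronoi
voting of simulated model segments — every model segment (whose true
brain-state type is known from the gain configuration that generated it)
is assigned to its nearest centroid, and each centroid takes the majority
label of its region.  Centroids with empty regions are dropped; if two
centroids win the same label, only the one with more label-defining
segments is kept, so labels are unique and a prototype set may hold fewer
than four prototypes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .features import FEATURE_NAMES, FeatureMatrix, znormalize
from .model import BrainStateLabel

__all__ = [
    "Projection",
    "PrototypeSet",
    "fit_pca",
    "kmeans_cluster",
    "match_centroids",
    "build_prototypes",
]


@dataclass
class Projection:
    """A fitted PCA basis tied to its source dataset's normalization.

    ``coefficients`` is the 11 x 4 loading matrix; a z-normalized feature
    vector f is projected to PC space as f @ coefficients.  The source
    dataset's z-normalization statistics ride along so the projection is
    fully specified by this object.
    """

    coefficients: np.ndarray
    explained_variance_ratio: np.ndarray
    source_norm_stats: dict | None = None
    source_dataset_id: str = ""

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=float
        )

    def project(self, values: np.ndarray) -> np.ndarray:
        """Project z-normalized feature rows into PC score space."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.coefficients.shape[0]:
            raise ValueError(
                f"expected {self.coefficients.shape[0]} features, got {values.shape[1]}"
            )
        return values @ self.coefficients


@dataclass
class PrototypeSet:
    """Labeled centroids in PC space plus the projection defining it."""

    centroids: np.ndarray
    labels: list[BrainStateLabel]
    projection: Projection
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("prototype labels must be unique")
        if not 1 <= len(self.labels) <= 4:
            raise ValueError("a prototype set holds between 1 and 4 prototypes")

    def to_json(self) -> str:
        doc = {
            "feature_names": list(FEATURE_NAMES),
            "norm_stats": self.projection.source_norm_stats,
            "pca_coefficients": self.projection.coefficients.tolist(),
            "explained_variance_ratio": self.projection.explained_variance_ratio.tolist(),
            "centroids": self.centroids.tolist(),
            "labels": [int(l) for l in self.labels],
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PrototypeSet":
        doc = json.loads(text)
        proj = Projection(
            coefficients=np.array(doc["pca_coefficients"]),
            explained_variance_ratio=np.array(doc["explained_variance_ratio"]),
            source_norm_stats=doc.get("norm_stats"),
            source_dataset_id=doc.get("provenance", {}).get("origin", ""),
        )
        return cls(
            centroids=np.array(doc["centroids"]),
            labels=[BrainStateLabel(l) for l in doc["labels"]],
            projection=proj,
            provenance=doc.get("provenance", {}),
        )


def fit_pca(fm: FeatureMatrix, n_components: int = 4) -> tuple[Projection, np.ndarray]:
    """Fit a PCA on a z-normalized feature matrix; return it with scores.

    The loading signs are fixed so the largest-magnitude entry of each
    component is positive, making the projection reproducible (PCA signs
    are otherwise arbitrary).  ``scores = values @ coefficients``.
    """
    if fm.n_segments < n_components:
        raise ValueError("need at least as many segments as components")
    pca = PCA(n_components=n_components)
    pca.fit(fm.values)
    coeff = pca.components_.T.copy()  # (n_features, n_components)
    for j in range(coeff.shape[1]):
        i = np.argmax(np.abs(coeff[:, j]))
        if coeff[i, j] < 0:
            coeff[:, j] = -coeff[:, j]
    proj = Projection(
        coefficients=coeff,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        source_norm_stats=fm.norm_stats,
        source_dataset_id=fm.dataset_id,
    )
    return proj, fm.values @ coeff


def kmeans_cluster(
    scores: np.ndarray, k: int = 4, seed: int | None = None, n_init: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on PC scores: returns (centroids, assignments).

    Uses k-means++ initialization with ``n_init`` restarts, keeping the
    solution with the lowest within-cluster sum of squares.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < k:
        raise ValueError("need at least k points")
    if np.unique(scores, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct points: clustering is degenerate")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(scores)
    return km.cluster_centers_, assignments


def match_centroids(
    centroids: np.ndarray,
    model_scores: np.ndarray,
    model_labels: np.ndarray,
    provenance: dict | None = None,
    projection: Projection | None = None,
) -> PrototypeSet:
    """Label centroids by Voronoi voting of model segments.

    Each model segment votes in the Voronoi region of its nearest
    centroid (Euclidean distance in PC space); each centroid takes the
    majority label of its region.  Vote ties go to the lower label number
    (with a warning).  Centroids whose region is empty are dropped.  If
    two centroids receive the same label, only the one with the larger
    number of label-defining segments is kept (index ties keep the
    smaller index, with a warning).
    """
    centroids = np.asarray(centroids, dtype=float)
    model_scores = np.asarray(model_scores, dtype=float)
    model_labels = np.asarray(model_labels, dtype=int)
    if len(model_scores) != len(model_labels):
        raise ValueError("model scores and labels must align")

    nearest = np.argmin(cdist(model_scores, centroids), axis=1)

    # majority vote per region
    candidates: list[tuple[int, BrainStateLabel, int]] = []  # (centroid idx, label, votes)
    for c in range(len(centroids)):
        region = model_labels[nearest == c]
        if region.size == 0:
            warnings.warn(f"centroid {c} has an empty Voronoi region and is dropped")
            continue
        counts = np.bincount(region, minlength=5)[1:5]
        top = counts.max()
        winners = np.flatnonzero(counts == top) + 1
        if len(winners) > 1:
            warnings.warn(
                f"vote tie in region of centroid {c} between labels "
                f"{winners.tolist()}; choosing lower label"
            )
        candidates.append((c, BrainStateLabel(int(winners[0])), int(top)))

    if not candidates:
        raise ValueError("no model segment fell into any region: no prototypes")

    # duplicate-label drop rule
    best: dict[BrainStateLabel, tuple[int, int]] = {}
    for c, label, votes in candidates:
        if label not in best:
            best[label] = (c, votes)
        else:
            kept_c, kept_votes = best[label]
            if votes > kept_votes:
                best[label] = (c, votes)
            elif votes == kept_votes:
                warnings.warn(
                    f"centroids {kept_c} and {c} tie at {votes} votes for label "
                    f"{int(label)}; keeping smaller index {kept_c}"
                )
            # votes < kept_votes: drop c

    kept = sorted(best.items(), key=lambda kv: kv[0])
    prov = dict(provenance or {})
    prov["n_vote_segments"] = {int(lbl): votes for lbl, (_, votes) in kept}
    return PrototypeSet(
        centroids=centroids[[c for _, (c, _) in kept]],
        labels=[lbl for lbl, _ in kept],
        projection=projection
        if projection is not None
        else Projection(np.eye(centroids.shape[1]), np.zeros(centroids.shape[1])),
        provenance=prov,
    )


def build_prototypes(
    dataset: FeatureMatrix,
    model_vote_set: FeatureMatrix,
    seed: int | None = None,
    n_components: int = 4,
    k: int = 4,
    n_init: int = 50,
) -> PrototypeSet:
    """Full prototype construction from a raw (or normalized) dataset.

    Composes z-normalization, PCA, k-means and centroid matching.  The
    voting model segments are z-normalized with their OWN statistics and
    then projected with the prototype dataset's PCA coefficients.  For
    model-driven prototyping, pass the simulated feature matrix as both
    ``dataset`` and ``model_vote_set``.
    """
    if dataset.norm_stats is None:
        dataset = znormalize(dataset)
    if model_vote_set.norm_stats is None:
        model_vote_set = znormalize(model_vote_set)
    if model_vote_set.true_labels is None:
        raise ValueError("model vote set must carry true labels")

    proj, scores = fit_pca(dataset, n_components=n_components)
    centroids, _ = kmeans_cluster(scores, k=k, seed=seed, n_init=n_init)
    model_scores = proj.project(model_vote_set.values)
    origin = dataset.dataset_id or "dataset"
    return match_centroids(
        centroids,
        model_scores,
        model_vote_set.true_labels,
        provenance={"origin": origin, "seed": seed},
        projection=proj,
    )
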