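"""Nearest-prototype classification of data segments.

A segment is classified by projecting its z-normalized feature vector
into the prototype set's PC space (features @ PCA coefficients) and
taking the label of the Euclidean-nearest prototype centroid.  Segments
are classified independently; new data are z-normalized with the
statistics of their own dataset before projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import FeatureMatrix, znormalize
from .model import BrainStateLabel
from .prototyping import PrototypeSet

__all__ = ["Prediction", "project", "classify", "predictions_to_frame"]

_NORM_TOL = 1e-6


@dataclass
class Prediction:
    """The predicted brain-state label for one segment."""

    segment_index: int
    predicted_label: BrainStateLabel
    distance_to_prototype: float
    prototype_origin: str = ""


def project(features: np.ndarray, proto: PrototypeSet) -> np.ndarray:
    """Project z-normalized feature rows into the prototype PC space."""
    return proto.projection.project(features)


def classify(segments: FeatureMatrix, proto: PrototypeSet) -> list[Prediction]:
    """Assign each segment the label of its nearest prototype.

    ``segments`` may be raw (z-normalization with its own dataset
    statistics is applied) or already normalized.  Distance ties are
    broken toward the lower label number, with a warning.
    """
    if len(proto.labels) == 0:
        raise ValueError("empty prototype set")
    if segments.norm_stats is None:
        col_mean = segments.values.mean(axis=0)
        col_std = segments.values.std(axis=0, ddof=1)
        looks_normalized = np.all(np.abs(col_mean) < _NORM_TOL) and np.all(
            (np.abs(col_std - 1) < _NORM_TOL) | (col_std < _NORM_TOL)
        )
        if not looks_normalized:
            segments = znormalize(segments)

    scores = project(segments.values, proto)
    dists = cdist(scores, proto.centroids)

    # order centroid columns by label so argmin ties resolve to lower label
    label_order = np.argsort([int(l) for l in proto.labels])
    ordered = dists[:, label_order]
    winner = np.argmin(ordered, axis=1)
    ties = (ordered == ordered[np.arange(len(winner)), winner][:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} segment(s) equidistant to several prototypes; "
            "assigned the lower label"
        )

    origin = str(proto.provenance.get("origin", ""))
    preds = []
    for i, w in enumerate(winner):
        j = label_order[w]
        preds.append(
            Prediction(
                segment_index=i,
                predicted_label=proto.labels[j],
                distance_to_prototype=float(dists[i, j]),
                prototype_origin=origin,
            )
        )
    return preds


def predictions_to_frame(preds: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "segment_id": [p.segment_index for p in preds],
            "predicted_label": [int(p.predicted_label) for p in preds],
            "distance": [p.distance_to_prototype for p in preds],
        }
    )
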