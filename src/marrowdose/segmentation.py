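"""Intensity-based VOI segmentation.

Kidney and lesion VOIs in the clinical workflow come from semi-automatic
k-means segmentation of PET/SPECT intensities.  Here this is a 1-D k-means
on voxel intensities within a mask, with deterministic seeding and labels
fixed by sorting centroids ascending (label k = hottest cluster).
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["kmeans_segment"]


def kmeans_segment(volume: np.ndarray, k: int, mask: np.ndarray,
                   seed: int = 0) -> np.ndarray:
    """Label masked voxels 1..k by 1-D intensity k-means.

    Deterministic given ``seed`` (k-means++ init, single restart); centroids
    are sorted ascending so label identities are reproducible and ties at
    equal distance resolve toward the lower-intensity centroid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("segmentation mask is empty")
    values = np.asarray(volume, dtype=float)[mask]
    if np.unique(values).size < k:
        raise ValueError(f"fewer than k={k} distinct intensities in mask")

    km = KMeans(n_clusters=k, n_init=1, random_state=int(seed))
    # fit on sorted intensities so the result cannot depend on voxel order
    km.fit(np.sort(values).reshape(-1, 1))
    centroids = np.sort(km.cluster_centers_.ravel())
    # re-label by nearest sorted centroid; ties (equidistant) go to the
    # lower centroid via strict '<' on the midpoint comparison
    edges = 0.5 * (centroids[:-1] + centroids[1:])
    labels = np.searchsorted(edges, values, side="left") + 1

    out = np.zeros(mask.shape, dtype=np.int16)
    out[mask] = labels
    return out
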