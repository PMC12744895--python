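"""One-dimensional k-means partition of the A*alpha enhancement-rate map.

Each region of interest (tumor, ipsilateral parenchyma, contralateral
parenchyma) is clustered separately into K = 5 groups on the scalar
per-voxel A*alpha value. Spatial position is not a feature. Final labels
are renumbered 1..K in ascending order of cluster mean, so cluster 1 always
holds the slowest-enhancing voxels and cluster K the fastest.

The default initializer is deterministic — centers start at the 10th, 30th,
50th, 70th and 90th percentiles of the masked values — so repeated runs are
bit-identical without any seed. A seeded random initializer is available as
an option. Lloyd iterations stop when the assignment is stable (a fixed
point: every value sits with its nearest center) or after 300 rounds; ties
in nearest-center distance break toward the lower cluster index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import DataError
from .kinetics import PseCurve
from . import kinetics

MAX_ITER = 300


class DegenerateClusteringError(DataError):
    """Fewer distinct values than requested clusters."""


@dataclass(frozen=True)
class ClusterAssignment:
    """Result of clustering one region.

    ``label_map`` is 0 where no cluster was assigned (outside the region or
    failed fits) and 1..k ascending by cluster mean inside it.
    """

    label_map: np.ndarray
    counts: np.ndarray
    means: np.ndarray
    region: str
    k: int = 5
    n_iter: int = 0

    def cluster_mask(self, cluster: int) -> np.ndarray:
        if not 1 <= cluster <= self.k:
            raise ValueError(f"cluster index {cluster} out of 1..{self.k}")
        return self.label_map == cluster


def _assign(vals: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment; ties break toward the lower index."""
    d = np.abs(vals[:, None] - centers[None, :])
    return np.argmin(d, axis=1)          # argmin returns first minimum


def kmeans_cluster(
    values: np.ndarray,
    mask: np.ndarray,
    k: int = 5,
    seed: int | None = None,
    init: str = "quantile",
    region: str = "region",
) -> ClusterAssignment:
    """Lloyd's algorithm on the masked scalar values.

    Parameters
    ----------
    values : 3D array of A*alpha (NaN at voxels without a usable fit).
    mask : boolean region mask on the same grid.
    init : "quantile" (deterministic, default) or "random" (seeded draw of
        k distinct values).
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise DataError("values and mask grids differ")
    sel = mask & np.isfinite(values)
    vals = values[sel]
    if np.unique(vals).size < k:
        raise DegenerateClusteringError(
            f"{region}: fewer than {k} distinct A*alpha values"
        )

    if init == "quantile":
        q = (np.arange(k) * 2 + 1) / (2.0 * k) * 100.0   # 10,30,...,90 for k=5
        centers = np.percentile(vals, q)
        # collapse of percentiles onto equal values would pin clusters; nudge
        # duplicates apart deterministically within the data range
        centers = _separate(centers, vals)
    elif init == "random":
        rng = np.random.default_rng(seed)
        centers = rng.choice(np.unique(vals), size=k, replace=False)
        centers = np.sort(centers)
    else:
        raise ValueError(f"unknown initializer {init!r}")

    assign = _assign(vals, centers)
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        new_centers = centers.copy()
        for c in range(k):
            members = vals[assign == c]
            if members.size:
                new_centers[c] = members.mean()
            else:
                # re-seed an emptied cluster at the value farthest from its
                # current center (deterministic)
                far = np.argmax(np.abs(vals - centers[assign]))
                new_centers[c] = vals[far]
        new_assign = _assign(vals, new_centers)
        centers = new_centers
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign

    means = np.array([vals[assign == c].mean() for c in range(k)])
    order = np.argsort(means, kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)

    label_map = np.zeros(values.shape, dtype=np.int16)
    label_map[sel] = rank[assign] + 1
    counts = np.array([(rank[assign] + 1 == c).sum() for c in range(1, k + 1)])
    means_sorted = means[order]
    if np.any(np.diff(means_sorted) <= 0):
        raise DegenerateClusteringError(
            f"{region}: cluster means not strictly ascending"
        )
    return ClusterAssignment(label_map=label_map, counts=counts,
                             means=means_sorted, region=region, k=k,
                             n_iter=n_iter)


def _separate(centers: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Make initial centers distinct while staying inside the data range."""
    centers = centers.astype(float).copy()
    lo, hi = vals.min(), vals.max()
    eps = max((hi - lo) * 1e-6, 1e-12)
    for i in range(1, centers.size):
        if centers[i] <= centers[i - 1]:
            centers[i] = centers[i - 1] + eps
    return np.clip(centers, lo, hi + eps * centers.size)


def cluster_mean_curves(series, assignment: ClusterAssignment) -> dict[int, PseCurve]:
    """Per-cluster mean raw-signal time course converted to PSE.

    Averages raw signal across the cluster's voxels, then normalizes by the
    cluster-mean precontrast baseline (not an average of per-voxel PSE).
    """
    if assignment.label_map.shape != series.shape:
        raise DataError("assignment grid does not match series grid")
    curves: dict[int, PseCurve] = {}
    for c in range(1, assignment.k + 1):
        m = assignment.cluster_mask(c)
        if not m.any():
            raise DataError(f"cluster {c} is empty")
        curves[c] = kinetics.compute_pse(series, m)
    return curves
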