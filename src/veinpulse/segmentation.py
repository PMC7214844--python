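"""Vessel segmentation from the cycle-averaged phase-contrast magnitude image.

Small through-plane vessels appear bright in the magnitude of the complex
difference between flow-compensated and flow-encoded images.  Candidate
vessels are voxels more than k standard deviations above the image mean
(default k = 2), grouped into clusters under 8-connectivity (immediate or
diagonal adjacency), then annotated with a vessel class and vascular
territory from a reference label map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .series import GatedPCSeries

__all__ = [
    "VALID_CLASS_LABELS", "VALID_TERRITORIES", "VesselClusterMap",
    "time_average_magnitude", "threshold_mask", "label_clusters",
    "annotate_clusters", "cluster_size_summary",
]

VALID_CLASS_LABELS = ("artery", "small_vein", "surface_vein", "sinus",
                      "discard")
VALID_TERRITORIES = ("ACA", "L_MCA", "R_MCA", "PCA", "none")


@dataclass
class VesselClusterMap:
    """Labelled vessel clusters plus a per-cluster annotation table.

    ``label_image`` holds 0 for background and consecutive ids 1..K,
    assigned in raster-scan order of each cluster's first voxel.
    ``clusters`` has one row per cluster: cluster_id, size,
    class_label (``unclassified`` before annotation) and territory.
    """

    label_image: np.ndarray
    clusters: pd.DataFrame

    def __post_init__(self) -> None:
        ids = sorted(set(np.unique(self.label_image)) - {0})
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be consecutive from 1")
        if list(self.clusters["cluster_id"]) != ids:
            raise ValueError("clusters table must list every labelled cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def voxels(self, cluster_id: int) -> np.ndarray:
        """(row, col) coordinates of one cluster, raster order."""
        return np.argwhere(self.label_image == cluster_id)


def time_average_magnitude(series: GatedPCSeries) -> np.ndarray:
    """Voxelwise mean of the magnitude stack over the cardiac cycle."""
    return series.magnitude.mean(axis=2)


def threshold_mask(image: np.ndarray, k: float = 2.0,
                   roi: np.ndarray | None = None) -> np.ndarray:
    """Voxels strictly brighter than mean + k * SD of the image.

    Statistics are computed over ``roi`` when given (e.g. a brain mask),
    else over the whole image; the returned mask is likewise restricted to
    the ROI.  Strict inequality means a perfectly uniform image yields an
    empty mask.
    """
    image = np.asarray(image, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if roi is None:
        sample = image
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != image.shape:
            raise ValueError("roi must match image shape")
        if not roi.any():
            raise ValueError("roi is empty")
        sample = image[roi]
    cut = sample.mean() + k * sample.std()
    mask = image > cut
    if roi is not None:
        mask &= roi
    return mask


def label_clusters(mask: np.ndarray) -> VesselClusterMap:
    """Partition a binary mask into 8-connected clusters.

    Two super-threshold voxels sharing an edge or a corner join the same
    cluster; a one-voxel background gap separates clusters.  Ids are
    renumbered so that cluster k is the k-th component encountered in a
    raster scan.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    raw = measure.label(mask, connectivity=2)
    # renumber by raster order of each component's first voxel
    flat = raw.ravel()
    first = {}
    for idx, lab in enumerate(flat):
        if lab and lab not in first:
            first[lab] = idx
    remap = {lab: new for new, lab in
             enumerate(sorted(first, key=first.get), start=1)}
    label = np.zeros_like(raw)
    for lab, new in remap.items():
        label[raw == lab] = new
    rows = [{"cluster_id": cid, "size": int((label == cid).sum()),
             "class_label": "unclassified", "territory": "none"}
            for cid in range(1, len(remap) + 1)]
    clusters = pd.DataFrame(rows, columns=["cluster_id", "size",
                                           "class_label", "territory"])
    return VesselClusterMap(label_image=label, clusters=clusters)


def annotate_clusters(cmap: VesselClusterMap,
                      legend: pd.DataFrame | None = None,
                      reference_labels: np.ndarray | None = None,
                      reference_table: pd.DataFrame | None = None
                      ) -> VesselClusterMap:
    """Attach class and territory annotations to clusters.

    Two entry points:

    * ``legend`` — a table keyed by our own cluster_id with class_label and
      territory columns (direct assignment; unspecified clusters keep their
      current annotation).
    * ``reference_labels`` + ``reference_table`` — an independent label image
      (e.g. from manual classification, or scene ground truth) intersected
      with the clusters.  A cluster overlapping reference vessels of two
      different classes (e.g. a vein and an artery) is set to ``discard``,
      as is a cluster overlapping nothing.

    Returns a new map; the input is not modified.
    """
    clusters = cmap.clusters.copy()

    def check(name: str, valid: tuple[str, ...]) -> None:
        if name not in valid:
            raise ValueError(f"unknown label {name!r}; expected one of {valid}")

    if legend is not None:
        legend = legend.set_index("cluster_id") \
            if "cluster_id" in legend.columns else legend
        for cid, row in legend.iterrows():
            cls = row["class_label"]
            terr = row.get("territory", "none")
            check(cls, VALID_CLASS_LABELS)
            check(terr, VALID_TERRITORIES)
            sel = clusters["cluster_id"] == cid
            clusters.loc[sel, "class_label"] = cls
            clusters.loc[sel, "territory"] = terr
    elif reference_labels is not None:
        if reference_table is None:
            raise ValueError("reference_table required with reference_labels")
        ref = reference_table.set_index("cluster_id")
        for cls in ref["class_label"]:
            check(cls, VALID_CLASS_LABELS)
        for i, row in clusters.iterrows():
            vox = cmap.voxels(int(row["cluster_id"]))
            hits = reference_labels[vox[:, 0], vox[:, 1]]
            hit_ids, counts = np.unique(hits[hits > 0], return_counts=True)
            hit_classes = {ref.loc[h, "class_label"] for h in hit_ids}
            if len(hit_classes) == 1:
                best = hit_ids[np.argmax(counts)]
                clusters.loc[i, "class_label"] = ref.loc[best, "class_label"]
                clusters.loc[i, "territory"] = ref.loc[best].get("territory",
                                                                 "none")
            else:
                # ambiguous (two classes) or no overlap at all
                clusters.loc[i, "class_label"] = "discard"
                clusters.loc[i, "territory"] = "none"
    else:
        raise ValueError("provide either legend or reference_labels")
    return VesselClusterMap(label_image=cmap.label_image.copy(),
                            clusters=clusters)


def cluster_size_summary(cmap: VesselClusterMap) -> pd.DataFrame:
    """Per-class cluster-size summary: count, median, 10th-90th percentile.

    Percentiles use linear interpolation.  Classes with no clusters are
    simply absent from the table.
    """
    rows = []
    for cls, grp in cmap.clusters.groupby("class_label"):
        sizes = grp["size"].to_numpy(dtype=float)
        rows.append({"class_label": cls, "n": len(sizes),
                     "median": float(np.median(sizes)),
                     "p10": float(np.percentile(sizes, 10)),
                     "p90": float(np.percentile(sizes, 90))})
    return pd.DataFrame(rows, columns=["class_label", "n", "median",
                                       "p10", "p90"])
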