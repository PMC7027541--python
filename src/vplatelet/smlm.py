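"""Cluster analysis of 2D single-molecule localization (SMLM) tables.

The pipeline mirrors a standard dSTORM workflow: localizations are
filtered on photon count (strictly greater than a threshold), grouped
with DBSCAN (eps in nm, min_pts counting the query point itself), and
each cluster is summarized by its detection count, convex-hull area and
detection density, with per-ROI cluster counts normalized to the region
area in square micrometres.

The DBSCAN here is written out in full rather than delegated, because
the border-point rule is part of the contract: border points are
assigned deterministically to the cluster of the lowest-index core point
that reaches them, so results do not depend on traversal order.  An
external reference implementation is used in the test suite as an
independent oracle for core points and core partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, ConvexHull
from scipy.spatial import QhullError

from .errors import ConfigurationError

__all__ = [
    "NOISE",
    "LocalizationTable",
    "ClusterParams",
    "ClusterResult",
    "filter_photons",
    "dbscan",
    "hull_area",
    "cluster_metrics",
    "group_replicates",
    "read_localizations",
]

logger = logging.getLogger(__name__)

NOISE = -1  # sentinel cluster label for unclustered points
NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class LocalizationTable:
    """2D detections: x, y in nm plus a photon count per detection."""

    x: np.ndarray
    y: np.ndarray
    photons: np.ndarray
    frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        photons = np.asarray(self.photons, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "photons", photons)
        if not (x.shape == y.shape == photons.shape) or x.ndim != 1:
            raise ConfigurationError("x, y, photons must be 1-D arrays of equal length")
        if x.size and not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ConfigurationError("coordinates must be finite")
        if np.any(photons < 0):
            raise ConfigurationError("photon counts must be >= 0")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x, self.y])

    def take(self, index: np.ndarray) -> "LocalizationTable":
        frame = self.frame[index] if self.frame is not None else None
        return LocalizationTable(
            x=self.x[index], y=self.y[index], photons=self.photons[index], frame=frame
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_nm": self.x, "y_nm": self.y, "photons": self.photons})
        if self.frame is not None:
            df["frame"] = self.frame
        return df


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN and photon-filter settings.

    Defaults follow the dSTORM analysis conditions: neighborhood radius
    25 nm, minimum of 10 points (query point included), edge points
    included, photon threshold 500.
    """

    eps_nm: float = 25.0
    min_pts: int = 10
    include_edge_points: bool = True
    photon_threshold: float = 500.0

    def __post_init__(self) -> None:
        if self.eps_nm <= 0:
            raise ConfigurationError(f"eps must be > 0 nm, got {self.eps_nm}")
        if self.min_pts < 1:
            raise ConfigurationError(f"min_pts must be >= 1, got {self.min_pts}")


def filter_photons(table: LocalizationTable, threshold: float) -> LocalizationTable:
    """Keep detections with photon count strictly greater than ``threshold``."""
    keep = np.flatnonzero(table.photons > threshold)
    kept = table.take(keep)
    logger.info("photon filter >%s: kept %d of %d detections",
                threshold, len(kept), len(table))
    return kept


@dataclass(frozen=True)
class ClusterResult:
    """DBSCAN output: per-point labels plus per-cluster geometry."""

    table: LocalizationTable
    labels: np.ndarray
    params: ClusterParams
    core_mask: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if self.labels.size else 0

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))

    def cluster_points(self, label: int) -> np.ndarray:
        return self.table.coords[self.labels == label]


def dbscan(table: LocalizationTable, params: ClusterParams) -> ClusterResult:
    """Classical DBSCAN on the (already photon-filtered) table.

    A point is a core point iff at least ``min_pts`` points (itself
    included) lie within Euclidean distance ``eps_nm``.  Clusters are the
    connected components of core points under the eps relation; border
    points (non-core within eps of a core) join the cluster of the
    lowest-index core point that reaches them when
    ``include_edge_points`` is set, otherwise they stay noise.  Cluster
    ids are numbered 0.. in order of their lowest-index core point.
    """
    n = len(table)
    labels = np.full(n, NOISE, dtype=int)
    core_mask = np.zeros(n, dtype=bool)
    if n == 0:
        return ClusterResult(table=table, labels=labels, params=params,
                             core_mask=core_mask)

    tree = cKDTree(table.coords)
    neighbors = tree.query_ball_point(table.coords, r=params.eps_nm)
    core_mask = np.array([len(nb) >= params.min_pts for nb in neighbors])

    # Flood-fill the core graph in index order: cluster ids come out
    # ordered by each cluster's lowest-index core point.
    cluster_id = 0
    for i in range(n):
        if not core_mask[i] or labels[i] != NOISE:
            continue
        stack = [i]
        labels[i] = cluster_id
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if core_mask[k] and labels[k] == NOISE:
                    labels[k] = cluster_id
                    stack.append(k)
        cluster_id += 1

    if params.include_edge_points:
        for i in range(n):
            if core_mask[i] or labels[i] != NOISE:
                continue
            reached = [k for k in neighbors[i] if core_mask[k]]
            if reached:
                labels[i] = labels[min(reached)]

    return ClusterResult(table=table, labels=labels, params=params,
                         core_mask=core_mask)


def hull_area(points: np.ndarray) -> float:
    """Area (nm^2) of the 2D convex hull of a cluster's detections.

    Fewer than 3 points, or any collinear configuration, has zero area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("expected an (n, 2) coordinate array")
    if pts.shape[0] < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # degenerate (collinear / coincident) input
    return float(hull.volume)  # in 2D, ConvexHull.volume is the area


def cluster_metrics(result: ClusterResult, roi_area_um2: float) -> dict:
    """Per-cluster and per-ROI summary of a DBSCAN result.

    Returns a dict with a per-cluster :class:`pandas.DataFrame`
    (``n_detections``, ``hull_area_nm2``, ``density_per_nm2``) and ROI
    metrics (``clusters_per_um2`` = cluster count / ROI area).
    Zero-area (degenerate) clusters keep their count but are excluded
    from density statistics and logged.
    """
    if roi_area_um2 <= 0:
        raise ConfigurationError(f"ROI area must be > 0 um^2, got {roi_area_um2}")
    rows = []
    for label in range(result.n_clusters):
        pts = result.cluster_points(label)
        area = hull_area(pts)
        density = pts.shape[0] / area if area > 0 else np.nan
        if area == 0:
            logger.warning(
                "cluster %d has zero hull area (%d detections); "
                "excluded from density statistics", label, pts.shape[0]
            )
        rows.append(
            {"cluster": label, "n_detections": pts.shape[0],
             "hull_area_nm2": area, "density_per_nm2": density}
        )
    per_cluster = pd.DataFrame(
        rows, columns=["cluster", "n_detections", "hull_area_nm2", "density_per_nm2"]
    )
    return {
        "per_cluster": per_cluster,
        "n_clusters": result.n_clusters,
        "n_noise": result.n_noise,
        "roi_area_um2": float(roi_area_um2),
        "clusters_per_um2": result.n_clusters / roi_area_um2,
    }


def group_replicates(
    fov_summaries: list[dict], fov_to_replicate: dict
) -> dict:
    """Pool cluster metrics within replicates, then summarize a condition.

    ``fov_summaries`` are :func:`cluster_metrics` outputs, each carrying
    a ``"fov"`` key; ``fov_to_replicate`` maps FOV id to replicate id.
    Cluster-level metrics are pooled across the FOVs of a replicate; the
    condition level reports mean +/- SD over replicate means (n =
    replicates, not FOVs).  SD is reported as ``None`` for a single
    replicate.
    """
    per_rep: dict = {}
    for summary in fov_summaries:
        fov = summary.get("fov")
        if fov not in fov_to_replicate:
            raise ConfigurationError(f"FOV {fov!r} has no replicate mapping")
        per_rep.setdefault(fov_to_replicate[fov], []).append(summary)

    metrics = ("n_detections", "hull_area_nm2", "density_per_nm2")
    replicate_rows = []
    for rep, summaries in sorted(per_rep.items()):
        pooled = pd.concat([s["per_cluster"] for s in summaries], ignore_index=True)
        row = {"replicate": rep, "n_fovs": len(summaries),
               "n_clusters": int(sum(s["n_clusters"] for s in summaries))}
        for m in metrics:
            valid = pooled[m].dropna()
            row[f"{m}_mean"] = float(valid.mean()) if len(valid) else np.nan
        row["clusters_per_um2_mean"] = float(
            np.mean([s["clusters_per_um2"] for s in summaries])
        )
        replicate_rows.append(row)
    per_replicate = pd.DataFrame(replicate_rows)

    condition: dict = {"n_replicates": len(replicate_rows)}
    for col in ("n_detections_mean", "hull_area_nm2_mean",
                "density_per_nm2_mean", "clusters_per_um2_mean"):
        values = per_replicate[col].to_numpy(dtype=float)
        condition[col.replace("_mean", "")] = {
            "mean": float(np.nanmean(values)),
            "sd": float(np.nanstd(values, ddof=1)) if len(values) > 1 else None,
        }
    return {"per_replicate": per_replicate, "condition": condition}


def read_localizations(path) -> LocalizationTable:
    """Read a delimited localization table with columns ``x_nm,y_nm,photons``.

    Extra columns are ignored; an optional ``frame`` column is carried
    through.
    """
    df = pd.read_csv(path)
    missing = {"x_nm", "y_nm", "photons"} - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"localization file missing columns {sorted(missing)}"
        )
    frame = df["frame"].to_numpy() if "frame" in df.columns else None
    return LocalizationTable(
        x=df["x_nm"].to_numpy(), y=df["y_nm"].to_numpy(),
        photons=df["photons"].to_numpy(), frame=frame,
    )
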