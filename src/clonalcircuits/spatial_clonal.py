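"""Spatial statistics of labelled interneuron point patterns.

Implements the nearest-neighbour-distance (NND) cumulative distribution
(within-label and cross-label variants), intra- versus interclonal pairwise
Euclidean distances, the same-barcode fraction within a distance range, and
single-linkage hierarchical dendrograms with Newick export.  All distances
are 3-D Euclidean (straight-line) in micrometres; 2-D inputs are accepted
with z = 0.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .simcircuit import CloneSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nearest-neighbour distances
# ---------------------------------------------------------------------------


@dataclass
class NndResult:
    """Per-cell nearest-neighbour distances under a stated class rule."""

    distances_um: np.ndarray      # d_i, one per eligible cell
    class_rule: str               # 'within-label' | 'cross-label' | 'all'
    n_excluded: int = 0           # cells with no eligible neighbour

    def cdf(self, d) -> np.ndarray:
        """Empirical CDF F(d) = mean_i f(d_i, d), f the indicator d_i <= d."""
        d = np.atleast_1d(np.asarray(d, dtype=float))
        di = np.sort(self.distances_um)
        return np.searchsorted(di, d, side="right") / di.size

    def cdf_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted distances and the CDF evaluated at them (CSV-ready)."""
        d = np.sort(self.distances_um)
        return d, np.arange(1, d.size + 1) / d.size


def _nearest_to(points: np.ndarray, targets: np.ndarray, self_query: bool):
    tree = cKDTree(targets)
    k = 2 if self_query else 1
    dist, _ = tree.query(points, k=k)
    return dist[:, -1] if self_query else np.atleast_1d(dist)


def nnd(cloneset: CloneSet, class_rule: str = "all") -> NndResult:
    """Nearest-neighbour distance of each cell under ``class_rule``.

    * ``'all'``: nearest other cell, regardless of label.
    * ``'within-label'``: nearest other cell sharing the fluorophore label.
    * ``'cross-label'``: for every cell, the nearest cell of the other label
      (both directions pooled into one sample).

    Cells without an eligible neighbour are excluded and counted.
    """
    pts = cloneset.points_um
    labels = cloneset.fluor_labels
    if class_rule == "all":
        if len(pts) < 2:
            raise ValidationError("need at least 2 points for NND")
        return NndResult(_nearest_to(pts, pts, True), class_rule)
    if class_rule == "within-label":
        dists, excluded = [], 0
        for lab in np.unique(labels):
            sub = pts[labels == lab]
            if len(sub) < 2:
                excluded += len(sub)
                continue
            dists.append(_nearest_to(sub, sub, True))
        if not dists:
            raise ValidationError("no label class has >= 2 points")
        if excluded:
            logger.info("nnd(within-label): excluded %d singleton-label cells", excluded)
        return NndResult(np.concatenate(dists), class_rule, excluded)
    if class_rule == "cross-label":
        labs = np.unique(labels)
        if len(labs) < 2:
            raise ValidationError("cross-label NND needs >= 2 label classes")
        dists, excluded = [], 0
        for lab in labs:
            own = pts[labels == lab]
            other = pts[labels != lab]
            if len(other) == 0:
                excluded += len(own)
                continue
            dists.append(_nearest_to(own, other, False))
        if excluded:
            logger.info("nnd(cross-label): excluded %d cells", excluded)
        return NndResult(np.concatenate(dists), class_rule, excluded)
    raise ValidationError(f"unknown class rule: {class_rule!r}")


def poisson_nnd_cdf(d, intensity_per_um3: float) -> np.ndarray:
    """Analytic 3-D Poisson NND law: F(d) = 1 - exp(-(4/3) pi lambda d^3)."""
    d = np.asarray(d, dtype=float)
    return 1.0 - np.exp(-(4.0 / 3.0) * np.pi * intensity_per_um3 * d**3)


# ---------------------------------------------------------------------------
# Intra- vs interclonal distances
# ---------------------------------------------------------------------------


@dataclass
class ClonalDistanceResult:
    intra_um: np.ndarray   # all sibling pairs in multi-cell clones
    inter_um: np.ndarray   # all non-sibling pairs
    per_clone: dict = field(default_factory=dict)  # clone id -> (size, mean intra)


def clonal_distances(cloneset: CloneSet) -> ClonalDistanceResult:
    """Pairwise Euclidean distances split into sibling and non-sibling pairs.

    Single-cell clones contribute only to the interclonal list.  With no
    multi-cell clone the intraclonal list is empty and a warning is issued.
    """
    n = len(cloneset)
    if n < 2:
        raise ValidationError("need at least 2 cells for pairwise distances")
    dm = squareform(pdist(cloneset.points_um))
    ids = cloneset.clone_ids
    iu, ju = np.triu_indices(n, k=1)
    same = ids[iu] == ids[ju]
    intra = dm[iu[same], ju[same]]
    inter = dm[iu[~same], ju[~same]]
    per_clone = {}
    for cid in np.unique(ids):
        mask = ids == cid
        size = int(mask.sum())
        if size >= 2:
            sub = dm[np.ix_(mask, mask)]
            vals = sub[np.triu_indices(size, k=1)]
            per_clone[cid] = (size, float(np.mean(vals)))
        else:
            per_clone[cid] = (size, np.nan)
    if intra.size == 0:
        warnings.warn("no multi-cell clone: intraclonal distance list is empty")
    return ClonalDistanceResult(intra_um=intra, inter_um=inter, per_clone=per_clone)


def same_barcode_fraction(
    cloneset: CloneSet, max_dist_um: float
) -> tuple[Optional[float], int]:
    """Fraction of unordered pairs within ``max_dist_um`` sharing a clone id.

    Returns ``(fraction, n_pairs)``; the fraction is ``None`` when no pair
    qualifies (undefined).
    """
    if max_dist_um < 0:
        raise ValidationError("max_dist_um must be non-negative")
    n = len(cloneset)
    if n < 2:
        return None, 0
    d = pdist(cloneset.points_um)
    ids = cloneset.clone_ids
    iu, ju = np.triu_indices(n, k=1)
    close = d <= max_dist_um
    n_pairs = int(close.sum())
    if n_pairs == 0:
        return None, 0
    same = ids[iu[close]] == ids[ju[close]]
    return float(np.mean(same)), n_pairs


# ---------------------------------------------------------------------------
# Dendrograms
# ---------------------------------------------------------------------------


def linkage_dendrogram(cloneset: CloneSet, method: str = "single") -> np.ndarray:
    """Agglomerative binary cluster tree on Euclidean distances.

    Returns the standard (n-1, 4) linkage matrix (merged ids, merge height,
    cluster size).  ``method`` is 'single' (default) or 'average'.
    """
    if method not in ("single", "average"):
        raise ValidationError("linkage method must be 'single' or 'average'")
    if len(cloneset) < 2:
        raise ValidationError("need at least 2 points for a dendrogram")
    return linkage(cloneset.points_um, method=method)


def linkage_to_newick(Z: np.ndarray, leaf_names: Optional[list] = None) -> str:
    """Newick string with branch lengths equal to merge-height differences."""
    n = Z.shape[0] + 1
    if leaf_names is None:
        leaf_names = [str(i) for i in range(n)]
    if len(leaf_names) != n:
        raise ValidationError("leaf_names must match the number of leaves")
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaf_names[i]) for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        nid = n + k
        node[nid] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
        height[nid] = h
    return node[n + Z.shape[0] - 1] + ";"


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CLONESET_COLUMNS = ["x_um", "y_um", "z_um", "clone_id", "label", "region"]


def write_cloneset_csv(cloneset: CloneSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CLONESET_COLUMNS)
        for p, cid, lab in zip(
            cloneset.points_um, cloneset.clone_ids, cloneset.fluor_labels
        ):
            w.writerow(
                [
                    repr(float(p[0])),
                    repr(float(p[1])),
                    repr(float(p[2])),
                    cid,
                    lab,
                    cloneset.region or "",
                ]
            )


def read_cloneset_csv(path) -> CloneSet:
    pts, cids, labs, regions = [], [], [], set()
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames is None or not set(CLONESET_COLUMNS[:5]) <= set(r.fieldnames):
            raise ValidationError(
                f"clone-set CSV must have columns {CLONESET_COLUMNS[:5]}"
            )
        for row in r:
            pts.append([float(row["x_um"]), float(row["y_um"]), float(row["z_um"])])
            cids.append(row["clone_id"])
            labs.append(row["label"])
            if row.get("region"):
                regions.add(row["region"])
    region = regions.pop() if len(regions) == 1 else None
    return CloneSet(
        points_um=np.asarray(pts, dtype=float).reshape(-1, 3),
        clone_ids=np.asarray(cids),
        fluor_labels=np.asarray(labs),
        region=region,
    )


def read_barcoded_csv(path, column_map: Optional[dict] = None) -> CloneSet:
    """Ingest an external barcoded dataset CSV with columns
    (x, y, z, barcode, region), optionally renamed via ``column_map``
    (external name -> canonical name)."""
    canonical = ("x", "y", "z", "barcode", "region")
    column_map = column_map or {}
    pts, cids, regions = [], [], []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames is None:
            raise ValidationError("empty barcoded CSV")
        rename = {src: dst for src, dst in column_map.items()}
        cols = [rename.get(c, c) for c in r.fieldnames]
        missing = [c for c in canonical[:4] if c not in cols]
        if missing:
            raise ValidationError(f"barcoded CSV missing columns: {missing}")
        for raw in r:
            row = {rename.get(k, k): v for k, v in raw.items()}
            pts.append([float(row["x"]), float(row["y"]), float(row.get("z") or 0.0)])
            cids.append(row["barcode"])
            regions.append(row.get("region", ""))
    region_vals = {x for x in regions if x}
    return CloneSet(
        points_um=np.asarray(pts, dtype=float).reshape(-1, 3),
        clone_ids=np.asarray(cids),
        fluor_labels=np.asarray(["barcoded"] * len(cids)),
        region=region_vals.pop() if len(region_vals) == 1 else None,
    )


def write_cdf_csv(result: NndResult, path) -> None:
    d, F = result.cdf_table()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["d_um", "F"])
        for a, b in zip(d, F):
            w.writerow([repr(float(a)), repr(float(b))])
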