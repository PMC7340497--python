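"""DBSCAN nanodomain ("hotspot") analysis of localization tables.

Hotspots are regions of elevated localization density in sptPALM/PALM
data, detected with DBSCAN: core points have at least ``min_density``
neighbors within ``eps``; clusters are density-connected components, and
clusters with fewer than ``min_locs_per_hotspot`` members are discarded
(the default of 18 guarantees a hotspot holds more than one short track,
most tracks having ~10 localizations).

Defaults follow the sptPALM analysis (eps = 80 nm, minPts = 20, ≥ 18
localizations); ``PALM_PARAMS`` carries the whole-cell PALM setting
(eps = 100 nm, ≥ 10 localizations per cluster).

Hotspot footprints are convex hulls of the member localizations; a
diffraction-limited projection of the localization stack (Gaussian
rendering + quantile threshold) supports mask-level Pearson / Mander's
overlap between channels, and tracks are associated to hotspots by
point-in-polygon membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from ._utils import NM_PER_UM
from .dynamics import MotilityClassifier, TrackSet

__all__ = [
    "HotspotParams",
    "PALM_PARAMS",
    "Hotspot",
    "OverlapResult",
    "HotspotDetector",
    "dbscan_hotspots",
    "hotspot_metrics",
    "render_projection",
    "mask_overlap",
    "associate_tracks",
]


@dataclass(frozen=True)
class HotspotParams:
    """DBSCAN parameters for hotspot detection."""

    eps: float = 80.0                 # nm
    min_density: int = 20             # DBSCAN minPts within eps
    min_locs_per_hotspot: int = 18

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_locs_per_hotspot < 2:
            raise ValueError("min_locs_per_hotspot must be >= 2")


#: Whole-cell PALM cluster setting.
PALM_PARAMS = HotspotParams(eps=100.0, min_density=10, min_locs_per_hotspot=10)


@dataclass
class Hotspot:
    """One density-connected cluster of localizations."""

    member_indices: np.ndarray    # indices into the input table
    points: np.ndarray            # (n, 2) nm
    centroid: np.ndarray          # (2,) nm
    polygon: object | None        # shapely Polygon (convex hull), None if degenerate
    area_um2: float               # NaN if degenerate (collinear/too few points)
    n_locs: int
    n_tracks: int = 0

    @property
    def density_per_um2(self) -> float:
        return self.n_locs / self.area_um2 if self.area_um2 > 0 else np.nan


@dataclass
class OverlapResult:
    """Pixel-level overlap between two hotspot masks."""

    pearson: float
    manders_m1: float   # |A∩B| / |A|
    manders_m2: float   # |A∩B| / |B|


def _table_points(locs) -> np.ndarray:
    if isinstance(locs, pd.DataFrame):
        return locs[["x", "y"]].to_numpy(dtype=float)
    return np.asarray(locs, dtype=float).reshape(-1, 2)


class HotspotDetector(ClusterMixin, BaseEstimator):
    """DBSCAN hotspot clustering of a localization table.

    sklearn-style clusterer: ``fit`` assigns ``labels_`` (−1 = noise, as in
    :class:`sklearn.cluster.DBSCAN`) and builds ``hotspots_``, the list of
    :class:`Hotspot` objects passing the minimum-size filter. Input points
    are sorted lexicographically before clustering so border points
    reachable from several clusters resolve deterministically regardless
    of input order.
    """

    def __init__(self, eps: float = 80.0, min_density: int = 20,
                 min_locs_per_hotspot: int = 18):
        self.eps = eps
        self.min_density = min_density
        self.min_locs_per_hotspot = min_locs_per_hotspot

    def fit(self, locs, y=None):
        pts = _table_points(locs)
        n = pts.shape[0]
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        inv = np.empty(n, dtype=int)
        inv[order] = np.arange(n)
        labels_sorted = (
            DBSCAN(eps=self.eps, min_samples=self.min_density).fit(pts[order]).labels_
            if n
            else np.empty(0, dtype=int)
        )
        labels = labels_sorted[inv]

        hotspots = []
        keep_map = {}
        for lab in np.unique(labels):
            if lab < 0:
                continue
            idx = np.flatnonzero(labels == lab)
            if idx.size < self.min_locs_per_hotspot:
                labels[idx] = -1
                continue
            member_pts = pts[idx]
            hull = MultiPoint(member_pts).convex_hull
            poly = hull if hull.geom_type == "Polygon" else None
            area = hull.area / NM_PER_UM**2 if poly is not None else np.nan
            keep_map[lab] = len(hotspots)
            hotspots.append(
                Hotspot(
                    member_indices=idx,
                    points=member_pts,
                    centroid=member_pts.mean(axis=0),
                    polygon=poly,
                    area_um2=float(area),
                    n_locs=int(idx.size),
                )
            )
        # compact labels to 0..k-1 in hotspot order
        self.labels_ = np.array([keep_map.get(l, -1) for l in labels], dtype=int)
        self.hotspots_ = hotspots
        self.n_clusters_ = len(hotspots)
        return self


def dbscan_hotspots(locs, params: HotspotParams | None = None) -> list[Hotspot]:
    """Detect hotspots in a localization table; see :class:`HotspotDetector`."""
    p = params or HotspotParams()
    det = HotspotDetector(
        eps=p.eps, min_density=p.min_density,
        min_locs_per_hotspot=p.min_locs_per_hotspot,
    ).fit(locs)
    return det.hotspots_


def hotspot_metrics(h: Hotspot) -> dict:
    """Area (µm², convex hull), localization count, and density of one hotspot.

    Degenerate clusters (collinear or < 3 distinct points) have no polygon;
    their area and density are reported missing (NaN).
    """
    return {
        "area_um2": h.area_um2,
        "n_locs": h.n_locs,
        "density_per_um2": h.density_per_um2,
        "centroid_x": float(h.centroid[0]),
        "centroid_y": float(h.centroid[1]),
    }


# ---------------------------------------------------------------------------
# Diffraction-limited projection and mask overlap
# ---------------------------------------------------------------------------

def render_projection(
    locs,
    pixel_size: float = 100.0,
    psf_sigma: float = 200.0 / 2.35,
    threshold_quantile: float = 0.99,
    shape: tuple[int, int] | None = None,
    return_image: bool = False,
):
    """Render localizations as a diffraction-limited image and threshold it.

    Localizations are binned onto a ``pixel_size`` (nm) grid, blurred with
    a Gaussian of ``psf_sigma`` (nm; default a 200 nm FWHM), and
    thresholded at the ``threshold_quantile`` of pixel intensities to give
    a binary hotspot mask. An empty table yields an all-background mask.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    pts = _table_points(locs)
    if shape is None:
        if pts.shape[0] == 0:
            shape = (1, 1)
        else:
            shape = (
                int(np.floor(pts[:, 1].max() / pixel_size)) + 1,
                int(np.floor(pts[:, 0].max() / pixel_size)) + 1,
            )
    img = np.zeros(shape, dtype=float)
    if pts.shape[0]:
        cols = np.clip((pts[:, 0] // pixel_size).astype(int), 0, shape[1] - 1)
        rows = np.clip((pts[:, 1] // pixel_size).astype(int), 0, shape[0] - 1)
        np.add.at(img, (rows, cols), 1.0)
        img = gaussian_filter(img, sigma=psf_sigma / pixel_size)
    if img.max() <= 0:
        mask = np.zeros(shape, dtype=bool)
    else:
        thr = np.quantile(img, threshold_quantile)
        thr = min(thr, img.max() * (1 - 1e-9))  # keep at least the peak pixels
        mask = img > thr
    return (mask, img) if return_image else mask


def mask_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> OverlapResult:
    """Pearson and Mander's overlap between two same-geometry masks.

    Pearson correlates pixel values (works for binary or intensity
    images); Mander's M1/M2 are intersection fractions of the binarized
    masks. An empty mask leaves its Mander's direction undefined (NaN).
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share geometry")
    af = a.astype(float).ravel()
    bf = b.astype(float).ravel()
    if af.std() == 0 or bf.std() == 0:
        pearson = np.nan
    else:
        pearson = float(np.corrcoef(af, bf)[0, 1])
    ab_ = a.astype(bool)
    bb_ = b.astype(bool)
    inter = float(np.logical_and(ab_, bb_).sum())
    m1 = inter / ab_.sum() if ab_.any() else np.nan
    m2 = inter / bb_.sum() if bb_.any() else np.nan
    return OverlapResult(pearson=pearson, manders_m1=float(m1), manders_m2=float(m2))


# ---------------------------------------------------------------------------
# Track association
# ---------------------------------------------------------------------------

def associate_tracks(
    tracks: TrackSet,
    hotspots: list[Hotspot],
    d_immobile: float = 0.01,
) -> dict:
    """Associate trajectories with hotspot footprints.

    A track *visits* a hotspot when at least one of its localizations lies
    inside (or on) the hotspot's footprint polygon; a track passing through
    counts once per hotspot regardless of how many interior points it has.
    Returns per-hotspot visit counts, the fraction of hotspots visited by
    ≥ 1 track, and the diffusion coefficients of visiting vs non-visiting
    tracks (first-four-MSD-points estimator).
    """
    n_h = len(hotspots)
    visits = np.zeros(n_h, dtype=int)
    visiting_ids: list[set] = [set() for _ in range(n_h)]
    track_visits = {}
    for tr in tracks:
        inside_any = False
        for hi, h in enumerate(hotspots):
            if h.polygon is None:
                continue
            minx, miny, maxx, maxy = h.polygon.bounds
            p = tr.positions
            box = (
                (p[:, 0] >= minx) & (p[:, 0] <= maxx)
                & (p[:, 1] >= miny) & (p[:, 1] <= maxy)
            )
            hit = any(
                h.polygon.covers(Point(xy)) for xy in p[box]
            ) if box.any() else False
            if hit:
                visits[hi] += 1
                visiting_ids[hi].add(tr.track_id)
                inside_any = True
        track_visits[tr.track_id] = inside_any

    for hi, h in enumerate(hotspots):
        h.n_tracks = int(visits[hi])

    # D statistics of visiting vs outside tracks
    usable = [tr for tr in tracks if len(tr) >= 5]
    d_in, d_out = [], []
    if usable:
        clf = MotilityClassifier().fit(TrackSet(tracks=usable))
        for _, row in clf.results_.iterrows():
            (d_in if track_visits.get(row["track_id"]) else d_out).append(row["d_coef"])
    return {
        "per_hotspot_track_count": visits,
        "fraction_hotspots_visited": float(np.mean(visits > 0)) if n_h else np.nan,
        "visiting_d": np.asarray(d_in),
        "non_visiting_d": np.asarray(d_out),
        "visiting_d_mean": float(np.mean(d_in)) if d_in else np.nan,
        "non_visiting_d_mean": float(np.mean(d_out)) if d_out else np.nan,
    }
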