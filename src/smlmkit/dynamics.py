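"""Per-track MSD analysis and motility classification for sptPALM data.

For each reconnected trajectory the time-averaged mean squared displacement
(MSD) is computed over all overlapping point pairs at each lag. Two fits
summarize each track:

* the instantaneous diffusion coefficient ``D`` from an ordinary
  least-squares line through the first four MSD points, ``D = slope/4``
  (2-D diffusion);
* the anomaly exponent ``α`` from a nonlinear fit ``MSD(t) = Γ·t^α + k``
  with Γ > 0, k ≥ 0, α ∈ (0, 2]. The offset ``k`` absorbs the static
  localization-error floor (≈ 4σ_loc² for i.i.d. error of scale σ_loc).

Tracks with ``D ≤ 0.01 µm²/s`` are classified immobile (they stay within
the ~50 nm resolution footprint of the instrument); mobile tracks are
assigned a motility class from α: confined (α < 0.1), anomalous
(0.1 ≤ α < 0.9), Brownian (0.9 ≤ α ≤ 1.1), directed (α > 1.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from ._utils import NM_PER_UM

__all__ = [
    "Track",
    "TrackSet",
    "MSDCurve",
    "MSDFit",
    "MotilityThresholds",
    "MotilityClassifier",
    "compute_msd",
    "fit_diffusion_coefficient",
    "fit_alpha",
    "classify_motility",
    "mobility_summary",
    "region_mobility_ratio",
    "ensemble_msd",
]


@dataclass
class Track:
    """One reconnected trajectory: frame indices and positions in nm."""

    track_id: str
    frames: np.ndarray       # strictly increasing ints; gaps allowed
    positions: np.ndarray    # (n, 2) nm
    frame_interval: float    # s
    roi_label: str = "unassigned"   # "edge" | "inner" | "unassigned"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int).ravel()
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.frames.size != self.positions.shape[0]:
            raise ValueError("frames and positions disagree in length")
        if (np.diff(self.frames) <= 0).any():
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def has_gaps(self) -> bool:
        return bool((np.diff(self.frames) > 1).any())


@dataclass
class TrackSet:
    """A collection of tracks sharing one frame interval."""

    tracks: list[Track] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i):
        return self.tracks[i]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track."""

    lags: np.ndarray      # s, positive increasing
    msd: np.ndarray       # µm²
    n_pairs: np.ndarray   # displacement pairs contributing to each lag


@dataclass
class MSDFit:
    """Power-law MSD fit MSD(t) = Γ·t^α + k."""

    d_coef: float          # µm²/s, first-four-points estimator
    alpha: float
    amplitude: float       # Γ, µm²/s^α
    offset: float          # k, µm²
    converged: bool = True
    d_floored: bool = False
    n_lags_alpha: int = 0


@dataclass(frozen=True)
class MotilityThresholds:
    """Classification cut-offs.

    ``d_immobile`` is inclusive: D ≤ d_immobile → immobile. α intervals are
    half-open at the confined/anomalous and anomalous/Brownian boundaries
    and closed at 1.1 so the partition is exhaustive and non-overlapping.
    """

    d_immobile: float = 0.01      # µm²/s
    confined_max: float = 0.1
    anomalous_max: float = 0.9
    brownian_max: float = 1.1


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def compute_msd(track: Track, max_lag_fraction: float = 1.0) -> MSDCurve:
    """Time-averaged MSD over all overlapping point pairs at each lag.

    Lags run from one frame up to ``max_lag_fraction`` of the track's frame
    span. Displacements spanning frame gaps simply do not contribute to the
    intermediate lag bins (the frame-indexed difference handles this
    naturally). Positions are converted nm → µm so MSD is in µm².
    """
    if len(track) < 5:
        raise ValueError("track must have >= 5 points for MSD analysis")
    span = int(track.frames[-1] - track.frames[0])
    max_lag = max(int(np.floor(max_lag_fraction * span)), 1)
    if max_lag < 1:
        raise ValueError("max_lag_fraction leaves no usable lag")

    # frame-indexed position array with NaN at missing frames
    grid = np.full((span + 1, 2), np.nan)
    grid[track.frames - track.frames[0]] = track.positions / NM_PER_UM

    lags, msd, n_pairs = [], [], []
    for lag in range(1, max_lag + 1):
        d = grid[lag:] - grid[:-lag]
        sq = np.einsum("ij,ij->i", d, d)
        valid = ~np.isnan(sq)
        n = int(valid.sum())
        if n == 0:
            continue
        lags.append(lag * track.frame_interval)
        msd.append(float(sq[valid].mean()))
        n_pairs.append(n)
    return MSDCurve(np.asarray(lags), np.asarray(msd), np.asarray(n_pairs, dtype=int))


def ensemble_msd(tracks: TrackSet, max_lag_fraction: float = 1.0) -> MSDCurve:
    """Pair-weighted average of per-track MSDs on the common lag grid."""
    acc: dict[float, list[float]] = {}
    for tr in tracks:
        if len(tr) < 5:
            continue
        c = compute_msd(tr, max_lag_fraction)
        for lag, m, n in zip(c.lags, c.msd, c.n_pairs):
            acc.setdefault(round(float(lag), 9), []).append((m, n))
    lags = np.array(sorted(acc))
    msd = np.array(
        [np.average([m for m, _ in acc[l]], weights=[n for _, n in acc[l]]) for l in lags]
    )
    n_pairs = np.array([sum(n for _, n in acc[l]) for l in lags], dtype=int)
    return MSDCurve(lags, msd, n_pairs)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

def fit_diffusion_coefficient(msd: MSDCurve, n_points: int = 4) -> tuple[float, bool]:
    """Instantaneous D from an OLS line through the first ``n_points`` MSD lags.

    Returns ``(D, floored)``; a negative slope is floored at D = 0 with the
    flag set. The intercept is free, absorbing the localization-error
    offset. The first four *nonzero* lags are used (no (0, 0) anchor).
    """
    if msd.lags.size < n_points:
        raise ValueError(f"need >= {n_points} MSD lags")
    t = msd.lags[:n_points]
    y = msd.msd[:n_points]
    if np.allclose(y, y[0]):
        return 0.0, True
    slope = float(np.polyfit(t, y, 1)[0])
    if slope < 0:
        return 0.0, True
    return slope / 4.0, False


def _alpha_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Log-log slope initialization after offset subtraction."""
    k0 = max(2.0 * y[0] - y[1], 0.0)  # linear extrapolation to t = 0
    yy = np.clip(y - k0, 1e-12 * max(y.max(), 1e-30), None)
    coef = np.polyfit(np.log(t), np.log(yy), 1)
    a0 = float(np.clip(coef[0], 0.05, 2.0))
    g0 = float(np.exp(coef[1]))
    return g0, a0, k0


def fit_alpha(msd: MSDCurve, fit_fraction: float = 0.5, min_lags: int = 5) -> MSDFit:
    """Fit MSD(t) = Γ·t^α + k over the first ``fit_fraction`` of lags.

    Bounded nonlinear least squares (Γ > 0, k ≥ 0, 0 < α ≤ 2), initialized
    from a log-log slope after offset subtraction, with two fallback
    restarts. Long-lag MSD points are noisy on short tracks, hence the
    default restriction to the first half of available lags; residuals are
    inverse-variance weighted using the time-averaged-MSD error structure
    (standard deviation growing as MSD·√lag), which keeps the ensemble
    mean of per-track α estimates close to the generating exponent.
    """
    n_fit = max(int(np.ceil(fit_fraction * msd.lags.size)), min_lags)
    n_fit = min(n_fit, msd.lags.size)
    if n_fit < min_lags:
        raise ValueError(f"need >= {min_lags} lags in fit range")
    t = msd.lags[:n_fit]
    y = msd.msd[:n_fit]
    d_coef, floored = fit_diffusion_coefficient(msd) if msd.lags.size >= 4 else (np.nan, False)

    if np.allclose(y, 0.0):
        return MSDFit(d_coef, np.nan, 0.0, 0.0, converged=False,
                      d_floored=floored, n_lags_alpha=n_fit)

    # TA-MSD noise grows roughly as MSD·√(lag index): weight accordingly
    w = 1.0 / (np.maximum(y, 1e-12 * y.max()) * np.sqrt(np.arange(1, t.size + 1)))
    w /= w.max()

    def resid(p):
        g, a, k = p
        return (g * t**a + k - y) * w

    starts = [_alpha_init(t, y), (y[-1] / t[-1], 1.0, 0.0), (y[-1] / t[-1] ** 0.5, 0.5, 0.0)]
    best = None
    for g0, a0, k0 in starts:
        g0 = float(np.clip(g0, 1e-12, 1e12))
        try:
            sol = least_squares(
                resid, x0=[g0, a0, max(k0, 0.0)],
                bounds=([1e-12, 1e-3, 0.0], [np.inf, 2.0, np.inf]),
                max_nfev=200,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e3:
        return MSDFit(d_coef, np.nan, np.nan, np.nan, converged=False,
                      d_floored=floored, n_lags_alpha=n_fit)
    g, a, k = best.x
    return MSDFit(d_coef, float(a), float(g), float(k), converged=True,
                  d_floored=floored, n_lags_alpha=n_fit)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_motility(fit: MSDFit, thresholds: MotilityThresholds | None = None) -> str:
    """Assign a motility class from a converged MSD fit.

    The immobile test (D ≤ threshold) runs before α is consulted, so
    immobile tracks never enter the α-based classes.
    """
    th = thresholds or MotilityThresholds()
    if fit.d_coef <= th.d_immobile:
        return "immobile"
    a = fit.alpha
    if not np.isfinite(a):
        return "unclassified"
    if a < th.confined_max:
        return "confined"
    if a < th.anomalous_max:
        return "anomalous"
    if a <= th.brownian_max:
        return "brownian"
    return "directed"


class MotilityClassifier(BaseEstimator):
    """Per-track MSD fitting and five-class motility assignment.

    sklearn-style estimator over a :class:`TrackSet` (or list of tracks):
    ``fit`` computes each track's MSD, D (first-four-points), and α
    (power-law fit); ``predict`` returns the class labels. Fitted
    attributes: ``results_`` (per-track DataFrame), ``labels_``,
    ``mobile_fraction_``, ``mean_alpha_``, ``ensemble_alpha_``.
    """

    def __init__(self, thresholds: MotilityThresholds | None = None,
                 n_points_d: int = 4, fit_fraction: float = 0.5,
                 max_lag_fraction: float = 1.0):
        self.thresholds = thresholds
        self.n_points_d = n_points_d
        self.fit_fraction = fit_fraction
        self.max_lag_fraction = max_lag_fraction

    def fit(self, tracks: TrackSet, y=None):
        th = self.thresholds or MotilityThresholds()
        rows = []
        for tr in tracks:
            if len(tr) < 5:
                continue
            curve = compute_msd(tr, self.max_lag_fraction)
            if curve.lags.size < max(self.n_points_d, 5):
                continue
            f = fit_alpha(curve, self.fit_fraction)
            d_coef, floored = fit_diffusion_coefficient(curve, self.n_points_d)
            f.d_coef, f.d_floored = d_coef, floored
            label = classify_motility(f, th) if (f.converged or d_coef <= th.d_immobile) \
                else "unclassified"
            rows.append(
                {
                    "track_id": tr.track_id,
                    "n_points": len(tr),
                    "d_coef": d_coef,
                    "alpha": f.alpha,
                    "amplitude": f.amplitude,
                    "offset": f.offset,
                    "converged": f.converged,
                    "d_floored": floored,
                    "motility_class": label,
                    "roi_label": tr.roi_label,
                }
            )
        if not rows:
            raise ValueError("no track with >= 5 points to classify")
        self.results_ = pd.DataFrame(rows)
        self.labels_ = self.results_["motility_class"].to_numpy()
        mobile = self.results_["d_coef"] > th.d_immobile
        self.mobile_fraction_ = float(mobile.mean())
        conv = self.results_["converged"] & np.isfinite(self.results_["alpha"])
        self.mean_alpha_ = float(self.results_.loc[conv, "alpha"].mean())
        ens = ensemble_msd(tracks, self.max_lag_fraction)
        self.ensemble_alpha_ = float(fit_alpha(ens, self.fit_fraction).alpha)
        self.thresholds_ = th
        return self

    def predict(self, tracks: TrackSet | None = None) -> np.ndarray:
        if tracks is not None:
            self.fit(tracks)
        return self.labels_


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def mobility_summary(tracks: TrackSet, thresholds: MotilityThresholds | None = None,
                     n_bins: int = 40) -> dict:
    """Mobile fraction, log₁₀D histogram, and per-class frequencies.

    The log₁₀D histogram marks the immobile boundary at log₁₀(0.01) = −2
    (the instrument's resolution floor); class frequencies are computed
    over mobile tracks only, as immobile tracks are excluded from the
    α-based classes.
    """
    clf = MotilityClassifier(thresholds=thresholds).fit(tracks)
    th = clf.thresholds_
    res = clf.results_
    d = res["d_coef"].to_numpy()
    log_d = np.log10(np.clip(d, 1e-6, None))
    hist, edges = np.histogram(log_d, bins=n_bins)
    mobile = res[res["d_coef"] > th.d_immobile]
    freqs = (
        mobile["motility_class"].value_counts(normalize=True).to_dict()
        if len(mobile)
        else {}
    )
    return {
        "mobile_fraction": clf.mobile_fraction_,
        "n_tracks": int(len(res)),
        "log10_d_hist": hist,
        "log10_d_edges": edges,
        "immobile_boundary_log10d": float(np.log10(th.d_immobile)),
        "class_frequencies": freqs,
        "mean_alpha": clf.mean_alpha_,
        "ensemble_alpha": clf.ensemble_alpha_,
        "results": res,
    }


def region_mobility_ratio(tracks: TrackSet, thresholds: MotilityThresholds | None = None) -> dict:
    """Mobile/immobile track-count ratio per ROI region label.

    Regions with no immobile track report ``ratio = inf`` (flagged);
    empty regions are omitted with a warning.
    """
    clf = MotilityClassifier(thresholds=thresholds).fit(tracks)
    th = clf.thresholds_
    out = {}
    for region, grp in clf.results_.groupby("roi_label"):
        n_mobile = int((grp["d_coef"] > th.d_immobile).sum())
        n_immobile = int(len(grp) - n_mobile)
        if len(grp) == 0:
            warnings.warn(f"region {region!r} has no tracks; omitted")
            continue
        ratio = n_mobile / n_immobile if n_immobile else np.inf
        out[region] = {"mobile": n_mobile, "immobile": n_immobile, "ratio": ratio}
    return out
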