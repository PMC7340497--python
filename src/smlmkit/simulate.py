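"""Synthetic single-molecule data with planted ground truth.

Generators for every input the analysis stages consume: two-channel spot
maps with a configurable pairing distance and fluorophore dark fraction,
GFP photobleaching staircases, single-molecule intensity populations built
from a unit distribution and its self-convolution, 2-D trajectories in five
motility classes, and localization tables with planted nanodomain hotspots.

Conventions
-----------
* Coordinates are nm; diffusion coefficients are µm²/s; frame intervals s.
* Every generator takes a single ``seed`` (int or ``numpy.random.Generator``)
  and derives independent sub-streams via ``numpy.random.SeedSequence``
  spawning, so one seed reproduces an entire simulated experiment
  bit-for-bit.
* Anomalous trajectories are fractional Brownian motion generated exactly
  from the fBm increment covariance (Cholesky factorization); tracks are
  short (≤ ~50 frames) so the exact route is cheap and removes any
  simulation bias from exponent-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from ._utils import (
    NM_PER_UM,
    Rect,
    as_rng,
    check_nonneg,
    check_prob_vector,
    check_unit_interval,
    split_rng,
)

MOTION_CLASSES = ("immobile", "confined", "anomalous", "brownian", "directed")

__all__ = [
    "MOTION_CLASSES",
    "SpotMapTruth",
    "TraceTruth",
    "TrackTruth",
    "HotspotTruth",
    "TrackSimParams",
    "generate_spot_map",
    "generate_bleach_traces",
    "generate_intensity_population",
    "generate_tracks",
    "generate_hotspot_localizations",
    "sample_unit_intensity",
    "lognormal_params_from_mean_cv",
]


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass
class SpotMapTruth:
    """Ground truth for a simulated two-channel spot map."""

    channel_a_points: np.ndarray  # (Na, 2) nm, all molecules incl. dark
    channel_b_points: np.ndarray  # (Nb, 2) nm, all molecules incl. dark
    pair_index: np.ndarray        # (Nb,) index into channel A, -1 = unpaired
    pairing_offsets: np.ndarray   # (Nb, 2) nm, NaN for unpaired
    dark_a: np.ndarray            # (Na,) bool
    dark_b: np.ndarray            # (Nb,) bool


@dataclass
class TraceTruth:
    """Planted step counts and bleach times for a photobleaching trace set."""

    step_counts: np.ndarray    # (n_traces,) int, true fluorophores per spot
    bleach_frames: list        # per trace: strictly increasing frame indices
    unit_step: float
    noise_sd: float


@dataclass
class TrackTruth:
    """Per-track generating parameters for a simulated track ensemble."""

    motion_class: np.ndarray       # (n,) str from MOTION_CLASSES
    diffusion_coefficient: np.ndarray  # (n,) µm²/s (generalized for fBm)
    alpha: np.ndarray              # (n,) anomaly exponent
    drift_speed: np.ndarray        # (n,) µm/s, 0 unless directed
    confinement_radius: np.ndarray  # (n,) nm, NaN unless confined
    localization_error: float      # nm
    frame_interval: float          # s


@dataclass
class HotspotTruth:
    """Planted hotspot geometry for a localization table."""

    centers: np.ndarray       # (k, 2) nm
    radii: np.ndarray         # (k,) nm  (Gaussian sigma of member scatter)
    counts: np.ndarray        # (k,) planted localization counts
    background_density: float  # per µm²
    overlapping: bool = False  # any pair of hotspots closer than sum of radii


# ---------------------------------------------------------------------------
# Two-channel spot maps (SIM-like input)
# ---------------------------------------------------------------------------

def generate_spot_map(
    density_a: float = 10.0,
    density_b: float = 10.0,
    paired_fraction: float = 1.0,
    offset_sigma: float = 20.0,
    dark_fraction: float = 0.0,
    roi: Rect = Rect(0, 0, 10_000, 10_000),
    seed=0,
):
    """Simulate two registered channels of diffraction-resolved spot centroids.

    Channel A molecules are homogeneous Poisson at ``density_a`` (spots/µm²).
    A ``paired_fraction`` of channel-B molecules sit at a randomly chosen
    A-partner position plus an isotropic Gaussian offset of scale
    ``offset_sigma`` (nm, emulating the tag-to-tag linker distance); the rest
    are independent Poisson at the density needed to reach ``density_b``.
    Every molecule in both channels is then independently deleted with
    probability ``dark_fraction`` (non-fluorescent tag) before emission.

    Returns ``(spots_a, spots_b, truth)`` where the spot sets are
    :class:`~smlmkit.colocalization.SpotSet` and *truth* records every
    molecule including dark ones.
    """
    from .colocalization import SpotSet

    check_nonneg("density_a", density_a)
    check_nonneg("density_b", density_b)
    check_unit_interval("paired_fraction", paired_fraction)
    check_nonneg("offset_sigma", offset_sigma)
    check_unit_interval("dark_fraction", dark_fraction)
    r_counts, r_pos, r_pair, r_dark = split_rng(seed, 4)

    area = roi.area_um2
    n_a = int(r_counts.poisson(density_a * area))
    n_b = int(r_counts.poisson(density_b * area))
    pts_a = np.column_stack(
        [
            r_pos.uniform(roi.x, roi.x + roi.w, n_a),
            r_pos.uniform(roi.y, roi.y + roi.h, n_a),
        ]
    )

    n_paired = int(round(paired_fraction * n_b)) if n_a > 0 else 0
    pair_index = np.full(n_b, -1, dtype=int)
    offsets = np.full((n_b, 2), np.nan)
    pts_b = np.empty((n_b, 2))
    if n_paired > 0:
        partners = (
            r_pair.permutation(n_a)[:n_paired]
            if n_paired <= n_a
            else r_pair.integers(0, n_a, n_paired)
        )
        pair_index[:n_paired] = partners
        offsets[:n_paired] = r_pair.normal(0.0, offset_sigma, (n_paired, 2))
        pts_b[:n_paired] = pts_a[partners] + offsets[:n_paired]
    if n_b - n_paired > 0:
        pts_b[n_paired:] = np.column_stack(
            [
                r_pos.uniform(roi.x, roi.x + roi.w, n_b - n_paired),
                r_pos.uniform(roi.y, roi.y + roi.h, n_b - n_paired),
            ]
        )

    dark_a = r_dark.random(n_a) < dark_fraction
    dark_b = r_dark.random(n_b) < dark_fraction
    truth = SpotMapTruth(pts_a, pts_b, pair_index, offsets, dark_a, dark_b)

    vis_b = pts_b[~dark_b]
    inside_b = roi.contains(vis_b) if len(vis_b) else np.zeros(0, bool)
    spots_a = SpotSet(points=pts_a[~dark_a], roi=roi, channel_label="A")
    spots_b = SpotSet(points=vis_b[inside_b], roi=roi, channel_label="B")
    return spots_a, spots_b, truth


# ---------------------------------------------------------------------------
# Photobleaching staircases
# ---------------------------------------------------------------------------

def generate_bleach_traces(
    n_traces: int = 100,
    step_count_weights=(0.35, 0.30, 0.20, 0.15),
    unit_step: float = 100.0,
    noise_sd: float = 10.0,
    n_frames: int = 1200,
    frame_interval: float = 0.1,
    mean_bleach_time: float = 30.0,
    seed=0,
):
    """Simulate spot-intensity traces that bleach in discrete steps.

    Each trace starts at ``k × unit_step`` with ``k`` drawn from
    ``step_count_weights`` (index 0 = one fluorophore) and loses one unit at
    each bleach event; per-fluorophore bleach times are i.i.d. exponential
    with mean ``mean_bleach_time`` (s), matching a constant-illumination
    first-order photobleaching model. Gaussian read noise of ``noise_sd`` is
    added to every frame. Default timing emulates a 2-minute movie at
    0.1 s/frame.

    Returns ``(traces, truth)``: a list of
    :class:`~smlmkit.stoichiometry.IntensityTrace` and a
    :class:`TraceTruth`.
    """
    from .stoichiometry import IntensityTrace

    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if unit_step == 0:
        raise ValueError("unit_step must be nonzero")
    weights = check_prob_vector("step_count_weights", step_count_weights)
    check_nonneg("noise_sd", noise_sd)
    r_count, r_time, r_noise = split_rng(seed, 3)

    counts = r_count.choice(np.arange(1, weights.size + 1), n_traces, p=weights)
    traces, bleach_frames = [], []
    t_end = (n_frames - 1) * frame_interval
    for i, k in enumerate(counts):
        # truncated exponential: every fluorophore bleaches within the movie,
        # so the trace ends at background and all k steps are observable
        trunc = 1.0 - np.exp(-t_end / mean_bleach_time)
        for _ in range(1000):
            u = r_time.random(int(k))
            times = -mean_bleach_time * np.log1p(-u * trunc)
            frames = np.clip(np.ceil(times / frame_interval).astype(int), 1, n_frames - 1)
            if np.unique(frames).size == k:
                break
        frames = np.sort(frames)
        level = np.full(n_frames, float(k) * unit_step)
        for j, f in enumerate(frames):
            level[f:] = (int(k) - j - 1) * unit_step
        values = level + r_noise.normal(0.0, noise_sd, n_frames)
        traces.append(
            IntensityTrace(values=values, frame_interval=frame_interval, spot_id=f"spot_{i:04d}")
        )
        bleach_frames.append(frames)
    truth = TraceTruth(counts.astype(int), bleach_frames, float(unit_step), float(noise_sd))
    return traces, truth


# ---------------------------------------------------------------------------
# Intensity populations
# ---------------------------------------------------------------------------

def lognormal_params_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """Return (mu, sigma) of a lognormal with the given mean and CV."""
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_unit_intensity(
    n: int, rng, mean: float = 100.0, cv: float = 0.35
) -> np.ndarray:
    """Draw single-fluorophore spot intensities (lognormal, EMCCD-like)."""
    mu, sigma = lognormal_params_from_mean_cv(mean, cv)
    return rng.lognormal(mu, sigma, n)


def generate_intensity_population(
    n_spots: int = 5000,
    two_unit_fraction: float = 0.5,
    unit_mean: float = 100.0,
    unit_cv: float = 0.35,
    dark_fraction: float = 0.0,
    seed=0,
):
    """Simulate background-subtracted spot intensities of 1- and 2-tag complexes.

    ``two_unit_fraction`` is the fraction of *complexes* carrying two tags
    (the rest carry one). Each tag is independently dark with probability
    ``dark_fraction``; a two-tag complex with one dark tag emits a single
    unit, and all-dark complexes are dropped. Visible spots therefore show a
    two-unit fraction of ``f_d p² / (p (1 + f_d (1 − p)))`` with
    ``p = 1 − dark_fraction`` — e.g. an all-two-tag population at 20% dark
    yields ~2/3 visibly double spots.

    Returns ``(population, truth)`` where *truth* is a dict with the planted
    and the realized (post-thinning) two-unit fractions.
    """
    from .stoichiometry import IntensityPopulation

    if n_spots < 100:
        raise ValueError("n_spots must be >= 100 (downstream fit is histogram-based)")
    check_unit_interval("two_unit_fraction", two_unit_fraction)
    check_unit_interval("dark_fraction", dark_fraction)
    if unit_mean <= 0 or unit_cv <= 0:
        raise ValueError("unit distribution must have positive support and spread")
    r_tags, r_int = split_rng(seed, 2)

    intensities = []
    n_visible_two = 0
    n_visible = 0
    # oversample complexes until n_spots visible spots are collected
    while n_visible < n_spots:
        batch = max(256, n_spots - n_visible)
        two_tag = r_tags.random(batch) < two_unit_fraction
        n_tags = np.where(two_tag, 2, 1)
        vis_tags = r_tags.binomial(n_tags, 1.0 - dark_fraction)
        vis_tags = vis_tags[vis_tags > 0][: n_spots - n_visible]
        draws = sample_unit_intensity(int(vis_tags.sum()), r_int, unit_mean, unit_cv)
        # sum unit draws within each spot
        idx = np.repeat(np.arange(vis_tags.size), vis_tags)
        intensities.append(np.bincount(idx, weights=draws, minlength=vis_tags.size))
        n_visible_two += int((vis_tags == 2).sum())
        n_visible += vis_tags.size

    values = np.concatenate(intensities)
    pop = IntensityPopulation(spot_intensities=values, epoch_label="early")
    truth = {
        "planted_two_tag_fraction": float(two_unit_fraction),
        "visible_two_unit_fraction": n_visible_two / n_visible,
        "dark_fraction": float(dark_fraction),
        "unit_mean": float(unit_mean),
        "unit_cv": float(unit_cv),
    }
    return pop, truth


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrackSimParams:
    """Per-class generating parameters for :func:`generate_tracks`.

    Defaults mirror the membrane-protein study conditions these simulations
    emulate: fast lateral diffusion at D = 0.15 µm²/s, subdiffusive exponent
    0.844, 16 nm localization precision, 0.05 s frames.
    """

    diffusion_coefficient: float = 0.15   # µm²/s (generalized µm²/s^α for fBm)
    alpha_anomalous: float = 0.844        # exponent for the anomalous class
    drift_speed: float = 0.5              # µm/s, directed class
    confinement_radius: float = 100.0     # nm, confined class (stationary RMS)
    immobile_diffusion: float = 0.0       # µm²/s residual motion of immobile spots
    localization_error: float = 16.0      # nm, i.i.d. Gaussian per coordinate
    frame_interval: float = 0.05          # s


def _fbm_increments(n_steps: int, alpha: float, d_coef: float, dt: float,
                    n_tracks: int, rng) -> np.ndarray:
    """Exact fBm increments, shape (n_tracks, n_steps, 2), in µm.

    Per-axis MSD is 2·D·t^α (so the 2-D MSD is 4·D·t^α). The increment
    autocovariance γ(k) = D·dt^α·(|k+1|^α − 2|k|^α + |k−1|^α) is assembled
    as a Toeplitz matrix and factorized — exact for the short tracks used
    here.
    """
    k = np.arange(n_steps, dtype=float)
    gamma = d_coef * dt**alpha * (
        np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha
    )
    cov = toeplitz(gamma)
    lower = cholesky(cov, lower=True)
    z = rng.standard_normal((n_steps, n_tracks * 2))
    inc = (lower @ z).T.reshape(n_tracks, 2, n_steps).transpose(0, 2, 1)
    return inc


def generate_tracks(
    n_tracks: int = 1000,
    class_weights=(0.0, 0.0, 0.0, 1.0, 0.0),
    params: TrackSimParams | None = None,
    n_frames: int = 50,
    seed=0,
):
    """Simulate 2-D single-particle trajectories in five motility classes.

    ``class_weights`` orders classes as :data:`MOTION_CLASSES`
    (immobile, confined, anomalous, brownian, directed).

    * brownian — i.i.d. Gaussian increments, variance 2·D·Δt per axis;
    * anomalous — exact fractional Brownian motion with Hurst H = α/2;
    * directed — Brownian plus constant drift ``v·Δt`` in a random direction;
    * confined — Ornstein–Uhlenbeck per axis with stationary RMS radius
      equal to ``confinement_radius`` (standard corralled-diffusion
      surrogate);
    * immobile — residual diffusion at ``immobile_diffusion`` (pure
      localization noise when 0).

    Localization error is added as i.i.d. Gaussian of scale
    ``localization_error`` to every point. Returns ``(tracks, truth)`` with
    *tracks* a :class:`~smlmkit.dynamics.TrackSet`.
    """
    from .dynamics import Track, TrackSet

    if n_frames < 5:
        raise ValueError("n_frames must be >= 5 for downstream MSD fitting")
    params = params or TrackSimParams()
    weights = check_prob_vector("class_weights", weights=class_weights)
    if weights.size != len(MOTION_CLASSES):
        raise ValueError(f"class_weights must have {len(MOTION_CLASSES)} entries")
    if not (0.0 < params.alpha_anomalous < 2.0):
        raise ValueError("alpha must lie in (0, 2)")
    for nm in ("diffusion_coefficient", "immobile_diffusion", "localization_error"):
        check_nonneg(nm, getattr(params, nm))
    if params.frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")

    dt = params.frame_interval
    n_steps = n_frames - 1
    r_class, r_motion, r_noise = split_rng(seed, 3)
    labels_idx = r_class.choice(len(MOTION_CLASSES), n_tracks, p=weights)

    d_arr = np.full(n_tracks, params.diffusion_coefficient)
    alpha_arr = np.ones(n_tracks)
    drift_arr = np.zeros(n_tracks)
    conf_arr = np.full(n_tracks, np.nan)

    disp_um = np.zeros((n_tracks, n_frames, 2))
    for ci, cname in enumerate(MOTION_CLASSES):
        sel = np.flatnonzero(labels_idx == ci)
        if sel.size == 0:
            continue
        if cname == "brownian":
            inc = r_motion.normal(
                0.0,
                np.sqrt(2 * params.diffusion_coefficient * dt),
                (sel.size, n_steps, 2),
            )
            disp_um[sel, 1:] = np.cumsum(inc, axis=1)
        elif cname == "immobile":
            d_arr[sel] = params.immobile_diffusion
            if params.immobile_diffusion > 0:
                inc = r_motion.normal(
                    0.0,
                    np.sqrt(2 * params.immobile_diffusion * dt),
                    (sel.size, n_steps, 2),
                )
                disp_um[sel, 1:] = np.cumsum(inc, axis=1)
        elif cname == "anomalous":
            alpha_arr[sel] = params.alpha_anomalous
            inc = _fbm_increments(
                n_steps, params.alpha_anomalous, params.diffusion_coefficient,
                dt, sel.size, r_motion,
            )
            disp_um[sel, 1:] = np.cumsum(inc, axis=1)
        elif cname == "directed":
            drift_arr[sel] = params.drift_speed
            inc = r_motion.normal(
                0.0,
                np.sqrt(2 * params.diffusion_coefficient * dt),
                (sel.size, n_steps, 2),
            )
            theta = r_motion.uniform(0, 2 * np.pi, sel.size)
            drift = params.drift_speed * dt * np.column_stack(
                [np.cos(theta), np.sin(theta)]
            )
            disp_um[sel, 1:] = np.cumsum(inc + drift[:, None, :], axis=1)
        elif cname == "confined":
            conf_arr[sel] = params.confinement_radius
            # OU per axis: stationary sd per axis = radius/√2 so that the
            # stationary RMS radial excursion equals the corral radius
            sd_ax = params.confinement_radius / NM_PER_UM / np.sqrt(2.0)
            tau = sd_ax**2 / params.diffusion_coefficient  # relaxation time
            rho = np.exp(-dt / tau)
            x = r_motion.normal(0.0, sd_ax, (sel.size, 2))
            x0 = x.copy()
            for step in range(1, n_frames):
                x = rho * x + r_motion.normal(
                    0.0, sd_ax * np.sqrt(1 - rho**2), (sel.size, 2)
                )
                disp_um[sel, step] = x - x0

    pos_nm = disp_um * NM_PER_UM
    pos_nm += r_noise.normal(0.0, params.localization_error, pos_nm.shape)
    # scatter track origins so tables look like a field of view
    origins = r_noise.uniform(0, 20_000, (n_tracks, 2))
    pos_nm += origins[:, None, :]

    frames = np.arange(n_frames)
    tracks = TrackSet(
        tracks=[
            Track(
                track_id=f"track_{i:05d}",
                frames=frames.copy(),
                positions=pos_nm[i],
                frame_interval=dt,
            )
            for i in range(n_tracks)
        ]
    )
    truth = TrackTruth(
        motion_class=np.array(MOTION_CLASSES, dtype=object)[labels_idx],
        diffusion_coefficient=d_arr,
        alpha=alpha_arr,
        drift_speed=drift_arr,
        confinement_radius=conf_arr,
        localization_error=float(params.localization_error),
        frame_interval=dt,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# Hotspot localization tables
# ---------------------------------------------------------------------------

def generate_hotspot_localizations(
    roi: Rect = Rect(0, 0, 5000, 5000),
    background_density: float = 1.0,
    centers=None,
    radii=50.0,
    counts=30,
    n_frames: int = 1000,
    seed=0,
) -> tuple[pd.DataFrame, HotspotTruth]:
    """Simulate a localization table with planted high-density hotspots.

    Background localizations are homogeneous Poisson at
    ``background_density`` (per µm²); each hotspot contributes ``counts``
    localizations scattered as an isotropic Gaussian of scale ``radii`` (nm)
    around its center. Frame indices are drawn uniformly so tracks can be
    overlaid. Overlapping hotspot configurations are allowed but flagged in
    the truth record.

    Returns ``(table, truth)`` with *table* a localization DataFrame
    (columns frame, x, y, intensity, uncertainty).
    """
    r_bg, r_hs, r_meta = split_rng(seed, 3)
    if centers is None:
        centers = np.array([[roi.x + roi.w / 2, roi.y + roi.h / 2]])
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    k = centers.shape[0]
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (k,)).copy()
    counts = np.broadcast_to(np.asarray(counts, dtype=int), (k,)).copy()
    if (radii <= 0).any():
        raise ValueError("hotspot radii must be > 0")
    if (~roi.contains(centers)).any():
        raise ValueError("hotspot centers must lie inside the ROI")
    check_nonneg("background_density", background_density)

    n_bg = int(r_bg.poisson(background_density * roi.area_um2))
    bg = np.column_stack(
        [r_bg.uniform(roi.x, roi.x + roi.w, n_bg), r_bg.uniform(roi.y, roi.y + roi.h, n_bg)]
    )
    parts = [bg]
    for c, r, n in zip(centers, radii, counts):
        parts.append(c + r_hs.normal(0.0, r, (int(n), 2)))
    xy = np.concatenate(parts, axis=0)
    n_total = xy.shape[0]

    table = pd.DataFrame(
        {
            "frame": np.sort(r_meta.integers(0, n_frames, n_total)),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "intensity": r_meta.gamma(5.0, 100.0, n_total),
            "uncertainty": np.abs(r_meta.normal(16.0, 3.7, n_total)),
        }
    )
    overlapping = False
    if k > 1:
        dist = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        iu = np.triu_indices(k, 1)
        overlapping = bool((dist[iu] < (radii[:, None] + radii[None, :])[iu]).any())
    truth = HotspotTruth(centers, radii, counts, float(background_density), overlapping)
    return table, truth
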