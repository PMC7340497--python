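"""MSD computation, D and alpha estimation, motility classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smlmkit import (
    MotilityClassifier,
    MotilityThresholds,
    MSDCurve,
    MSDFit,
    Track,
    TrackSet,
    classify_motility,
    compute_msd,
    ensemble_msd,
    fit_alpha,
    fit_diffusion_coefficient,
    mobility_summary,
    region_mobility_ratio,
)
from smlmkit.simulate import TrackSimParams, generate_tracks


def brute_force_msd(track: Track):
    """Exhaustive double-loop time-averaged MSD (the independent oracle)."""
    pos = track.positions / 1000.0
    frames = track.frames
    acc = {}
    n = len(frames)
    for i in range(n):
        for j in range(i + 1, n):
            lag = int(frames[j] - frames[i])
            acc.setdefault(lag, []).append(np.sum((pos[j] - pos[i]) ** 2))
    lags = sorted(acc)
    return (
        np.array([l * track.frame_interval for l in lags]),
        np.array([np.mean(acc[l]) for l in lags]),
        np.array([len(acc[l]) for l in lags]),
    )


def make_track(positions, frames=None, dt=0.05, **kw):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Track(track_id="t", frames=frames, positions=positions,
                 frame_interval=dt, **kw)


class TestComputeMSD:
    def test_ballistic_track_is_quadratic(self):
        v_um_s = 1.0  # 1 µm/s along x
        dt = 0.05
        pos = np.column_stack([v_um_s * 1000.0 * dt * np.arange(20), np.zeros(20)])
        curve = compute_msd(make_track(pos, dt=dt))
        np.testing.assert_allclose(curve.msd, (v_um_s * curve.lags) ** 2, rtol=1e-10)

    @given(st.integers(0, 500))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        pos = rng.normal(0, 200, (n, 2))
        track = make_track(pos)
        curve = compute_msd(track)
        lags, msd, n_pairs = brute_force_msd(track)
        np.testing.assert_allclose(curve.lags, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.msd, msd, rtol=1e-10)
        np.testing.assert_array_equal(curve.n_pairs, n_pairs)

    def test_gap_spanning_displacements_excluded(self):
        frames = np.array([0, 1, 2, 5, 6, 7])
        rng = np.random.default_rng(3)
        track = make_track(rng.normal(0, 100, (6, 2)), frames=frames)
        curve = compute_msd(track)
        lags, msd, n_pairs = brute_force_msd(track)
        np.testing.assert_allclose(curve.msd, msd, rtol=1e-10)
        np.testing.assert_array_equal(curve.n_pairs, n_pairs)
        # only frame-index differences with actual pairs contribute: the
        # 3-frame lag comes solely from the (2, 5) pair spanning the gap
        assert curve.n_pairs[list(curve.lags).index(3 * track.frame_interval)] == 1

    def test_npairs_decreasing_for_contiguous_tracks(self, rng):
        track = make_track(rng.normal(0, 50, (40, 2)))
        curve = compute_msd(track)
        assert (np.diff(curve.n_pairs) <= 0).all()

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(make_track(np.zeros((4, 2))))


class TestDiffusionFit:
    def test_closed_form_4dt_line(self):
        curve = MSDCurve(
            lags=np.array([0.05, 0.10, 0.15, 0.20]),
            msd=np.array([0.03, 0.06, 0.09, 0.12]),
            n_pairs=np.array([10, 9, 8, 7]),
        )
        d, floored = fit_diffusion_coefficient(curve)
        assert d == pytest.approx(0.15)
        assert not floored

    def test_constant_msd_floored_to_zero(self):
        curve = MSDCurve(np.array([0.05, 0.1, 0.15, 0.2]), np.zeros(4), np.ones(4, int))
        d, floored = fit_diffusion_coefficient(curve)
        assert d == 0.0 and floored

    def test_ensemble_recovery_within_5pct(self):
        tracks, _ = generate_tracks(
            n_tracks=600, class_weights=(0, 0, 0, 1, 0),
            params=TrackSimParams(diffusion_coefficient=0.15, localization_error=0.0),
            n_frames=50, seed=21,
        )
        d = [fit_diffusion_coefficient(compute_msd(tr))[0] for tr in tracks]
        assert np.mean(d) == pytest.approx(0.15, rel=0.05)

    def test_localization_noise_appears_as_offset(self):
        # static-error floor: MSD offset ~ 4 sigma_loc^2
        sigma_um = 0.016
        tracks, _ = generate_tracks(
            n_tracks=800, class_weights=(0, 0, 0, 1, 0),
            params=TrackSimParams(diffusion_coefficient=0.1,
                                  localization_error=16.0),
            n_frames=50, seed=22,
        )
        ens = ensemble_msd(TrackSet(tracks=list(tracks)))
        coef = np.polyfit(ens.lags[:4], ens.msd[:4], 1)
        assert coef[1] == pytest.approx(4 * sigma_um**2, rel=0.25)


class TestAlphaFit:
    def test_ballistic_msd_gives_alpha_two(self):
        t = 0.05 * np.arange(1, 21)
        curve = MSDCurve(t, (1.0 * t) ** 2, np.arange(20, 0, -1))
        fit = fit_alpha(curve)
        assert fit.alpha == pytest.approx(2.0, abs=1e-3)

    def test_exact_brownian_msd_gives_alpha_one_no_offset(self):
        t = 0.05 * np.arange(1, 21)
        curve = MSDCurve(t, 4 * 0.15 * t, np.arange(20, 0, -1))
        fit = fit_alpha(curve)
        assert fit.alpha == pytest.approx(1.0, abs=1e-3)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.6, rel=1e-3)

    def test_anomalous_ensemble_recovery(self):
        tracks, _ = generate_tracks(
            n_tracks=600, class_weights=(0, 0, 1, 0, 0),
            params=TrackSimParams(alpha_anomalous=0.844, localization_error=0.0),
            n_frames=50, seed=23,
        )
        alphas = []
        for tr in tracks:
            f = fit_alpha(compute_msd(tr))
            if f.converged:
                alphas.append(f.alpha)
        assert np.mean(alphas) == pytest.approx(0.844, abs=0.05)

    def test_all_zero_msd_flagged(self):
        curve = MSDCurve(0.05 * np.arange(1, 11), np.zeros(10), np.ones(10, int))
        assert not fit_alpha(curve).converged


class TestClassification:
    @pytest.mark.parametrize(
        "d,alpha,expected",
        [
            (0.005, 1.0, "immobile"),
            (0.01, 1.0, "immobile"),    # boundary inclusive
            (0.1, 0.05, "confined"),
            (0.1, 0.5, "anomalous"),
            (0.1, 1.0, "brownian"),
            (0.1, 0.9, "brownian"),     # boundary belongs to Brownian
            (0.1, 1.1, "brownian"),     # upper boundary inclusive
            (0.1, 1.2, "directed"),
            (0.1, 0.1, "anomalous"),    # lower anomalous boundary inclusive
        ],
    )
    def test_boundary_conventions(self, d, alpha, expected):
        fit = MSDFit(d_coef=d, alpha=alpha, amplitude=1.0, offset=0.0)
        assert classify_motility(fit) == expected

    def test_partition_exhaustive_and_exclusive(self):
        for a in np.linspace(0.001, 2.0, 200):
            label = classify_motility(MSDFit(0.1, float(a), 1.0, 0.0))
            assert label in {"confined", "anomalous", "brownian", "directed"}


class TestSummaries:
    def test_all_mobile(self):
        tracks, _ = generate_tracks(
            n_tracks=40, class_weights=(0, 0, 0, 1, 0),
            params=TrackSimParams(diffusion_coefficient=0.15), seed=30,
        )
        s = mobility_summary(tracks)
        assert s["mobile_fraction"] == 1.0
        assert s["immobile_boundary_log10d"] == pytest.approx(-2.0)

    def test_mixture_recovered_within_binomial_ci(self):
        p_mobile = 0.87
        n = 600
        tracks, truth = generate_tracks(
            n_tracks=n, class_weights=(1 - p_mobile, 0, 0, p_mobile, 0),
            params=TrackSimParams(diffusion_coefficient=0.15,
                                  immobile_diffusion=0.001),
            seed=31,
        )
        s = mobility_summary(tracks)
        ci = 1.96 * np.sqrt(p_mobile * (1 - p_mobile) / n)
        assert abs(s["mobile_fraction"] - p_mobile) < ci + 0.02

    def test_region_ratio_ordering(self):
        tracks_edge, _ = generate_tracks(
            n_tracks=60, class_weights=(0.2, 0, 0, 0.8, 0),
            params=TrackSimParams(immobile_diffusion=0.0), seed=32,
        )
        tracks_inner, _ = generate_tracks(
            n_tracks=60, class_weights=(0.5, 0, 0, 0.5, 0),
            params=TrackSimParams(immobile_diffusion=0.0), seed=33,
        )
        all_tracks = []
        for tr in tracks_edge:
            tr.roi_label = "edge"
            all_tracks.append(tr)
        for tr in tracks_inner:
            tr.roi_label = "inner"
            all_tracks.append(tr)
        ratios = region_mobility_ratio(TrackSet(tracks=all_tracks))
        assert ratios["edge"]["ratio"] > ratios["inner"]["ratio"]

    def test_all_mobile_region_flagged_infinite(self):
        tracks, _ = generate_tracks(
            n_tracks=20, class_weights=(0, 0, 0, 1, 0), seed=34
        )
        for tr in tracks:
            tr.roi_label = "edge"
        ratios = region_mobility_ratio(tracks)
        assert np.isinf(ratios["edge"]["ratio"])


class TestMotilityClassifierEstimator:
    def test_fit_exposes_per_track_table_and_labels(self):
        tracks, truth = generate_tracks(
            n_tracks=80, class_weights=(0.1, 0, 0.3, 0.5, 0.1), seed=40
        )
        clf = MotilityClassifier().fit(tracks)
        assert len(clf.results_) == 80
        assert set(clf.labels_) <= {
            "immobile", "confined", "anomalous", "brownian", "directed", "unclassified"
        }
        assert 0 <= clf.mobile_fraction_ <= 1
        assert np.isfinite(clf.mean_alpha_)
        assert clf.get_params()["n_points_d"] == 4

    def test_track_validation(self):
        with pytest.raises(ValueError):
            Track("x", np.array([0, 1, 1]), np.zeros((3, 2)), 0.05)
        with pytest.raises(ValueError):
            Track("x", np.arange(3), np.zeros((4, 2)), 0.05)
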