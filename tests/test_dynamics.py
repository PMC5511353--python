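"""Temporal filters, bleach correction, masks, tracking, enrichment, kymographs."""

import dataclasses
import itertools

import numpy as np
import pytest

from ccsquant import MovieStack, SimulationConfig, simulate_ccs_movie
from ccsquant.dynamics import (
    Kymograph,
    Track,
    TrackingParams,
    bleach_correct,
    ccs_mask,
    detect_centroids,
    enrichment_series,
    epi_tirf_ratio,
    kymograph,
    link_frame_pair,
    link_tracks,
    temporal_filter,
    track_stats,
    tracks_to_table,
)
from ccsquant.errors import ComputationError, ParameterError
from ccsquant.synthetic import simulate_internalization_movies


def movie_from(data, dt=1.0, px=100.0):
    return MovieStack(np.asarray(data, dtype=float), dt, px)


# ---------------------------------------------------------------- temporal filter
def test_temporal_filter_identity_cases(rng):
    data = rng.uniform(0, 100, (7, 8, 8))
    mv = movie_from(data)
    assert np.allclose(temporal_filter(mv, 1, "mean").data, data)
    const = movie_from(np.ones((5, 4, 4)) * 7)
    for kind in ("mean", "median"):
        assert np.allclose(temporal_filter(const, 3, kind).data, 7.0)


def test_temporal_mean_spreads_impulse():
    data = np.zeros((7, 4, 4))
    data[3, 2, 2] = 3.0
    out = temporal_filter(movie_from(data), 3, "mean")
    assert np.allclose(out.data[2:5, 2, 2], 1.0)
    assert np.allclose(out.data[[0, 1, 5, 6], 2, 2], 0.0)


def test_temporal_filter_shrinking_edges():
    data = np.arange(5, dtype=float).reshape(5, 1, 1)
    out = temporal_filter(movie_from(data), 3, "mean")
    assert out.data[0, 0, 0] == pytest.approx(0.5)  # mean of frames 0,1
    assert out.data[4, 0, 0] == pytest.approx(3.5)


def test_even_window_rejected():
    with pytest.raises(ParameterError):
        temporal_filter(movie_from(np.zeros((6, 4, 4))), 2, "mean")


# ---------------------------------------------------------------- bleach correction
def _spot_movie(decay, amp=100.0, bg=5.0, T=20):
    data = np.full((T, 32, 32), bg)
    yy, xx = np.mgrid[0:32, 0:32]
    spot = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 8.0)
    for t in range(T):
        data[t] += amp * decay(t) * spot
    return movie_from(data)


def test_bleach_correct_no_decay_is_identity():
    mv = _spot_movie(lambda t: 1.0)
    out = bleach_correct(mv)
    assert np.allclose(out.data, mv.data, rtol=1e-9)


def test_bleach_correct_flattens_exponential_decay():
    """Signal decaying as exp(-t/tau) over zero background comes back flat."""
    tau = 15.0
    mv = _spot_movie(lambda t: np.exp(-t / tau), bg=0.0)
    out = bleach_correct(mv)
    sig = out.data.mean(axis=(1, 2))
    assert np.allclose(sig, sig[0], rtol=1e-6)


def test_bleach_correct_idempotent():
    mv = _spot_movie(lambda t: np.exp(-t / 10.0))
    once = bleach_correct(mv)
    twice = bleach_correct(once)
    assert np.allclose(twice.data, once.data, rtol=1e-6)


def test_bleach_correct_rejects_constant_frame():
    mv = _spot_movie(lambda t: 1.0, T=3)
    mv.data[1] = 0.0
    with pytest.raises(ComputationError, match="frame 1"):
        bleach_correct(mv)


# ---------------------------------------------------------------- CCS masks
def test_blank_movie_gives_empty_masks():
    assert not ccs_mask(movie_from(np.zeros((4, 16, 16)))).any()


def test_mask_monotone_in_structure_intensity(quiet_movie_config):
    """Doubling structures over fixed background never unmasks planted pixels."""
    cfg = dataclasses.replace(quiet_movie_config, n_frames=4)
    movies, truth = simulate_ccs_movie(cfg, n_structures=5)
    bg = cfg.background_level
    base = movies["clathrin"]
    doubled = movie_from(bg + 2 * (base.data - bg), base.frame_interval_s, base.pixel_size_nm)
    m1 = ccs_mask(base)
    m2 = ccs_mask(doubled)
    planted = truth.footprint_masks(radius_px=1.5 * cfg.spot_sigma_px)
    assert not (m1 & planted & ~m2).any()


def test_mask_object_level_recovery_at_snr10():
    """Every planted blob detected, every mask component explained (SNR ~10)."""
    cfg = SimulationConfig(
        seed=2, n_frames=10, lifetime_mode="full", bleach_tau_s=np.inf,
        spot_amplitude=32.0, background_level=10.0, movie_step_sd_nm=0.0,
    )
    movies, truth = simulate_ccs_movie(cfg, n_structures=10)
    # the tracking workflow smooths in time before masking; do the same
    smoothed = temporal_filter(temporal_filter(movies["clathrin"], 3, "mean"), 9, "median")
    masks = ccs_mask(smoothed)
    foot = truth.footprint_masks(radius_px=1.5 * cfg.spot_sigma_px)
    from skimage.measure import label as sklabel

    recalls, precisions = [], []
    for t in range(cfg.n_frames):
        lab_truth = sklabel(foot[t], connectivity=2)
        hit = sum(
            1
            for k in range(1, lab_truth.max() + 1)
            if (masks[t] & (lab_truth == k)).sum() >= 0.5 * (lab_truth == k).sum()
        )
        recalls.append(hit / lab_truth.max())
        lab_mask = sklabel(masks[t], connectivity=2)
        if lab_mask.max():
            ok = sum(
                1 for k in range(1, lab_mask.max() + 1) if (foot[t] & (lab_mask == k)).any()
            )
            precisions.append(ok / lab_mask.max())
    assert min(recalls) >= 0.9
    assert min(precisions) >= 0.9


# ---------------------------------------------------------------- tracking
def test_single_stationary_detection_one_track():
    detections = [np.array([[500.0, 500.0]])] * 10
    tracks = link_tracks(detections, TrackingParams(300.0))
    assert len(tracks) == 1
    assert tracks[0].n_frames == 10
    assert tracks[0].net_displacement_nm == 0.0


def test_jump_beyond_limit_splits_track():
    detections = [np.array([[0.0, 0.0]]), np.array([[400.0, 0.0]])]
    tracks = link_tracks(detections, TrackingParams(300.0))
    assert len(tracks) == 2
    near = [np.array([[0.0, 0.0]]), np.array([[250.0, 0.0]])]
    assert len(link_tracks(near, TrackingParams(300.0))) == 1


def _brute_force_cost(prev, curr, b):
    n, m = len(prev), len(curr)
    best = None
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                d2 = [((prev[r] - curr[c]) ** 2).sum() for r, c in zip(rows, cols)]
                if any(d > b for d in d2):
                    continue
                cost = sum(d2) + b * ((n - k) + (m - k))
                if best is None or cost < best:
                    best = cost
    return best


def test_frame_pair_assignment_is_globally_optimal(rng):
    """LAP cost equals exhaustive enumeration on small frames."""
    b = 300.0**2
    for _ in range(20):
        prev = rng.uniform(0, 1200, (rng.integers(1, 5), 2))
        curr = rng.uniform(0, 1200, (rng.integers(1, 5), 2))
        links = link_frame_pair(prev, curr, 300.0)
        cost = sum(((prev[r] - curr[c]) ** 2).sum() for r, c in links)
        cost += b * ((len(prev) - len(links)) + (len(curr) - len(links)))
        assert cost == pytest.approx(_brute_force_cost(prev, curr, b))


def test_tracking_conserves_detections(rng):
    detections = [rng.uniform(0, 3000, (rng.integers(0, 6), 2)) for _ in range(12)]
    tracks = link_tracks(detections, TrackingParams(500.0))
    used = [d for t in tracks for d in t.detection_ids]
    assert len(used) == len(set(used)) == sum(len(d) for d in detections)


def test_generator_lifetimes_recovered_exactly():
    cfg = SimulationConfig(
        seed=3, n_frames=30, lifetime_mean_s=12.0, lifetime_mode="fixed",
        bleach_tau_s=np.inf, poisson_noise=False, read_noise_sd=0.0, movie_step_sd_nm=10.0,
    )
    movies, truth = simulate_ccs_movie(cfg, n_structures=20)
    masks = ccs_mask(movies["clathrin"])
    tracks = link_tracks(detect_centroids(movies["clathrin"], masks), TrackingParams(300.0))
    assert sorted(t.n_frames for t in tracks) == sorted(t.lifetime_frames for t in truth.tracks)


def test_track_stats_full_length_filter():
    t_full = Track(0, np.arange(10), np.zeros(10), np.zeros(10), [(f, 0) for f in range(10)])
    t_short = Track(1, np.arange(9), np.zeros(9), np.zeros(9), [(f, 1) for f in range(9)])
    stats = track_stats([t_full, t_short], 1.0, full_length_only=True, movie_T=10)
    assert list(stats.track_id) == [0]
    all_stats = track_stats([t_full, t_short], 1.0)
    assert len(all_stats) == 2
    assert tracks_to_table([t_full]).shape == (10, 4)


# ---------------------------------------------------------------- enrichment
def _recruitment_setup(fold=3.0, stim=10, noise=False):
    cfg = SimulationConfig(
        seed=4, n_frames=30, lifetime_mode="full", stim_frame=stim,
        recruitment_fold=fold, recruitment_tau_s=0.0, bleach_tau_s=np.inf,
        poisson_noise=noise, read_noise_sd=1.0 if noise else 0.0, movie_step_sd_nm=0.0,
    )
    movies, truth = simulate_ccs_movie(cfg, n_structures=8)
    return movies["receptor"], truth.footprint_masks(), stim


def test_enrichment_prestimulus_mean_exactly_one():
    signal, masks, stim = _recruitment_setup(noise=True)
    series = enrichment_series(signal, masks, stim)
    assert np.nanmean(series.values[:stim]) == pytest.approx(1.0, abs=1e-12)


def test_enrichment_recovers_recruitment_fold():
    signal, masks, stim = _recruitment_setup(fold=3.0)
    series = enrichment_series(signal, masks, stim)
    assert series.values[-1] == pytest.approx(3.0, abs=1e-6)


def test_enrichment_empty_mask_frame_is_missing():
    signal, masks, stim = _recruitment_setup()
    masks[12] = False
    with pytest.warns(UserWarning, match="frame 12"):
        series = enrichment_series(signal, masks, stim)
    assert np.isnan(series.values[12])
    assert np.isfinite(series.values[11]) and np.isfinite(series.values[13])


def test_enrichment_needs_prestimulus_frames():
    signal, masks, _ = _recruitment_setup()
    with pytest.raises(ParameterError):
        enrichment_series(signal, masks, 0)


# ---------------------------------------------------------------- kymographs
def test_kymograph_shape_and_static_column(quiet_movie_config):
    movies, truth = simulate_ccs_movie(quiet_movie_config, n_structures=3)
    tr = truth.tracks[0]
    line = ((tr.x_nm[0] - 500, tr.y_nm[0]), (tr.x_nm[0] + 500, tr.y_nm[0]))
    k = kymograph(movies["clathrin"], line)
    assert isinstance(k, Kymograph)
    assert k.data.shape[0] == quiet_movie_config.n_frames
    assert k.data.shape[1] >= 2
    # static noiseless structure: every column constant over time
    assert np.allclose(k.data, k.data[0], atol=1e-9)


def test_two_channel_kymographs_co_fluctuate():
    cfg = SimulationConfig(
        seed=8, n_frames=40, lifetime_mode="full", bleach_tau_s=20.0,
        movie_step_sd_nm=0.0, poisson_noise=False, read_noise_sd=1.0,
    )
    movies, truth = simulate_ccs_movie(cfg, n_structures=4, two_channel=True)
    tr = truth.tracks[0]
    line = ((tr.x_nm[0] - 300, tr.y_nm[0]), (tr.x_nm[0] + 300, tr.y_nm[0]))
    k1 = kymograph(movies["clathrin"], line)
    k2 = kymograph(movies["receptor"], line)
    assert k1.data.shape == k2.data.shape
    cors = [
        np.corrcoef(k1.data[:, j], k2.data[:, j])[0, 1] for j in range(k1.data.shape[1])
    ]
    assert np.median(cors) >= 0.9


def test_kymograph_outside_field_rejected():
    mv = movie_from(np.zeros((3, 16, 16)))
    with pytest.raises(ParameterError):
        kymograph(mv, ((-100, 0), (500, 0)))


# ---------------------------------------------------------------- EPI/TIRF
def test_epi_tirf_identical_movies_ratio_one(rng):
    data = rng.uniform(10, 100, (5, 16, 16))
    mv = movie_from(data)
    mask = np.ones((16, 16), dtype=bool)
    assert np.allclose(epi_tirf_ratio(mv, mv, mask), 1.0)


def test_epi_tirf_halved_tirf_doubles_ratio():
    base = np.zeros((2, 16, 16))
    base[:, 4:12, 4:12] = 100.0
    tirf = base.copy()
    tirf[1] *= 0.5
    mask = base[0] > 0
    ratio = epi_tirf_ratio(movie_from(base), movie_from(tirf), mask)
    assert ratio[1] == pytest.approx(2.0)


def test_epi_tirf_internalization_closed_form(quiet_movie_config):
    cfg = dataclasses.replace(quiet_movie_config, stim_frame=5)
    epi, tirf, mask = simulate_internalization_movies(cfg, 0.5, tau_s=5.0)
    ratio = epi_tirf_ratio(epi, tirf, mask)
    t_last = (cfg.n_frames - 1 - 5) * cfg.frame_interval_s
    expected = 1.0 / (1.0 - 0.5 * (1 - np.exp(-t_last / 5.0)))
    assert ratio[-1] == pytest.approx(expected, rel=0.05)
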