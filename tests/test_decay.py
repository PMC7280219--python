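"""Spatial binning and bi-exponential lifetime fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dermaflim.decay import (
    BiexpFit,
    DecayCube,
    component_percentages,
    fit_biexponential,
    fit_frame,
    fit_traces,
    frame_lifetime_stats,
    mean_lifetime,
    spatial_bin,
)
from dermaflim.exceptions import (
    BelowThresholdError,
    ConfigurationError,
    EmptyMapError,
    InsufficientDataError,
    UndefinedValueError,
)
from dermaflim.simulate import GroupParams, generate_decay_frame

from conftest import DT_NS, N_BINS, biexp_trace


# ----------------------------------------------------------- spatial_bin
def brute_force_window_sum(counts, n):
    h, w, t = counts.shape
    out = np.zeros_like(counts, dtype=np.int64)
    for i in range(h):
        for j in range(w):
            ys = slice(max(0, i - n), min(h, i + n + 1))
            xs = slice(max(0, j - n), min(w, j + n + 1))
            out[i, j] = counts[ys, xs].sum(axis=(0, 1))
    return out


def test_spatial_bin_identity_at_n0():
    cube = DecayCube(np.arange(2 * 3 * 8).reshape(2, 3, 8), 0.05)
    assert spatial_bin(cube, 0) is cube


def test_spatial_bin_uniform_interior_is_81c():
    """The n=4 window spans (2*4+1)^2 = 81 pixels."""
    c = 3
    cube = DecayCube(np.full((16, 16, 8), c), 0.05)
    out = spatial_bin(cube, 4)
    assert (out.counts[4:-4, 4:-4] == 81 * c).all()
    # corner pixel sees only a clipped 5x5 window
    assert out.counts[0, 0, 0] == 25 * c


def test_spatial_bin_broadcasts_single_pixel():
    counts = np.zeros((3, 3, 4), dtype=int)
    counts[1, 1] = [5, 3, 2, 1]
    out = spatial_bin(DecayCube(counts, 0.05), 1)
    assert (out.counts == counts[1, 1]).all()


def test_spatial_bin_rejects_negative_factor():
    with pytest.raises(ConfigurationError):
        spatial_bin(DecayCube(np.zeros((4, 4, 8), dtype=int), 0.05), -1)


@settings(max_examples=30, deadline=None)
@given(
    counts=arrays(
        np.int64,
        st.tuples(
            st.integers(2, 7), st.integers(2, 7), st.integers(1, 4)
        ),
        elements=st.integers(0, 50),
    ),
    n=st.integers(0, 3),
)
def test_spatial_bin_matches_window_sum_oracle(counts, n):
    """Exact integer agreement with the brute-force clipped window sum."""
    out = spatial_bin(DecayCube(counts, 0.05), n)
    assert (out.counts == brute_force_window_sum(counts, n)).all()


# ------------------------------------------------------ fit_biexponential
def test_noiseless_biexponential_recovery_within_1pct():
    trace = biexp_trace(1000, 0.3, 500, 2.5)
    fit = fit_biexponential(trace, DT_NS)
    assert fit.a1 == pytest.approx(1000, rel=0.01)
    assert fit.tau1_ns == pytest.approx(0.3, rel=0.01)
    assert fit.a2 == pytest.approx(500, rel=0.01)
    assert fit.tau2_ns == pytest.approx(2.5, rel=0.01)
    assert fit.converged


def test_single_exponential_collapses_to_one_component():
    trace = biexp_trace(1000, 1.0, 0, 5.0)
    fit = fit_biexponential(trace, DT_NS)
    p1, p2 = component_percentages(fit)
    dominant_p = max(p1, p2)
    dominant_tau = fit.tau1_ns if p1 >= p2 else fit.tau2_ns
    assert dominant_p >= 99.0
    assert dominant_tau == pytest.approx(1.0, rel=0.02)


def test_fit_is_deterministic():
    rng = np.random.default_rng(11)
    trace = rng.poisson(biexp_trace(400, 0.4, 200, 2.0))
    f1 = fit_biexponential(trace, DT_NS)
    f2 = fit_biexponential(trace, DT_NS)
    assert f1 == f2


def test_dim_trace_raises_below_threshold():
    with pytest.raises(BelowThresholdError):
        fit_biexponential(np.ones(N_BINS) * 0.1, DT_NS, min_photons=100)


def test_poisson_noisy_tau2_median_error_below_10pct():
    shape = biexp_trace(1000, 0.3, 500, 2.5)
    lam = shape / shape.sum() * 1e4
    rng = np.random.default_rng(42)
    traces = rng.poisson(lam, size=(40, N_BINS)).astype(float)
    res = fit_traces(traces, DT_NS)
    rel_err = np.abs(res["tau2_ns"] / 2.5 - 1.0)
    assert np.median(rel_err) < 0.10


def grid_search_oracle(trace, dt, n_grid=80):
    """Dense (tau1, tau2) grid with amplitudes by linear least squares."""
    t = (np.arange(trace.size) + 0.5) * dt
    taus = np.geomspace(0.05, 8.0, n_grid)
    w = 1.0 / np.maximum(trace, 1.0)
    best = (np.inf, None)
    for i, t1 in enumerate(taus):
        for t2 in taus[i + 1 :]:
            basis = np.stack([np.exp(-t / t1), np.exp(-t / t2)], axis=1)
            bw = basis * w[:, None]
            amps, *_ = np.linalg.lstsq(bw.T @ basis, bw.T @ trace, rcond=None)
            if (amps < 0).any():
                continue
            resid = trace - basis @ amps
            cost = (w * resid**2).sum()
            if cost < best[0]:
                best = (cost, (amps[0], amps[1], t1, t2))
    return best[1]


@pytest.mark.parametrize(
    "params", [(1000, 0.3, 500, 2.5), (300, 0.6, 900, 3.5)]
)
def test_fit_matches_grid_search_oracle(params):
    """Noiseless fits agree with an exhaustive grid search within its resolution."""
    a1, t1, a2, t2 = params
    trace = biexp_trace(a1, t1, a2, t2)
    fit = fit_biexponential(trace, DT_NS)
    oracle = grid_search_oracle(trace, DT_NS)
    assert oracle is not None
    # geometric grid resolution is ~6% per step; the LM fit must land
    # within one grid cell of the oracle's lifetimes
    assert fit.tau1_ns == pytest.approx(oracle[2], rel=0.08)
    assert fit.tau2_ns == pytest.approx(oracle[3], rel=0.08)


@settings(max_examples=25, deadline=None)
@given(
    a1=st.floats(100, 2000),
    a2=st.floats(100, 2000),
    tau1=st.floats(0.1, 2.0),
    ratio=st.floats(1.5, 8.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_components_always_sorted_ascending(a1, a2, tau1, ratio, seed):
    tau2 = min(tau1 * ratio, 9.5)
    rng = np.random.default_rng(seed)
    trace = rng.poisson(biexp_trace(a1, tau1, a2, tau2, n_bins=128)).astype(float)
    res = fit_traces(trace[None, :], 12.5 / 128)
    assert res["tau1_ns"][0] <= res["tau2_ns"][0]
    assert res["a1"][0] >= 0 and res["a2"][0] >= 0


# --------------------------------------------------- derived per-fit values
def _fit(a1, tau1, a2, tau2):
    return BiexpFit(a1=a1, a2=a2, tau1_ns=tau1, tau2_ns=tau2,
                    chi2_reduced=1.0, n_photons=1000)


@pytest.mark.parametrize(
    "fit, expected",
    [
        (_fit(500, 1.0, 500, 3.0), 2.0),
        (_fit(800, 0.7, 0, 0.7), 0.7),
        (_fit(1000, 0.3, 500, 2.5), 1550 / 1500),
    ],
)
def test_mean_lifetime_values(fit, expected):
    assert mean_lifetime(fit) == pytest.approx(expected)


@pytest.mark.parametrize(
    "fit, expected",
    [
        (_fit(500, 1.0, 500, 3.0), (50.0, 50.0)),
        (_fit(800, 0.7, 0, 0.7), (100.0, 0.0)),
        (_fit(1000, 0.3, 500, 2.5), (66.67, 33.33)),
    ],
)
def test_component_percentages_values(fit, expected):
    p1, p2 = component_percentages(fit)
    assert p1 == pytest.approx(expected[0], abs=0.01)
    assert p2 == pytest.approx(expected[1], abs=0.01)
    assert p1 + p2 == pytest.approx(100.0, abs=1e-9)


def test_intensity_weighted_percentages_differ():
    fit = _fit(1000, 0.3, 500, 2.5)
    p1w, p2w = component_percentages(fit, intensity_weighted=True)
    assert p2w == pytest.approx(100 * 1250 / 1550, abs=0.01)


def test_zero_amplitude_fit_raises():
    fit = _fit(0, 1.0, 0, 2.0)
    with pytest.raises(UndefinedValueError):
        mean_lifetime(fit)
    with pytest.raises(UndefinedValueError):
        component_percentages(fit)


# -------------------------------------------------------------- fit_frame
def test_uniform_frame_fits_agree_everywhere():
    trace = biexp_trace(80, 0.3, 40, 2.5, n_bins=64, dt=12.5 / 64)
    rng = np.random.default_rng(5)
    counts = rng.poisson(trace, size=(16, 16, 64))
    lt = fit_frame(DecayCube(counts, 12.5 / 64), n=2, min_photons=100)
    tau2 = lt.tau2_ns[lt.mask]
    assert tau2.std() / tau2.mean() < 0.05


def test_frame_mean_lifetimes_track_generative_values():
    params = GroupParams(group_label="control", tau1_ns=0.4, tau2_ns=2.2,
                         a2_fraction=0.4, photons_per_pixel=300)
    cube = generate_decay_frame(params, 0.0, frame_size=64, n_time_bins=128,
                                seed=7)
    lt = fit_frame(cube, n=4, min_photons=100, stride=4)
    stats = frame_lifetime_stats(lt)
    assert stats.tau2_mean_ns == pytest.approx(2.2, rel=0.05)
    assert stats.tau1_mean_ns == pytest.approx(0.4, rel=0.05)


def test_zero_count_cube_raises_empty_map():
    cube = DecayCube(np.zeros((8, 8, 32), dtype=int), 0.05)
    with pytest.raises(EmptyMapError):
        fit_frame(cube, n=1, min_photons=10)


# ---------------------------------------------------- frame_lifetime_stats
def _map_from(tau2_values, mask=None):
    n = len(tau2_values)
    from dermaflim.decay import LifetimeMap

    return LifetimeMap(
        tau1_ns=np.full((1, n), 0.3),
        tau2_ns=np.array([tau2_values]),
        a1=np.full((1, n), 100.0),
        a2=np.full((1, n), 50.0),
        mask=np.array([mask if mask is not None else [True] * n]),
        chi2_reduced=np.ones((1, n)),
    )


def test_stats_hand_example_and_population_divisor():
    stats = frame_lifetime_stats(_map_from([2.0, 4.0]))
    assert stats.tau2_mean_ns == pytest.approx(3.0)
    assert stats.tau2_std_ns == pytest.approx(1.0)  # divisor N, not N-1


def test_stats_constant_map_has_zero_std():
    stats = frame_lifetime_stats(_map_from([2.5, 2.5, 2.5]))
    assert stats.tau2_std_ns == 0.0


def test_stats_ignore_masked_outlier():
    clean = frame_lifetime_stats(_map_from([2.0, 4.0]))
    with_outlier = frame_lifetime_stats(
        _map_from([2.0, 4.0, 9.9], mask=[True, True, False])
    )
    assert with_outlier.tau2_mean_ns == clean.tau2_mean_ns
    assert with_outlier.tau2_std_ns == clean.tau2_std_ns


def test_stats_require_two_valid_pixels():
    with pytest.raises(InsufficientDataError):
        frame_lifetime_stats(_map_from([2.0, 4.0], mask=[True, False]))


def test_parameter_recovery_bias_shrinks_with_photon_budget():
    """Frame-mean tau2 bias decreases as the photon budget grows."""
    biases = []
    for photons in (50, 400, 3200):
        params = GroupParams(group_label="control", tau2_ns=2.0,
                             a2_fraction=0.35, photons_per_pixel=photons,
                             texture_amplitude=0.0, puncta_density=0.0)
        cube = generate_decay_frame(params, 0.0, frame_size=64,
                                    n_time_bins=128, seed=13)
        lt = fit_frame(cube, n=4, min_photons=50, stride=4)
        stats = frame_lifetime_stats(lt)
        biases.append(abs(stats.tau2_mean_ns - 2.0))
    assert biases[2] < biases[0]
    assert biases[2] < 0.02
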