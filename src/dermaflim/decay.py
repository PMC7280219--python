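"""Per-pixel bi-exponential lifetime fitting for TCSPC decay cubes.

The decay of two-photon autofluorescence in skin is modelled as the sum of
two exponential components,

    f(t) = a1 * exp(-t / tau1) + a2 * exp(-t / tau2),

where ``a`` is the amplitude (counts at t = 0) and ``tau`` the lifetime of a
component, with components reported in ascending lifetime order
(``tau1 <= tau2``).  Fitting is weighted least squares with Poisson weights
``1 / max(count, 1)`` and is fully deterministic: the initial guess comes
from a log-linear fit to the decay tail, and a projected Levenberg-Marquardt
loop refines it.  The solver is vectorised over pixels so whole frames fit
in seconds.

Before fitting, frames are spatially binned: each pixel's trace becomes the
sum of the traces in a ``(2n+1) x (2n+1)`` moving window (clipped at the
frame edges), which trades lateral resolution for photon statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    BelowThresholdError,
    ConfigurationError,
    EmptyMapError,
    InsufficientDataError,
    UndefinedValueError,
)

__all__ = [
    "DecayCube",
    "BiexpFit",
    "LifetimeMap",
    "FrameStats",
    "spatial_bin",
    "fit_biexponential",
    "fit_traces",
    "fit_frame",
    "mean_lifetime",
    "component_percentages",
    "frame_lifetime_stats",
]

# Fit bounds: lifetimes in nanoseconds, amplitudes in counts.
TAU_MIN_NS = 0.01
TAU_MAX_NS = 10.0
DEFAULT_MIN_PHOTONS = 100
CHI2_SENTINEL = np.inf

# Relative lifetime gap below which the two components are considered tied
# and collapsed to a single-component report.
_TIE_REL_TOL = 0.02


@dataclass(frozen=True)
class DecayCube:
    """Per-pixel photon-count decay histograms for one optical section.

    Parameters
    ----------
    counts
        Integer array of shape ``(y, x, t)`` — photon counts per time bin.
    time_bin_ns
        Width of one time bin in nanoseconds.
    depth_um
        Axial position of the section below the skin surface, micrometres.
    """

    counts: np.ndarray
    time_bin_ns: float
    depth_um: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ConfigurationError(
                f"counts must be (y, x, t); got shape {counts.shape}"
            )
        if self.time_bin_ns <= 0:
            raise ConfigurationError("time_bin_ns must be positive")
        if counts.size and counts.min() < 0:
            raise ConfigurationError("photon counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[2]

    def time_axis_ns(self) -> np.ndarray:
        """Bin-centre times in nanoseconds."""
        return (np.arange(self.n_time_bins) + 0.5) * self.time_bin_ns

    def intensity(self) -> np.ndarray:
        """Time-summed photon counts per pixel (the 2PF intensity image)."""
        return self.counts.sum(axis=2)


@dataclass(frozen=True)
class BiexpFit:
    """Result of a two-component exponential fit to one decay trace."""

    a1: float
    a2: float
    tau1_ns: float
    tau2_ns: float
    chi2_reduced: float
    n_photons: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau1_ns > self.tau2_ns:
            raise ValueError("components must be sorted: tau1_ns <= tau2_ns")


@dataclass
class LifetimeMap:
    """Per-pixel fitted lifetime parameters for one frame.

    ``mask`` is True on pixels with a valid fit; all derived statistics are
    computed over the mask only.  When the fit grid is subsampled
    (``stride > 1``) the arrays cover the sampled grid.
    """

    tau1_ns: np.ndarray
    tau2_ns: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    mask: np.ndarray
    chi2_reduced: np.ndarray
    depth_um: float = 0.0
    stride: int = 1
    mean_lifetime_ns: np.ndarray = field(init=False)
    p1_percent: np.ndarray = field(init=False)
    p2_percent: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.a1 + self.a2
        safe = np.where(total > 0, total, 1.0)
        self.mean_lifetime_ns = (
            self.a1 * self.tau1_ns + self.a2 * self.tau2_ns
        ) / safe
        self.p1_percent = 100.0 * self.a1 / safe
        self.p2_percent = 100.0 * self.a2 / safe
        self.mask = self.mask & (total > 0)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class FrameStats:
    """Frame-level summary of a lifetime map over its valid pixels."""

    tau1_mean_ns: float
    tau1_std_ns: float
    tau2_mean_ns: float
    tau2_std_ns: float
    p1_mean_percent: float
    p2_mean_percent: float
    mean_lifetime_mean_ns: float
    n_valid: int
    fraction_masked: float


def spatial_bin(cube: DecayCube, n: int) -> DecayCube:
    """Sum each pixel's decay over a ``(2n+1) x (2n+1)`` moving window.

    The window is clipped at the frame edges, so edge pixels sum over fewer
    neighbours.  ``n = 0`` is the identity.  Integer arithmetic throughout.
    """
    if n < 0:
        raise ConfigurationError(f"binning factor must be >= 0, got {n}")
    if n == 0:
        return cube
    counts = cube.counts
    h, w, t = counts.shape
    out = np.empty((h, w, t), dtype=np.int64)
    y0 = np.clip(np.arange(h) - n, 0, h)
    y1 = np.clip(np.arange(h) + n + 1, 0, h)
    x0 = np.clip(np.arange(w) - n, 0, w)
    x1 = np.clip(np.arange(w) + n + 1, 0, w)
    # Integral image per time-slice chunk keeps peak memory bounded.
    chunk = max(1, int(2**22 // max(h * w, 1)))
    for t0 in range(0, t, chunk):
        t1 = min(t, t0 + chunk)
        c = counts[:, :, t0:t1].astype(np.int64)
        integral = np.zeros((h + 1, w + 1, t1 - t0), dtype=np.int64)
        np.cumsum(c, axis=0, out=integral[1:, 1:])
        np.cumsum(integral[1:, 1:], axis=1, out=integral[1:, 1:])
        block = (
            integral[y1[:, None], x1[None, :]]
            - integral[y0[:, None], x1[None, :]]
            - integral[y1[:, None], x0[None, :]]
            + integral[y0[:, None], x0[None, :]]
        )
        out[:, :, t0:t1] = block
    return DecayCube(out, cube.time_bin_ns, cube.depth_um)


def _initial_guess(traces: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Deterministic start values, one row (a1, a2, tau1, tau2) per trace.

    The long lifetime comes from a count-weighted log-linear regression on
    the tail (last 40% of bins); the short lifetime starts at tau2 / 5 and
    the amplitudes from a weighted linear solve at those lifetimes.
    """
    n_traces, n_bins = traces.shape
    tail_start = int(round(0.6 * n_bins))
    y_tail = traces[:, tail_start:]
    t_tail = t[tail_start:]
    w = y_tail.astype(float)  # Poisson: weight log-counts by counts
    logy = np.log(np.clip(y_tail, 1e-12, None))
    wsum = np.clip(w.sum(axis=1), 1e-12, None)
    tbar = (w * t_tail).sum(axis=1) / wsum
    ybar = (w * logy).sum(axis=1) / wsum
    cov = (w * (t_tail - tbar[:, None]) * (logy - ybar[:, None])).sum(axis=1)
    var = np.clip((w * (t_tail - tbar[:, None]) ** 2).sum(axis=1), 1e-12, None)
    slope = cov / var
    tau2 = np.clip(-1.0 / np.minimum(slope, -1e-3), 5 * TAU_MIN_NS, TAU_MAX_NS)
    tau1 = np.clip(tau2 / 5.0, TAU_MIN_NS, TAU_MAX_NS)
    e1 = np.exp(-t[None, :] / tau1[:, None])
    e2 = np.exp(-t[None, :] / tau2[:, None])
    wfit = 1.0 / np.maximum(traces, 1.0)
    # 2x2 weighted normal equations per trace, solved in closed form.
    g11 = (wfit * e1 * e1).sum(axis=1)
    g12 = (wfit * e1 * e2).sum(axis=1)
    g22 = (wfit * e2 * e2).sum(axis=1)
    b1 = (wfit * e1 * traces).sum(axis=1)
    b2 = (wfit * e2 * traces).sum(axis=1)
    det = np.clip(g11 * g22 - g12 * g12, 1e-300, None)
    a1 = (g22 * b1 - g12 * b2) / det
    a2 = (g11 * b2 - g12 * b1) / det
    floor = 1e-3 * np.clip(traces.max(axis=1), 1.0, None)
    a1 = np.maximum(a1, floor)
    a2 = np.maximum(a2, floor)
    return np.stack([a1, a2, tau1, tau2], axis=1)


def _model_and_jac(params: np.ndarray, t: np.ndarray):
    a1, a2 = params[:, 0:1], params[:, 1:2]
    tau1, tau2 = params[:, 2:3], params[:, 3:4]
    e1 = np.exp(-t[None, :] / tau1)
    e2 = np.exp(-t[None, :] / tau2)
    model = a1 * e1 + a2 * e2
    jac = np.stack(
        [e1, e2, a1 * t[None, :] / tau1**2 * e1, a2 * t[None, :] / tau2**2 * e2],
        axis=2,
    )
    return model, jac


def _clip_params(params: np.ndarray) -> np.ndarray:
    params[:, 0:2] = np.maximum(params[:, 0:2], 0.0)
    params[:, 2:4] = np.clip(params[:, 2:4], TAU_MIN_NS, TAU_MAX_NS)
    return params


def _lm_pass(
    traces: np.ndarray,
    t: np.ndarray,
    weights: np.ndarray,
    params: np.ndarray,
    max_iter: int,
    xtol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One Levenberg-Marquardt run at fixed weights; returns
    (params, model, cost, converged)."""
    n_traces = traces.shape[0]
    model, jac = _model_and_jac(params, t)
    resid = traces - model
    cost = (weights * resid**2).sum(axis=1)
    lam = np.full(n_traces, 1e-3)
    converged = np.zeros(n_traces, dtype=bool)
    eye = np.eye(4)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        jw = jac * weights[:, :, None]
        # Normal equations per trace: (J^T W J) delta = J^T W r
        jtj = np.einsum("ntp,ntq->npq", jw, jac)
        g = np.einsum("ntp,nt->np", jw, resid)
        damped = jtj + lam[:, None, None] * (
            jtj * eye + 1e-12 * eye
        )
        try:
            delta = np.linalg.solve(damped, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(
                damped.reshape(-1, 4), g.reshape(-1, 1), rcond=None
            )[0].reshape(n_traces, 4)
        trial = _clip_params(params + delta)
        trial_model, trial_jac = _model_and_jac(trial, t)
        trial_resid = traces - trial_model
        trial_cost = (weights * trial_resid**2).sum(axis=1)
        accept = active & (trial_cost <= cost)
        params[accept] = trial[accept]
        model[accept] = trial_model[accept]
        jac[accept] = trial_jac[accept]
        resid[accept] = trial_resid[accept]
        step_small = np.abs(delta).max(axis=1) <= xtol * (
            1.0 + np.abs(params).max(axis=1)
        )
        rel_impr = (cost - trial_cost) / np.clip(cost, 1e-300, None)
        newly_done = accept & (step_small | (rel_impr < 1e-12))
        cost[accept] = trial_cost[accept]
        converged |= newly_done
        lam = np.where(accept, lam * 0.3, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e8)
    return params, model, cost, converged


def _lm_pass_1exp(
    traces: np.ndarray,
    t: np.ndarray,
    weights: np.ndarray,
    params: np.ndarray,
    max_iter: int,
    xtol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-exponential LM (params columns: amplitude, tau); returns
    (params, model, converged)."""
    n_traces = traces.shape[0]

    def model_jac(p):
        a, tau = p[:, 0:1], p[:, 1:2]
        e = np.exp(-t[None, :] / tau)
        return a * e, np.stack([e, a * t[None, :] / tau**2 * e], axis=2)

    def clip(p):
        p[:, 0] = np.maximum(p[:, 0], 0.0)
        p[:, 1] = np.clip(p[:, 1], TAU_MIN_NS, TAU_MAX_NS)
        return p

    model, jac = model_jac(params)
    resid = traces - model
    cost = (weights * resid**2).sum(axis=1)
    lam = np.full(n_traces, 1e-3)
    converged = np.zeros(n_traces, dtype=bool)
    eye = np.eye(2)
    for _ in range(max_iter):
        if converged.all():
            break
        jw = jac * weights[:, :, None]
        jtj = np.einsum("ntp,ntq->npq", jw, jac)
        g = np.einsum("ntp,nt->np", jw, resid)
        damped = jtj + lam[:, None, None] * (jtj * eye + 1e-12 * eye)
        delta = np.linalg.solve(damped, g[:, :, None])[:, :, 0]
        trial = clip(params + delta)
        trial_model, trial_jac = model_jac(trial)
        trial_resid = traces - trial_model
        trial_cost = (weights * trial_resid**2).sum(axis=1)
        accept = ~converged & (trial_cost <= cost)
        params[accept] = trial[accept]
        model[accept] = trial_model[accept]
        jac[accept] = trial_jac[accept]
        resid[accept] = trial_resid[accept]
        step_small = np.abs(delta).max(axis=1) <= xtol * (
            1.0 + np.abs(params).max(axis=1)
        )
        rel_impr = (cost - trial_cost) / np.clip(cost, 1e-300, None)
        converged |= accept & (step_small | (rel_impr < 1e-12))
        cost[accept] = trial_cost[accept]
        lam = np.where(accept, lam * 0.3, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e8)
    return params, model, converged


def _poisson_deviance(traces: np.ndarray, model: np.ndarray) -> np.ndarray:
    """Per-trace Poisson deviance 2*sum(m - y + y*ln(y/m))."""
    m = np.clip(model, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(traces > 0, traces * np.log(traces / m), 0.0)
    return 2.0 * (m - traces + term).sum(axis=1)


#: Deviance margin by which the two-component model must beat the
#: single-component model to be reported (roughly a chi-square with the 2
#: extra parameters, p ~ 0.01).
DEVIANCE_MARGIN = 9.0


def fit_traces(
    traces: np.ndarray,
    time_bin_ns: float,
    max_iter: int = 80,
    xtol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Fit the bi-exponential model to many traces at once.

    Poisson weighting is applied iteratively: a first Levenberg-Marquardt
    pass uses data-derived weights ``1/max(count, 1)``, then the weights
    are recomputed from the fitted model, ``1/max(model, 1)``, and a
    second pass refines the estimate.  Model-derived weights remove the
    first-order bias that data weights incur because noisy counts appear
    in their own weights.

    A single-exponential model is fitted alongside; when the
    two-component fit does not beat it by :data:`DEVIANCE_MARGIN` in
    Poisson deviance (the bi-exponential surface is a flat ridge for
    one-component data), the trace is reported as a single component
    with ``a2 = 0`` and both lifetimes equal.

    Parameters
    ----------
    traces
        Array ``(n_traces, n_bins)`` of photon counts.
    time_bin_ns
        Time-bin width in nanoseconds.

    Returns
    -------
    dict with arrays ``a1, a2, tau1_ns, tau2_ns, chi2_reduced, n_photons,
    converged`` (components sorted ascending by lifetime; near-tied
    lifetimes collapsed to a single component with a2 = 0).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] < 8:
        raise ConfigurationError("traces must be (n_traces, n_bins>=8)")
    if time_bin_ns <= 0:
        raise ConfigurationError("time_bin_ns must be positive")
    n_traces, n_bins = traces.shape
    t = (np.arange(n_bins) + 0.5) * time_bin_ns

    init = _clip_params(_initial_guess(traces, t))
    weights = 1.0 / np.maximum(traces, 1.0)
    params, model, cost, conv1 = _lm_pass(
        traces, t, weights, init, max_iter, xtol
    )
    weights2 = 1.0 / np.maximum(model, 1.0)
    params, model, cost, conv2 = _lm_pass(
        traces, t, weights2, params, max_iter, xtol
    )
    converged = conv1 | conv2

    # Single-component alternative (same two-pass weighting scheme).
    sp = np.stack(
        [np.maximum(init[:, 0] + init[:, 1], 1e-6), init[:, 3]], axis=1
    )
    sp, smodel, sconv1 = _lm_pass_1exp(traces, t, weights, sp, max_iter, xtol)
    sweights = 1.0 / np.maximum(smodel, 1.0)
    sp, smodel, sconv2 = _lm_pass_1exp(traces, t, sweights, sp, max_iter, xtol)
    single_better = (
        _poisson_deviance(traces, smodel)
        < _poisson_deviance(traces, model) + DEVIANCE_MARGIN
    )
    if single_better.any():
        params[single_better, 0] = sp[single_better, 0]
        params[single_better, 1] = 0.0
        params[single_better, 2] = sp[single_better, 1]
        params[single_better, 3] = sp[single_better, 1]
        converged[single_better] = (sconv1 | sconv2)[single_better]
        # chi2 of the selected model under its own model weights
        sresid = traces[single_better] - smodel[single_better]
        cost[single_better] = (
            sweights[single_better] * sresid**2
        ).sum(axis=1)

    # Sort components ascending by lifetime.
    swap = params[:, 2] > params[:, 3]
    params[swap] = params[swap][:, [1, 0, 3, 2]]
    # Collapse near-ties to a single-component report.
    tied = (params[:, 3] - params[:, 2]) < _TIE_REL_TOL * params[:, 3]
    if tied.any():
        total = params[tied, 0] + params[tied, 1]
        tau_eff = np.where(
            total > 0,
            (
                params[tied, 0] * params[tied, 2]
                + params[tied, 1] * params[tied, 3]
            )
            / np.clip(total, 1e-300, None),
            params[tied, 2],
        )
        params[tied, 0] = total
        params[tied, 1] = 0.0
        params[tied, 2] = tau_eff
        params[tied, 3] = tau_eff

    dof = max(n_bins - 4, 1)
    chi2 = cost / dof
    chi2 = np.where(converged, chi2, CHI2_SENTINEL)
    return {
        "a1": params[:, 0],
        "a2": params[:, 1],
        "tau1_ns": params[:, 2],
        "tau2_ns": params[:, 3],
        "chi2_reduced": chi2,
        "n_photons": traces.sum(axis=1).astype(np.int64),
        "converged": converged,
    }


def fit_biexponential(
    trace: np.ndarray,
    time_bin_ns: float,
    min_photons: int = DEFAULT_MIN_PHOTONS,
) -> BiexpFit:
    """Fit one decay trace; raises ``BelowThresholdError`` if too dim."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 8:
        raise ConfigurationError("trace must be 1-D with at least 8 bins")
    n_photons = int(round(trace.sum()))
    if n_photons < min_photons:
        raise BelowThresholdError(
            f"trace has {n_photons} photons < min_photons={min_photons}"
        )
    r = fit_traces(trace[None, :], time_bin_ns)
    return BiexpFit(
        a1=float(r["a1"][0]),
        a2=float(r["a2"][0]),
        tau1_ns=float(r["tau1_ns"][0]),
        tau2_ns=float(r["tau2_ns"][0]),
        chi2_reduced=float(r["chi2_reduced"][0]),
        n_photons=n_photons,
        converged=bool(r["converged"][0]),
    )


def fit_frame(
    cube: DecayCube,
    n: int = 4,
    min_photons: int = DEFAULT_MIN_PHOTONS,
    stride: int = 1,
) -> LifetimeMap:
    """Spatially bin a cube and fit every (sampled) pixel.

    ``stride`` fits every stride-th pixel in each direction, a pure
    compute-reduction knob: frame statistics are estimated from the sampled
    grid.  Pixels below ``min_photons`` or failing to converge are masked.
    Raises ``EmptyMapError`` when no pixel survives.
    """
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    binned = spatial_bin(cube, n)
    sub = binned.counts[::stride, ::stride, :]
    h, w, _ = sub.shape
    traces = sub.reshape(h * w, -1).astype(float)
    photons = traces.sum(axis=1)
    bright = photons >= min_photons
    if not bright.any():
        raise EmptyMapError(
            f"all {h * w} pixels below min_photons={min_photons}"
        )
    out = {
        k: np.zeros(h * w)
        for k in ("a1", "a2", "tau1_ns", "tau2_ns", "chi2_reduced")
    }
    fitted = fit_traces(traces[bright], cube.time_bin_ns)
    mask = np.zeros(h * w, dtype=bool)
    mask[bright] = fitted["converged"]
    for k in ("a1", "a2", "tau1_ns", "tau2_ns", "chi2_reduced"):
        out[k][bright] = fitted[k]
    if not mask.any():
        raise EmptyMapError("no pixel produced a converged fit")
    return LifetimeMap(
        tau1_ns=out["tau1_ns"].reshape(h, w),
        tau2_ns=out["tau2_ns"].reshape(h, w),
        a1=out["a1"].reshape(h, w),
        a2=out["a2"].reshape(h, w),
        mask=mask.reshape(h, w),
        chi2_reduced=out["chi2_reduced"].reshape(h, w),
        depth_um=cube.depth_um,
        stride=stride,
    )


def mean_lifetime(fit: BiexpFit) -> float:
    """Amplitude-weighted mean lifetime ``(a1*tau1 + a2*tau2)/(a1 + a2)``."""
    total = fit.a1 + fit.a2
    if total <= 0:
        raise UndefinedValueError("mean lifetime undefined for a1 + a2 = 0")
    return (fit.a1 * fit.tau1_ns + fit.a2 * fit.tau2_ns) / total


def component_percentages(
    fit: BiexpFit, intensity_weighted: bool = False
) -> tuple[float, float]:
    """Percentage of fluorescence attributed to each component.

    By default the amplitude convention ``p_i = 100 * a_i / (a1 + a2)`` is
    used (the SPCImage-style default); ``intensity_weighted=True`` uses the
    photon-integral convention ``p_i = 100 * a_i*tau_i / sum(a*tau)``.
    """
    if intensity_weighted:
        w1, w2 = fit.a1 * fit.tau1_ns, fit.a2 * fit.tau2_ns
    else:
        w1, w2 = fit.a1, fit.a2
    total = w1 + w2
    if total <= 0:
        raise UndefinedValueError("percentages undefined for a1 + a2 = 0")
    return (100.0 * w1 / total, 100.0 * w2 / total)


def frame_lifetime_stats(lifetime_map: LifetimeMap) -> FrameStats:
    """Mean and population standard deviation of the fitted lifetimes.

    Statistics are over valid pixels only; the standard deviation uses the
    population (N) divisor.  Requires at least two valid pixels.
    """
    mask = lifetime_map.mask
    n_valid = int(mask.sum())
    if n_valid < 2:
        raise InsufficientDataError(
            f"need >= 2 valid pixels for frame statistics, got {n_valid}"
        )
    tau1 = lifetime_map.tau1_ns[mask]
    tau2 = lifetime_map.tau2_ns[mask]
    return FrameStats(
        tau1_mean_ns=float(tau1.mean()),
        tau1_std_ns=float(tau1.std()),
        tau2_mean_ns=float(tau2.mean()),
        tau2_std_ns=float(tau2.std()),
        p1_mean_percent=float(lifetime_map.p1_percent[mask].mean()),
        p2_mean_percent=float(lifetime_map.p2_percent[mask].mean()),
        mean_lifetime_mean_ns=float(lifetime_map.mean_lifetime_ns[mask].mean()),
        n_valid=n_valid,
        fraction_masked=float(1.0 - n_valid / mask.size),
    )
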