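"""Characterization toolkit: spatiotemporal correlation, k–ω spectra,
ridge/group-velocity fits, and HSS/SF/TW/SC regime classification.

Regime labels: HSS — homogeneous steady state with no flow; SF — steady
spontaneous flow (x-invariant); TW — traveling waves with traveling vortices;
SC — spatiotemporal chaos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrate import Trajectory, detect_steady_state


# ----------------------------------------------------------------------
# spatiotemporal correlation
# ----------------------------------------------------------------------

@dataclass
class CorrelationMap:
    """C(Δx, Δy; Δt): time-averaged polarity dot product (cos Δθ for unit p)."""

    lags: np.ndarray            # time lags Δt
    values: np.ndarray          # shape (n_lags, n_y_offsets, n_x_offsets)
    r0: tuple[int, int]         # reference node (iy, ix)
    window: float               # averaging window duration
    baseline: np.ndarray = None # mean-field product <p(r0)>.<p(r0+dr)>: the
                                # large-lag plateau of a mixing field

    def at_zero_offset(self) -> np.ndarray:
        return self.values[:, 0, 0]


def spatiotemporal_correlation(traj: Trajectory, r0: tuple[int, int] | None = None,
                               lags: list[float] | None = None,
                               window: float | None = None,
                               average_over_x: bool = False) -> CorrelationMap:
    """Correlation C(Δr, Δt) = ⟨ p(r0, t) · p(r0 + Δr, t + Δt) ⟩_t.

    The inner product of unit polarity vectors equals cos Δθ, so C lies in
    [−1, 1]: −1 is perfect anti-alignment, +1 perfect alignment, 0 perfect
    decorrelation.  Offsets wrap periodically in x; along y they wrap too
    (offsets beyond the film report the wrapped row).  Default r0 is the
    domain centre.  With ``average_over_x`` the reference point is averaged
    over the whole x row through r0 (legitimate by translation invariance of
    the channel); this multiplies the effective sample count on short records.
    """
    times = traj.times
    dt_s = traj.dt_sample
    if lags is None:
        lags = [0.0]
    if r0 is None:
        r0 = (traj.grid.n_y // 2, traj.grid.n_x // 2)
    lag_steps = []
    for lag in lags:
        n = int(round(lag / dt_s)) if lag > 0 else 0
        if abs(n * dt_s - lag) > 1e-9 * max(dt_s, 1.0):
            raise ValueError(f"lag {lag} is not a multiple of the sampling step {dt_s}")
        lag_steps.append(n)
    n_t = len(times)
    max_lag = max(lag_steps)
    if window is None:
        n_win = n_t - max_lag
    else:
        n_win = int(round(window / dt_s)) + 1 if dt_s > 0 else 1
    if n_win < 1 or n_win + max_lag > n_t:
        raise ValueError("window plus maximum lag exceeds the trajectory length")
    px = np.stack([s.p_x for s in traj.states])
    py = np.stack([s.p_y for s in traj.states])
    iy0, ix0 = r0
    mx, my = px.mean(axis=0), py.mean(axis=0)
    vals = np.empty((len(lag_steps), traj.grid.n_y, traj.grid.n_x))
    if average_over_x:
        # reference averaged over the x row through r0: correlate row iy0
        # against every offset via FFT in the x direction
        mxr = np.fft.rfft(mx, axis=1)
        myr = np.fft.rfft(my, axis=1)
        n_x = traj.grid.n_x
        base = np.fft.irfft(np.conj(mxr[iy0]) * np.roll(mxr, -iy0, axis=0)
                            + np.conj(myr[iy0]) * np.roll(myr, -iy0, axis=0),
                            n=n_x, axis=1) / n_x
        for i, nlag in enumerate(lag_steps):
            ax = np.fft.rfft(px[:n_win, iy0, :], axis=1)
            ay = np.fft.rfft(py[:n_win, iy0, :], axis=1)
            bx = np.fft.rfft(np.roll(px[nlag:nlag + n_win], -iy0, axis=1), axis=2)
            by = np.fft.rfft(np.roll(py[nlag:nlag + n_win], -iy0, axis=1), axis=2)
            cc = np.fft.irfft(np.conj(ax)[:, None, :] * bx
                              + np.conj(ay)[:, None, :] * by, n=n_x, axis=2)
            vals[i] = cc.mean(axis=0) / n_x
    else:
        base = (mx[iy0, ix0] * np.roll(np.roll(mx, -iy0, axis=0), -ix0, axis=1)
                + my[iy0, ix0] * np.roll(np.roll(my, -iy0, axis=0), -ix0, axis=1))
        for i, nlag in enumerate(lag_steps):
            a_x = px[:n_win, iy0, ix0][:, None, None]
            a_y = py[:n_win, iy0, ix0][:, None, None]
            b_x = np.roll(np.roll(px[nlag:nlag + n_win], -iy0, axis=1), -ix0, axis=2)
            b_y = np.roll(np.roll(py[nlag:nlag + n_win], -iy0, axis=1), -ix0, axis=2)
            vals[i] = (a_x * b_x + a_y * b_y).mean(axis=0)
    return CorrelationMap(np.asarray(lags, dtype=float), vals, r0,
                          (n_win - 1) * dt_s, base)


# ----------------------------------------------------------------------
# k–ω power spectrum
# ----------------------------------------------------------------------

@dataclass
class SpectrumMap:
    """Normalized power over (k_x, ω) with k_y summed out."""

    k_x: np.ndarray
    omega: np.ndarray
    power: np.ndarray           # shape (n_omega, n_kx); sums to 1
    total_power: float          # normalization constant (pre-normalization sum)
    meta: dict = field(default_factory=dict)


def power_spectrum(traj: Trajectory, *, window: str | None = "hann",
                   pad_y: bool = True) -> SpectrumMap:
    """3D DFT power of the polarity angle θ(x, y, t), k_y integrated out.

    The x-and-time-averaged (anchored) θ profile is subtracted, a Hann window
    is applied in time (finite record), the y direction is zero-padded to
    soften the non-periodic walls, and the squared modulus is normalized by
    the total power.
    """
    times = traj.times
    if len(times) < 2:
        raise ValueError("power spectrum requires at least two snapshots")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-8, atol=0.0):
        raise ValueError("power spectrum requires uniformly sampled snapshots")
    theta = traj.theta()                       # (n_t, n_y, n_x)
    n_t, n_y, n_x = theta.shape
    mean_profile = theta.mean(axis=(0, 2))
    theta = theta - mean_profile[None, :, None]
    if window == "hann":
        w = np.hanning(n_t)
        theta = theta * w[:, None, None]
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    n_y_fft = 2 * n_y if pad_y else n_y
    F = np.fft.fft(theta, axis=2)
    F = np.fft.fft(F, n=n_y_fft, axis=1)
    F = np.fft.fft(F, axis=0)
    P = np.abs(F) ** 2
    total = float(P.sum())
    S = P.sum(axis=1)                          # integrate out k_y -> (n_omega, n_kx)
    if total > 0:
        S = S / total
    dt_s = float(dts[0])
    # sign flip: with numpy's e^{-i w t} transform a wave cos(k x - w0 t)
    # lands at (k, -w0); negating makes omega the physical frequency with
    # the convention theta ~ e^{i(k x - w t)}, so a +x-moving wave has w = c k
    omega = -2.0 * np.pi * np.fft.fftfreq(n_t, d=dt_s)
    k_x = 2.0 * np.pi * np.fft.fftfreq(n_x, d=traj.grid.h_x)
    meta = {"window": window, "pad_y": pad_y, "n_t": n_t,
            "mean_profile_subtracted": True,
            "raw_power_sum": total, "n_fft": (n_t, n_y_fft, n_x)}
    return SpectrumMap(k_x, omega, S, total, meta)


def group_velocity(spec: SpectrumMap) -> tuple[float, float]:
    """Fit ω = c k_x through the power-weighted dispersion ridge.

    Returns (c, ridge_power_fraction) where the fraction is the share of
    non-DC power within ±1 ω-bin of the fitted line.  A non-dispersive
    traveling wave concentrates its power on the ridge (fraction → 1);
    a static pattern gives c = 0.
    """
    S = spec.power
    k, w = spec.k_x, spec.omega
    non_dc = S.copy()
    non_dc[:, 0] = 0.0          # remove k_x = 0 column (incl. DC bin)
    tot = non_dc.sum()
    if tot <= 0:
        raise ValueError("all spectral power is at k_x = 0; group velocity undefined")
    # peak frequency per k_x > 0 column, power-weighted straight-line fit ω = c k
    pos = np.where(k > 0)[0]
    wk, ck = [], []
    for j in pos:
        col = non_dc[:, j]
        s = col.sum()
        if s <= 0:
            continue
        w_peak = w[int(np.argmax(col))]
        wk.append(s)
        ck.append((k[j], w_peak))
    wk = np.asarray(wk)
    kk = np.asarray([a for a, _ in ck])
    ww = np.asarray([b for _, b in ck])
    denom = np.sum(wk * kk**2)
    c = float(np.sum(wk * kk * ww) / denom) if denom > 0 else 0.0
    # fraction of non-DC power within one ω-bin of the ridge (±k branches)
    dw = np.abs(w[1] - w[0]) if len(w) > 1 else np.inf
    W, K = np.meshgrid(w, k, indexing="ij")
    # wrap the expected frequency onto the principal FFT band
    w_span = len(w) * dw
    expected = c * K
    diff = np.abs((W - expected + w_span / 2) % w_span - w_span / 2)
    on_ridge = diff <= 1.5 * dw
    frac = float(non_dc[on_ridge].sum() / tot)
    return c, frac


# ----------------------------------------------------------------------
# regime classification
# ----------------------------------------------------------------------

@dataclass
class ClassifierThresholds:
    eps_v: float = 1e-6          # flow amplitude below which the film is quiescent
    eps_x: float = 1e-6          # x-invariance deviation for "homogeneous along x"
    f_min: float = 0.5           # minimum ridge power fraction for TW
    corr_decay: float = 0.2      # correlation cut for "decorrelated" (SC)
    steady_tol: float = 1e-6     # max |dp/dt| for steadiness
    eps_lambda: float = 1e-3     # absolute floor (1/time) for "lambda is zero":
                                 # on a clean periodic attractor the window
                                 # samples barely fluctuate and 3 stderr alone
                                 # underestimates the neutral band


@dataclass
class RegimeReport:
    label: str
    lyapunov: float | None
    lyapunov_stderr: float | None
    max_flow_speed: float
    x_invariance: float
    group_velocity: float | None
    ridge_fraction: float | None
    correlation_decay: float | None
    thresholds: ClassifierThresholds
    steady: bool
    details: dict = field(default_factory=dict)


def x_invariance_deviation(field2d: np.ndarray) -> float:
    """Max deviation of a field from its x-average (0 for x-invariant fields)."""
    return float(np.abs(field2d - field2d.mean(axis=1, keepdims=True)).max())


def classify_regime(traj: Trajectory, lyapunov_result=None,
                    spec: SpectrumMap | None = None,
                    corr: CorrelationMap | None = None,
                    thresholds: ClassifierThresholds | None = None) -> RegimeReport:
    """Decision rules (measurements on the post-transient trajectory):

    HSS: steady, max|v| < eps_v and x-invariance deviation < eps_x.
    SF:  steady, max|v| >= eps_v.
    TW:  unsteady, λ consistent with 0 (within max(3·stderr, eps_lambda)),
         ridge fraction >= f_min.
    SC:  unsteady, λ positive beyond both 3·stderr and eps_lambda, spatial
         correlation decays below the cut.
    Anything else: "indeterminate" with all measurements attached.
    """
    th = thresholds or ClassifierThresholds()
    steady, _ = detect_steady_state(traj, tol=th.steady_tol)
    vmax = float(traj.max_speed[-1]) if traj.max_speed is not None else np.nan
    theta_dev = x_invariance_deviation(traj.states[-1].theta)
    lam = stderr = None
    if lyapunov_result is not None:
        lam = lyapunov_result.lambda_max
        stderr = lyapunov_result.stderr
    c = frac = None
    if spec is not None:
        try:
            c, frac = group_velocity(spec)
        except ValueError:
            c, frac = 0.0, 0.0
    decay = None
    if corr is not None and len(corr.lags) > 0:
        # RMS of the connected correlation (C minus the mean-alignment
        # plateau) over spatial offsets at the largest lag: ~0 once spatial
        # correlations have disappeared, O(1) for a coherent translating
        # pattern
        plateau = corr.baseline if corr.baseline is not None else 0.0
        decay = float(np.sqrt(np.mean((corr.values[-1] - plateau) ** 2)))

    label = "indeterminate"
    if steady:
        if vmax >= th.eps_v:
            label = "SF"
        elif theta_dev < th.eps_x:
            label = "HSS"
    else:
        tw_ok = (lam is not None and stderr is not None
                 and abs(lam) <= max(3.0 * stderr, th.eps_lambda)
                 and frac is not None and frac >= th.f_min)
        sc_ok = (lam is not None and stderr is not None
                 and lam - 3.0 * stderr > 0.0 and lam > th.eps_lambda
                 and (decay is None or decay < th.corr_decay))
        if tw_ok and not sc_ok:
            label = "TW"
        elif sc_ok and not tw_ok:
            label = "SC"
    return RegimeReport(label, lam, stderr, vmax, theta_dev, c, frac, decay,
                        th, steady,
                        details={"n_samples": len(traj.times)})
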