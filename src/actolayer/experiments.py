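"""Scripted experiments: configured runs, activity scans, friction-threshold
scans, snapshot I/O and synthetic fixtures.

Everything is deterministic given an ``ExperimentConfig``; every output bundle
embeds the fully resolved configuration and a content hash so a run can be
reproduced bit-exactly from its own metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .diagnostics import (ClassifierThresholds, CorrelationMap, RegimeReport,
                          classify_regime, power_spectrum,
                          spatiotemporal_correlation)
from .fields import FieldState, FlowState
from .grid import GridSpec
from .integrate import Trajectory, detect_steady_state, initial_condition, run
from .lyapunov import benettin_mle
from .params import DEFAULT_DT, DEFAULT_L, MaterialParams, preset
from .stability import alpha_c_interval
from .stokes import StokesBC, solve_flow

log = logging.getLogger("actolayer")


@dataclass
class ExperimentConfig:
    """Fully resolved settings of one simulation + diagnostics pipeline."""

    preset: str = "tumbling"            # tumbling | aligning
    alpha_ratio: float = 3.0            # activity over the lower alpha_c bound
    n_x: int = 64
    n_y: int = 65
    L_x: float = DEFAULT_L
    L_y: float = DEFAULT_L
    dt: float = DEFAULT_DT
    t_end: float = 50.0
    stride: int = 125                   # snapshot every stride steps
    perturbation_percent: float = 1.0
    mu: float | None = None             # equal-wall friction override
    tail_fraction: float = 0.5          # post-transient portion for diagnostics
    lyap_windows: int = 200
    lyap_steps_per_window: int = 50
    lyap_delta0: float = 1e-6
    seed: int = 0
    outdir: str | None = None

    # -- construction helpers -------------------------------------------

    def grid(self) -> GridSpec:
        return GridSpec(self.n_x, self.n_y, self.L_x, self.L_y)

    def material(self) -> MaterialParams:
        p = preset(self.preset)
        if self.mu is not None:
            p = p.with_mu(self.mu)
        lo, _ = alpha_c_interval(p, self.grid())
        return p.with_alpha(self.alpha_ratio * lo)

    def bc(self) -> StokesBC:
        return StokesBC.from_params(self.material())

    # -- (de)serialization ----------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    trajectory: Trajectory
    report: RegimeReport
    alpha_c_lower: float
    timings: dict


# ----------------------------------------------------------------------
# snapshot I/O
# ----------------------------------------------------------------------

def write_snapshot(state: FieldState, path: str | Path, grid: GridSpec,
                   params: MaterialParams | None = None,
                   flow: FlowState | None = None) -> None:
    """Array container with axis coordinates, parameter record and checksum."""
    with h5py.File(path, "w") as f:
        f.attrs["code_version"] = _version
        f.attrs["t"] = state.t
        f.create_dataset("p_x", data=state.p_x)
        f.create_dataset("p_y", data=state.p_y)
        f.create_dataset("x", data=grid.x)
        f.create_dataset("y", data=grid.y)
        if flow is not None:
            f.create_dataset("v_x", data=flow.v_x)
            f.create_dataset("v_y", data=flow.v_y)
            f.create_dataset("P", data=flow.P)
        if params is not None:
            for k, v in asdict(params).items():
                f.attrs[f"param_{k}"] = v
        digest = hashlib.sha256(state.p_x.tobytes() + state.p_y.tobytes()).hexdigest()
        f.attrs["sha256"] = digest


def read_snapshot(path: str | Path) -> tuple[FieldState, dict]:
    """Read a snapshot; verifies the checksum (integrity error on mismatch)."""
    with h5py.File(path, "r") as f:
        p_x = f["p_x"][...]
        p_y = f["p_y"][...]
        t = float(f.attrs["t"])
        meta = dict(f.attrs)
        digest = hashlib.sha256(p_x.tobytes() + p_y.tobytes()).hexdigest()
        if digest != f.attrs.get("sha256"):
            raise IOError(f"snapshot {path} failed its integrity check")
        if meta.get("code_version") != _version:
            import warnings
            warnings.warn(f"snapshot written by version {meta.get('code_version')}, "
                          f"reading with {_version}")
    return FieldState(p_x, p_y, t), meta


# ----------------------------------------------------------------------
# the standard pipeline
# ----------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate from the standard initial condition and classify the regime.

    If ``config.outdir`` is set, the resolved config, a restart checkpoint and
    the final report are written there; an existing checkpoint with a matching
    config hash is resumed (bit-exact, since the state determines the future).
    """
    grid = config.grid()
    params = config.material()
    bc = config.bc()
    lo, _ = alpha_c_interval(params, grid)
    timings = {}
    outdir = Path(config.outdir) if config.outdir else None
    state = initial_condition(grid, config.perturbation_percent)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        ckpt = outdir / "checkpoint.h5"
        if ckpt.exists():
            prev, meta = read_snapshot(ckpt)
            if meta.get("config_hash") == config.content_hash() and prev.t < config.t_end:
                log.info("resuming from checkpoint at t=%.4g", prev.t)
                state = prev

    t0 = time.perf_counter()
    traj = run(state, config.t_end, config.dt, params, grid, bc,
               stride=config.stride)
    timings["simulate"] = time.perf_counter() - t0
    if outdir is not None:
        final = traj.states[-1]
        write_snapshot(final, outdir / "checkpoint.h5", grid, params)
        with h5py.File(outdir / "checkpoint.h5", "a") as f:
            f.attrs["config_hash"] = config.content_hash()

    # post-transient tail for diagnostics
    n = len(traj.times)
    i0 = int(n * (1.0 - config.tail_fraction))
    tail = Trajectory(traj.times[i0:], traj.states[i0:], None, params, grid,
                      config.stride, traj.max_rate[i0:], traj.max_speed[i0:])

    t0 = time.perf_counter()
    steady, _ = detect_steady_state(tail)
    spec = corr = lyap = None
    if not steady and len(tail.times) >= 8:
        spec = power_spectrum(tail)
        dt_s = tail.dt_sample
        lags = [0.0, dt_s * max(1, (len(tail.times) - 1) // 2)]
        corr = spatiotemporal_correlation(tail, lags=lags, average_over_x=True)
        # seed the companion along the local phase direction (the angle rate):
        # the neutral mode of any periodic attractor, so the window average
        # reaches the leading exponent without a long mode-mixing transient
        from .integrate import _rate
        fin = traj.states[-1]
        rx, ry, _ = _rate(fin.p_x, fin.p_y, fin.t, params, grid, bc, True)
        tdot = -fin.p_y * rx + fin.p_x * ry
        if np.abs(tdot[1:-1]).max() == 0.0:
            tdot = None
        lyap = benettin_mle(fin, params, grid, bc, dt=config.dt,
                            steps_per_window=config.lyap_steps_per_window,
                            n_windows=config.lyap_windows,
                            delta0=config.lyap_delta0,
                            perturbation=tdot,
                            rng=np.random.default_rng(config.seed))
    report = classify_regime(tail, lyap, spec, corr)
    timings["diagnostics"] = time.perf_counter() - t0
    log.info("ratio=%.3g -> %s (|v|max=%.3g)", config.alpha_ratio, report.label,
             report.max_flow_speed)

    if outdir is not None:
        payload = {
            "label": report.label,
            "lyapunov": report.lyapunov,
            "lyapunov_stderr": report.lyapunov_stderr,
            "max_flow_speed": report.max_flow_speed,
            "x_invariance": report.x_invariance,
            "group_velocity": report.group_velocity,
            "ridge_fraction": report.ridge_fraction,
            "alpha_c_lower": lo,
            "config_hash": config.content_hash(),
            "timings": timings,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))
    return ExperimentResult(config, traj, report, lo, timings)


def phase_scan(preset_name: str, alpha_ratios: list[float],
               base_config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Run the standard pipeline at each activity ratio and tabulate regimes.

    The α/α_c column is normalized by the lower bound of the analytic
    critical-activity interval.
    """
    rows = []
    for ratio in alpha_ratios:
        cfg = dataclasses.replace(base_config or ExperimentConfig(),
                                  preset=preset_name, alpha_ratio=ratio)
        res = run_experiment(cfg)
        r = res.report
        rows.append({
            "alpha_ratio": ratio,
            "label": r.label,
            "lyapunov": r.lyapunov,
            "lyapunov_stderr": r.lyapunov_stderr,
            "max_flow_speed": r.max_flow_speed,
            "x_invariance": r.x_invariance,
            "group_velocity": r.group_velocity,
            "ridge_fraction": r.ridge_fraction,
        })
    return pd.DataFrame(rows)


def threshold_scan_mu(preset_name: str, mu_values: list[float], transition: str,
                      base_config: ExperimentConfig | None = None,
                      ratio_bracket: tuple[float, float] = (3.0, 120.0),
                      n_bisect: int = 5) -> pd.DataFrame:
    """Bracket the activity threshold of a regime transition versus friction.

    ``transition`` is ``"SF->TW"`` or ``"TW->SC"``; both walls share the same
    friction μ.  Returns one row per μ with the bracketing (lower, upper)
    activity-ratio interval — the numerical uncertainty of the threshold.
    """
    if transition not in ("SF->TW", "TW->SC"):
        raise ValueError("transition must be 'SF->TW' or 'TW->SC'")
    low_labels = ("HSS", "SF") if transition == "SF->TW" else ("HSS", "SF", "TW")
    rows = []
    for mu in mu_values:
        lo, hi = ratio_bracket
        for _ in range(n_bisect):
            mid = np.sqrt(lo * hi)   # geometric bisection over activity
            cfg = dataclasses.replace(base_config or ExperimentConfig(),
                                      preset=preset_name, alpha_ratio=mid, mu=mu)
            label = run_experiment(cfg).report.label
            if label in low_labels:
                lo = mid
            else:
                hi = mid
        rows.append({"mu": mu, "ratio_lower": lo, "ratio_upper": hi,
                     "transition": transition})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# synthetic fixtures
# ----------------------------------------------------------------------

def make_fixture(kind: str, **kw):
    """Synthetic inputs for testing the solver and the diagnostics.

    kinds: ``manufactured_stokes`` (exact Stokes solution + forcing),
    ``plane_wave_traj`` (non-dispersive traveling wave trajectory),
    ``chaotic_map_signal`` (coupled logistic-map lattice, chaotic).
    """
    if kind == "manufactured_stokes":
        return _manufactured_stokes(**kw)
    if kind == "plane_wave_traj":
        return _plane_wave_traj(**kw)
    if kind == "chaotic_map_signal":
        return _chaotic_map_signal(**kw)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _manufactured_stokes(grid: GridSpec, eta: float = 1.0, mode: int = 1,
                         amp: float = 1.0):
    """Divergence-free velocity with no-slip walls and the force making it exact.

    ψ = A sin(kx) y²(L−y)², v = (∂_y ψ, −∂_x ψ), P = A cos(kx) cos(πy/L);
    f = ∇P − η Δv.
    """
    x, y = np.meshgrid(grid.x, grid.y)
    L = grid.L_y
    k = 2.0 * np.pi * mode / grid.L_x
    g = y**2 * (L - y) ** 2
    g1 = 2 * y * (L - y) ** 2 - 2 * y**2 * (L - y)
    g2 = 2 * (L - y) ** 2 - 8 * y * (L - y) + 2 * y**2
    g3 = 12.0 * (2 * y - L)
    s, c = np.sin(k * x), np.cos(k * x)
    v_x = amp * s * g1
    v_y = -amp * k * c * g
    q = np.cos(np.pi * y / L)
    q1 = -(np.pi / L) * np.sin(np.pi * y / L)
    P = amp * c * q
    f_x = -amp * k * s * q - eta * amp * s * (g3 - k**2 * g1)
    f_y = amp * c * q1 + eta * amp * k * c * (g2 - k**2 * g)
    P = P - grid.mean(P)
    return {"v_x": v_x, "v_y": v_y, "P": P, "f_x": f_x, "f_y": f_y,
            "eta": eta, "grid": grid}


def _plane_wave_traj(grid: GridSpec, mode: int = 2, omega0: float = 2.0,
                     n_t: int = 64, dt: float = 0.25, amp: float = 0.1,
                     y_envelope: bool = False,
                     params: MaterialParams | None = None) -> Trajectory:
    """Trajectory with θ(x, y, t) = A cos(k₀ x − ω₀ t) (group velocity ω₀/k₀)."""
    k0 = 2.0 * np.pi * mode / grid.L_x
    x, y = np.meshgrid(grid.x, grid.y)
    env = np.sin(np.pi * y / grid.L_y) if y_envelope else np.ones_like(y)
    times = np.arange(n_t) * dt
    states = [FieldState.from_theta(amp * env * np.cos(k0 * x - omega0 * t), t)
              for t in times]
    return Trajectory(times, states, None, params or MaterialParams(), grid, 1,
                      np.full(n_t, np.inf), np.zeros(n_t))


def _chaotic_map_signal(n_sites: int = 64, n_t: int = 256, eps: float = 0.1,
                        r: float = 4.0, seed: int = 0) -> np.ndarray:
    """Diffusively coupled logistic-map lattice (positive Lyapunov exponent)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 0.8, n_sites)
    out = np.empty((n_t, n_sites))
    f = lambda u: r * u * (1.0 - u)
    for t in range(n_t):
        fx = f(x)
        x = (1 - eps) * fx + 0.5 * eps * (np.roll(fx, 1) + np.roll(fx, -1))
        out[t] = x
    return out
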