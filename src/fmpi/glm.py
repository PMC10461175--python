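"""General linear model for hemodynamic MPI time series.

The per-voxel signal during a hyper-/hypocapnia block experiment is modelled
as a linear combination of five regressors:

1. the *activation* term: the capnic block waveform convolved with a CO2
   response kernel ``t * exp(-t/tau1)`` and multiplied by the tracer blood
   clearance envelope ``exp(-t/tau2)``;
2. a constant baseline;
3. a linear and
4. a quadratic drift term (instrumental gain drift);
5. an initial transient ``exp(-t/tau_d)`` capturing warm-up effects, with
   tau_d set to one third of the first activation half period (100 s for
   5 min states).

Variants: BOLD mode drops the clearance envelope (no tracer); phantom mode
additionally drops the CO2 kernel (the stimulus is mechanical in/out motion)
and appends a signal-conditional linear drift column that is zero while the
phantom is out of the bore.

The activation regressor is rescaled to unit peak-to-peak amplitude, so the
fitted coefficient reads directly as the peak-to-peak signal change Delta-S
and the contrast-to-noise ratio is simply beta / residual SD.  A variable
onset delay Delta-t (manual stimulus timing uncertainty) is grid searched in
5 s steps over -20..+20 s; tau1 and tau2 are found by bounded nonlinear
least squares from a coarse multistart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "GLMParams",
    "GLMFit",
    "co2rf",
    "activation_regressor",
    "build_design",
    "fit_voxel",
    "fit_glm",
    "optimize_params",
    "cnr_map",
    "percent_change_map",
    "activation_map",
    "blood_half_life",
    "tau2_from_half_life",
    "DELTA_T_GRID",
    "CNR_CAP",
]

#: onset delay grid, seconds
DELTA_T_GRID: tuple[float, ...] = tuple(float(d) for d in range(-20, 25, 5))

#: sentinel cap for CNR when the residual vanishes
CNR_CAP = 1e6

#: reference time constants (figure-level hemodynamic values) used as
#: placeholders in modes where a constant does not enter the model
REF_TAU1 = 51.0
REF_TAU2 = 3100.0

_MODES = ("fmpi", "phantom", "bold")


@dataclass(frozen=True)
class GLMParams:
    """Hemodynamic model parameters.

    tau1: CO2 response time constant (s); tau2: tracer blood clearance (s);
    tau_d: warm-up transient constant (s, default 100 = one third of a 5 min
    half period); delta_t: stimulus onset delay (s) on the 5 s grid.
    """

    tau1: float = REF_TAU1
    tau2: float = REF_TAU2
    tau_d: float = 100.0
    delta_t: float = 0.0
    mode: str = "fmpi"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        for name in ("tau1", "tau2", "tau_d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GLMFit:
    """Per-voxel GLM results over a (possibly masked) image series."""

    betas: np.ndarray  # (n_voxels, n_regressors)
    names: list[str]
    residual_sd: np.ndarray  # (n_voxels,)
    cnr: np.ndarray
    percent_change: np.ndarray  # % Delta-S/S, nan where baseline invalid
    t_stat: np.ndarray
    p_value: np.ndarray
    dof: int
    params: GLMParams
    shape: tuple[int, ...]  # spatial shape for map reshaping
    mask: np.ndarray | None = None

    def map(self, values: np.ndarray) -> np.ndarray:
        """Scatter a per-voxel vector back onto the spatial grid."""
        if self.mask is None:
            return values.reshape(self.shape)
        out = np.full(self.shape, np.nan)
        out[self.mask] = values
        return out


# ---------------------------------------------------------------------------
# regressor construction
# ---------------------------------------------------------------------------


def co2rf(t, tau1: float):
    """CO2 response kernel ``t * exp(-t/tau1)`` for t >= 0, 0 otherwise.

    Peaks at t = tau1; lumps gas-line, lung, transit and hemodynamic delays
    into a single gamma-like kernel.
    """
    if not tau1 > 0:
        raise ValueError("tau1 must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, t * np.exp(-np.minimum(t, 700.0 * tau1) / tau1), 0.0)
    return out if out.ndim else float(out)


def _as_block_fn(block, timestamps=None) -> Callable[[np.ndarray], np.ndarray]:
    """Normalize a block specification to a callable of absolute time.

    Accepts a callable t -> {0,1}, an object exposing ``.block`` (a capnia
    protocol), or a sample array aligned with ``timestamps`` (reconstructed
    as a right-continuous step function; before the first sample the first
    value holds).
    """
    if hasattr(block, "block") and callable(block.block):
        return block.block
    if callable(block):
        return block
    vals = np.asarray(block, dtype=float)
    if timestamps is None:
        raise ValueError("array-valued block requires timestamps")
    ts = np.asarray(timestamps, dtype=float)
    if vals.shape != ts.shape:
        raise ValueError("block samples and timestamps must align")

    def fn(t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(ts, t, side="right") - 1, 0, len(ts) - 1)
        return vals[idx]

    return fn


def _convolved_block(
    block_fn: Callable,
    out_times: np.ndarray,
    tau1: float,
    delta_t: float,
    dt: float = 2.5,
) -> np.ndarray:
    """Block waveform convolved with the unit-gain CO2 kernel.

    Evaluated on an internal uniform grid (``dt`` s) from t = 0 and sampled
    at ``out_times``.  The discrete kernel is normalized to unit sum so a
    long plateau asymptotes exactly to the block amplitude (unit
    steady-state gain); history before t = 0 is taken as zero.
    """
    out_times = np.asarray(out_times, dtype=float)
    t_hi = np.arange(0.0, out_times.max() + dt, dt)
    b = np.asarray(block_fn(t_hi - delta_t), dtype=float)
    k_t = np.arange(0.0, 10.0 * tau1 + dt, dt)
    kernel = k_t * np.exp(-k_t / tau1)
    kernel /= kernel.sum()
    conv = signal.fftconvolve(b, kernel)[: len(t_hi)]
    return np.interp(out_times, t_hi, conv)


def _activation_terms(
    block,
    timestamps: np.ndarray,
    tau1: float,
    tau2: float,
    delta_t: float,
    mode: str,
    dt: float = 2.5,
) -> tuple[np.ndarray, float, float]:
    """Raw activation term, its peak-to-peak, and the undecayed peak-to-peak."""
    timestamps = np.asarray(timestamps, dtype=float)
    fn = _as_block_fn(block, timestamps)
    if mode == "phantom":
        conv = np.asarray(fn(timestamps - delta_t), dtype=float)
    else:
        conv = _convolved_block(fn, timestamps, tau1, delta_t, dt)
    if mode == "fmpi":
        raw = conv * np.exp(-timestamps / tau2)
    else:  # bold / phantom: no tracer clearance
        raw = conv
    return raw, float(np.ptp(raw)), float(np.ptp(conv))


def activation_regressor(
    block,
    timestamps,
    tau1: float = REF_TAU1,
    tau2: float = REF_TAU2,
    delta_t: float = 0.0,
    mode: str = "fmpi",
    dt: float = 2.5,
) -> np.ndarray:
    """Unit peak-to-peak activation regressor at the frame timestamps.

    fmpi: (shifted block (*) CO2RF) * exp(-t/tau2); bold: clearance term set
    to 1; phantom: the shifted block itself.  Raises on a flat (degenerate)
    regressor, for which no peak-to-peak normalization exists.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    raw, ptp_raw, _ = _activation_terms(block, timestamps, tau1, tau2, delta_t, mode, dt)
    scale = max(1.0, float(np.max(np.abs(raw))) if raw.size else 1.0)
    if ptp_raw <= 1e-12 * scale:
        raise ValueError("activation regressor is flat; cannot normalize to unit peak-to-peak")
    return raw / ptp_raw


def build_design(
    timestamps,
    params: GLMParams,
    block,
    dt: float = 2.5,
) -> tuple[pd.DataFrame, dict]:
    """Design matrix (frames x regressors) plus normalization metadata.

    Columns: activation (unit peak-to-peak), constant, linear, quadratic
    (both centered and scaled to unit range for conditioning), transient
    ``exp(-t/tau_d)``; phantom mode appends a conditional linear drift that
    is zeroed while the phantom is out.  The metadata dictionary carries the
    factors needed to reference fitted amplitudes back to physical scale at
    t = 0 (see :func:`percent_change_map`).
    """
    t = np.asarray(timestamps, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 frames (more frames than regressors)")
    raw, ptp_raw, ptp_conv = _activation_terms(
        block, t, params.tau1, params.tau2, params.delta_t, params.mode, dt
    )
    scale = max(1.0, float(np.max(np.abs(raw))) if raw.size else 1.0)
    if ptp_raw <= 1e-12 * scale:
        raise ValueError("activation regressor is flat; check block/protocol inputs")
    activation = raw / ptp_raw

    t_span = float(np.ptp(t)) or 1.0
    lin = (t - t.mean()) / t_span
    quad_raw = lin**2
    quad_c = quad_raw - quad_raw.mean()
    quad_span = float(np.ptp(quad_c)) or 1.0
    quad = quad_c / quad_span
    transient = np.exp(-t / params.tau_d)

    cols = {
        "activation": activation,
        "constant": np.ones_like(t),
        "linear": lin,
        "quadratic": quad,
        "transient": transient,
    }
    if params.mode == "phantom":
        fn = _as_block_fn(block, t)
        present = np.asarray(fn(t - params.delta_t), dtype=float) >= 0.5
        cols["conditional_drift"] = lin * present

    design = pd.DataFrame(cols, index=pd.Index(t, name="time_s"))
    # drift polynomial evaluated at t = 0 in the scaled coordinates
    l0 = (0.0 - t.mean()) / t_span
    q0 = (l0**2 - quad_raw.mean()) / quad_span
    meta = {
        "ptp_ratio": ptp_conv / ptp_raw,  # undecayed / decayed peak-to-peak
        "l0": l0,
        "q0": q0,
    }
    return design, meta


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_voxel(values, design) -> tuple[np.ndarray, float]:
    """Ordinary least squares fit of one voxel time course.

    Returns (betas, residual_sd) with residual_sd = sqrt(SSR / (n - p)).
    Noiseless data generated from the same design is recovered to machine
    precision.
    """
    X = design.to_numpy() if hasattr(design, "to_numpy") else np.asarray(design, float)
    y = np.asarray(values, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    residual_sd = float(np.sqrt(resid @ resid / (n - p)))
    return beta, residual_sd


def fit_glm(
    frames,
    design,
    meta: dict | None = None,
    params: GLMParams | None = None,
    mask: np.ndarray | None = None,
) -> GLMFit:
    """Vectorized per-voxel OLS over an image series.

    ``frames`` is (T, ...spatial...); an optional boolean ``mask`` restricts
    the fit to in-mask voxels.  Produces coefficient, CNR, percent-change and
    p-value summaries per voxel (two-sided t test on the activation
    coefficient with n - p degrees of freedom).
    """
    X = design.to_numpy() if hasattr(design, "to_numpy") else np.asarray(design, float)
    names = list(design.columns) if hasattr(design, "columns") else [
        f"b{i}" for i in range(X.shape[1])
    ]
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    shape = frames.shape[1:]
    Y = frames.reshape(T, -1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        Y = Y[:, mask.ravel()]
    n, p = X.shape
    if n != T:
        raise ValueError("design and series lengths differ")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    dof = n - p
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    ssr = np.einsum("ij,ij->j", resid, resid)
    residual_sd = np.sqrt(ssr / dof)

    ia = names.index("activation")
    b_act = beta[ia]
    with np.errstate(divide="ignore", invalid="ignore"):
        cnr = b_act / residual_sd
    degenerate = (residual_sd == 0.0) | (np.abs(cnr) > CNR_CAP)
    if np.any(degenerate):
        warnings.warn("vanishing residual SD; CNR capped at sentinel", RuntimeWarning)
        cnr = np.where(degenerate, np.sign(b_act) * CNR_CAP, cnr)

    xtx_inv = np.linalg.inv(X.T @ X)
    se = residual_sd * np.sqrt(xtx_inv[ia, ia])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, b_act / np.where(se > 0, se, 1.0), np.sign(b_act) * np.inf)
    p_value = 2.0 * stats.t.sf(np.abs(t_stat), dof)

    meta = meta or {"ptp_ratio": 1.0, "l0": 0.0, "q0": 0.0}
    s0 = beta[names.index("constant")].copy()
    if "linear" in names:
        s0 = s0 + beta[names.index("linear")] * meta.get("l0", 0.0)
    if "quadratic" in names:
        s0 = s0 + beta[names.index("quadratic")] * meta.get("q0", 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 100.0 * b_act * meta.get("ptp_ratio", 1.0) / s0
    pc = np.where(s0 > 0, pc, np.nan)

    return GLMFit(
        betas=beta.T,
        names=names,
        residual_sd=residual_sd,
        cnr=cnr,
        percent_change=pc,
        t_stat=t_stat,
        p_value=p_value,
        dof=dof,
        params=params or GLMParams(),
        shape=shape,
        mask=mask,
    )


def optimize_params(
    series,
    block,
    tau1_bounds: tuple[float, float] = (5.0, 300.0),
    tau2_bounds: tuple[float, float] = (600.0, 30000.0),
    delta_grid: Sequence[float] = DELTA_T_GRID,
    mode: str = "fmpi",
    tau_d: float = 100.0,
    dt: float = 2.5,
    n_starts: int = 4,
    ss_tol: float = 1e-8,
) -> tuple[GLMParams, GLMFit]:
    """Grid/multistart search for the hemodynamic parameters.

    For each onset delay on the 5 s grid, (tau1, tau2) are found by
    Nelder-Mead minimization of the residual sum of squares of the in-mask
    mean time course, started from an ``n_starts x n_starts`` log-spaced
    coarse grid.  The overall arg-min is returned (ties broken by smallest
    |delta_t|, then the earlier delay), together with the voxelwise fit at
    those parameters.  A single global hemodynamic model is assumed:
    per-voxel time constants are not fitted.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    frames = np.asarray(series.frames, dtype=float)
    t = np.asarray(series.timestamps, dtype=float)
    mask = getattr(series, "mask", None)
    Y = frames.reshape(frames.shape[0], -1)
    if mask is not None:
        Y = Y[:, np.asarray(mask, bool).ravel()]
    y = Y.mean(axis=1)

    def ss_for(params: GLMParams) -> float:
        design, _ = build_design(t, params, block, dt=dt)
        X = design.to_numpy()
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    t1_starts = np.geomspace(tau1_bounds[0], tau1_bounds[1], n_starts)
    t2_starts = np.geomspace(tau2_bounds[0], tau2_bounds[1], n_starts)

    best: tuple[float, float, float] | None = None  # (ss, |dt|, dt)
    best_params: GLMParams | None = None
    any_converged = False
    diagnostics = []

    for d in delta_grid:
        if mode == "phantom":
            params = GLMParams(REF_TAU1, REF_TAU2, tau_d, float(d), mode)
            candidates = [(ss_for(params), params, True)]
        elif mode == "bold":
            candidates = []
            for t1 in t1_starts:
                res = optimize.minimize(
                    lambda x: ss_for(GLMParams(float(x[0]), REF_TAU2, tau_d, float(d), mode)),
                    np.array([t1]),
                    method="Nelder-Mead",
                    bounds=[tau1_bounds],
                    options={"fatol": ss_tol, "xatol": 1e-3, "maxiter": 200},
                )
                p = GLMParams(float(res.x[0]), REF_TAU2, tau_d, float(d), mode)
                candidates.append((float(res.fun), p, bool(res.success)))
                diagnostics.append((d, res.success, res.message))
        else:
            candidates = []
            for t1 in t1_starts:
                for t2 in t2_starts:
                    res = optimize.minimize(
                        lambda x: ss_for(
                            GLMParams(float(x[0]), float(x[1]), tau_d, float(d), mode)
                        ),
                        np.array([t1, t2]),
                        method="Nelder-Mead",
                        bounds=[tau1_bounds, tau2_bounds],
                        options={"fatol": ss_tol, "xatol": 1e-3, "maxiter": 300},
                    )
                    p = GLMParams(float(res.x[0]), float(res.x[1]), tau_d, float(d), mode)
                    candidates.append((float(res.fun), p, bool(res.success)))
                    diagnostics.append((d, res.success, res.message))
        for ss, p, ok in candidates:
            any_converged = any_converged or ok
            key = (ss, abs(p.delta_t), p.delta_t)
            if best is None:
                best, best_params = key, p
                continue
            rel = abs(ss - best[0]) <= 1e-9 * max(1.0, best[0])
            if (not rel and ss < best[0]) or (rel and key[1:] < best[1:]):
                best, best_params = (min(ss, best[0]),) + key[1:], p

    if not any_converged and mode != "phantom":
        raise RuntimeError(f"optimizer failed to converge at every start: {diagnostics}")
    assert best_params is not None
    design, meta = build_design(t, best_params, block, dt=dt)
    fit = fit_glm(frames, design, meta, best_params, mask=mask)
    return best_params, fit


# ---------------------------------------------------------------------------
# summary maps
# ---------------------------------------------------------------------------


def cnr_map(fit: GLMFit) -> np.ndarray:
    """Signed per-voxel contrast-to-noise ratio map.

    CNR = activation coefficient (peak-to-peak signal change, given the
    unit peak-to-peak regressor) divided by the residual SD.  Invariant to
    a global rescaling of the series.
    """
    return fit.map(fit.cnr)


def percent_change_map(fit: GLMFit) -> np.ndarray:
    """Percent signal change map, Delta-S / S x 100.

    The activation amplitude is corrected back to its undecayed (t = 0)
    envelope and referenced to the fitted drift baseline extrapolated to
    t = 0; voxels with a non-positive baseline are flagged nan.
    """
    return fit.map(fit.percent_change)


def activation_map(fit: GLMFit, alpha: float = 1e-12) -> np.ndarray:
    """Boolean activation map thresholded at family-wise level ``alpha``.

    ``alpha`` is interpreted as the already Bonferroni-corrected survival
    threshold on the per-voxel two-sided t-test p-value (the correction is
    not applied a second time).
    """
    return fit.map((fit.p_value < alpha).astype(float)) > 0.5


def blood_half_life(tau2: float) -> float:
    """Blood half-life t_1/2 = tau2 * ln 2 from the clearance constant."""
    return float(tau2) * float(np.log(2.0))


def tau2_from_half_life(t_half: float) -> float:
    """Inverse of :func:`blood_half_life`."""
    return float(t_half) / float(np.log(2.0))
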