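"""Synthetic study generator: phantoms, capnic physiology and measurement noise.

Everything downstream of the scanner (reconstruction, filtering, GLM,
sensitivity metrics) is exercised against data built here, so no external
dataset is required.  Three ingredient families:

* **Phantoms** — dilution series of point-like wells (sensitivity
  calibration) and an elliptical rat-brain blood-pool map with ~210 ng Fe
  per 3 mm voxel and 20x large-vessel hotspots.
* **Physiology** — an alternating hyper-/hypocapnia block protocol (5 min
  states, 3 cycles) whose cerebral blood volume response is the block
  convolved with the CO2 response kernel, scaled by the fractional CBV
  modulation (~25%) and multiplied by the tracer blood-clearance
  envelope exp(-t/tau2).
* **Noise** — a two-component model: thermal noise of SD sigma0 plus a
  signal-proportional instrumental gain term of fractional SD lambda
  (sigma_tot = sqrt(sigma0^2 + (lambda S)^2)), an alternating half-rotation
  gain imbalance that imprints 0.2 / 0.4 cycles-per-sample artifacts on the
  series, slow polynomial drifts, and an exponential warm-up transient.

The generator emulates instrumental statistics, not biology: it contains no
physiological noise (cardiac/respiratory signal modulation), no motion, and
no out-of-plane anatomy beyond the slices it is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .glm import _convolved_block, _as_block_fn
from .scanner_sim import SinogramSeries, TracerMap

__all__ = [
    "CapniaProtocol",
    "NoiseModel",
    "make_dilution_phantom",
    "make_brain_phantom",
    "capnia_block",
    "cbv_timecourse",
    "inject_noise",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_VOXEL_SIZE",
]

#: default phantom grid: 9 x 9 voxels of 3 mm (27 mm, inside the 30 mm FOV)
DEFAULT_GRID_SHAPE = (9, 9, 1)
DEFAULT_VOXEL_SIZE = (3.0, 3.0, 1.75)


@dataclass(frozen=True)
class CapniaProtocol:
    """Alternating hyper-/hypocapnia block protocol.

    5 min states (10 min cycle), three cycles, starting hypocapnic, with a
    fractional CBV modulation depth of 25% between states.
    """

    state_duration: float = 300.0  # s
    n_cycles: int = 3
    start_state: str = "hypo"
    delta_cbv_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.state_duration <= 0:
            raise ValueError("state_duration must be positive")
        if not 0.0 <= self.delta_cbv_fraction < 1.0:
            raise ValueError("delta_cbv_fraction must be in [0, 1)")
        if self.start_state not in ("hyper", "hypo"):
            raise ValueError("start_state must be 'hyper' or 'hypo'")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def total_duration(self) -> float:
        return 2.0 * self.state_duration * self.n_cycles

    def block(self, t) -> np.ndarray:
        """Hypercapnia indicator at absolute time t (vectorized).

        1 during hypercapnia, 0 during hypocapnia; outside the protocol span
        the starting state holds.
        """
        t = np.asarray(t, dtype=float)
        start_hyper = self.start_state == "hyper"
        inside = (t >= 0.0) & (t < self.total_duration)
        half = np.floor_divide(t, self.state_duration).astype(int)
        odd = (half % 2) == 1
        state = np.where(odd, not start_hyper, start_hyper)
        out = np.where(inside, state, start_hyper).astype(float)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class NoiseModel:
    """Two-component instrument noise plus structured artifacts.

    sigma0: additive thermal SD (A.U.); lambda_gain: fractional per-frame
    gain fluctuation (signal-proportional SD); quadrant_gain_delta:
    peak-to-peak gain imbalance between alternating half-rotation frames
    within a set (1% default, motivated by the drive-current stability
    figure); drift terms and warm-up transient default off.
    """

    sigma0: float = 0.0133  # A.U.
    lambda_gain: float = 0.017
    quadrant_gain_delta: float = 0.01
    drift_linear: float = 0.0  # A.U. / s
    drift_quadratic: float = 0.0  # A.U. / s^2
    transient_amplitude: float = 0.0  # A.U.
    transient_tau: float = 100.0  # s

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.lambda_gain < 0:
            raise ValueError("sigma0 and lambda_gain must be non-negative")
        if self.transient_tau <= 0:
            raise ValueError("transient_tau must be positive")

    def sigma_tot(self, signal_level) -> np.ndarray:
        """sigma_tot = sqrt(sigma0^2 + (lambda * S)^2)."""
        s = np.asarray(signal_level, dtype=float)
        return np.sqrt(self.sigma0**2 + (self.lambda_gain * s) ** 2)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def _empty_map(grid_shape, voxel_size, origin=(0.0, 0.0, 0.0)) -> TracerMap:
    return TracerMap(np.zeros(grid_shape), tuple(voxel_size), tuple(origin))


def _nearest_voxel(tracer: TracerMap, position) -> tuple[int, ...]:
    idx = []
    pos = list(position) + [0.0] * (3 - len(position))
    for axis in range(3):
        coords = tracer.axis_coords(axis)
        idx.append(int(np.argmin(np.abs(coords - pos[axis]))))
    return tuple(idx)


def make_dilution_phantom(
    top_mass: float,
    n_wells: int,
    dilution_factor: float | Sequence[float] = 0.5,
    well_positions: Sequence[Sequence[float]] | None = None,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> TracerMap:
    """Point-like dilution series: well k holds top_mass * prod(factors[:k]).

    ``dilution_factor`` is either a constant ratio between consecutive wells
    (0.5 gives the 250 / 125 / 62.5 / 31.25 / 15.625 ng series) or a
    per-step sequence (e.g. a large first dilution followed by halvings for
    the wide-range sensitivity series).  Wells occupy single voxels; default
    positions are spread along the x axis at y = 0.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if np.isscalar(dilution_factor):
        factors = [float(dilution_factor)] * (n_wells - 1)
    else:
        factors = [float(f) for f in dilution_factor]
        if len(factors) < n_wells - 1:
            raise ValueError("need a dilution factor per step between wells")
    masses = top_mass * np.concatenate([[1.0], np.cumprod(factors[: n_wells - 1])])
    tracer = _empty_map(grid_shape, voxel_size)
    if well_positions is None:
        xs = tracer.axis_coords(0)
        step = max(1, (len(xs) - 1) // max(1, n_wells - 1)) if n_wells > 1 else 1
        picks = [xs[min(i * step, len(xs) - 1)] for i in range(n_wells)]
        well_positions = [(x, 0.0, 0.0) for x in picks]
    if len(well_positions) != n_wells:
        raise ValueError("need one position per well")
    for pos, mass in zip(well_positions, masses):
        tracer.grid[_nearest_voxel(tracer, pos)] = mass
    return tracer


def make_brain_phantom(
    parenchyma_mass: float,
    vessel_positions: Sequence[Sequence[float]] = (),
    vessel_factor: float = 20.0,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    semi_axes: tuple[float, float] = (12.0, 9.0),
) -> TracerMap:
    """Elliptical brain blood-pool map with large-vessel hotspots.

    Voxels inside the in-plane ellipse carry ``parenchyma_mass`` ng
    (resting-brain estimate: ~210 ng per 3 mm voxel at a 10 mg/kg dose);
    listed vessel voxels carry ``vessel_factor`` times that (large vessels
    hold roughly 20x the blood volume of parenchyma).
    """
    if parenchyma_mass < 0:
        raise ValueError("parenchyma_mass must be non-negative")
    tracer = _empty_map(grid_shape, voxel_size)
    xs = tracer.axis_coords(0)
    ys = tracer.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = (gx / semi_axes[0]) ** 2 + (gy / semi_axes[1]) ** 2 <= 1.0
    tracer.grid[:, :, :] = parenchyma_mass * inside[:, :, None]
    for pos in vessel_positions:
        tracer.grid[_nearest_voxel(tracer, pos)] = parenchyma_mass * vessel_factor
    return tracer


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------


def capnia_block(protocol: CapniaProtocol, timestamps, delay: float = 0.0) -> np.ndarray:
    """Hypercapnia indicator (0/1) at each timestamp, edges shifted by delay."""
    t = np.asarray(timestamps, dtype=float)
    if t.ndim and np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted")
    return protocol.block(t - delay)


def cbv_timecourse(
    block,
    timestamps,
    tau1: float,
    tau2: float,
    baseline_mass: float,
    delta_fraction: float,
    dt: float = 2.5,
) -> np.ndarray:
    """Voxel Fe mass (ng) over time under a capnic block stimulus.

    mass(t) = baseline * (1 + delta * (block (*) CO2RF_norm)(t)) * exp(-t/tau2)

    with the CO2 kernel normalized to unit steady-state gain, so a long
    hypercapnic plateau asymptotes to baseline * (1 + delta) before
    clearance.  ``tau2`` may be ``numpy.inf`` to disable clearance.
    """
    if not tau1 > 0 or not tau2 > 0:
        raise ValueError("tau1 and tau2 must be positive")
    t = np.asarray(timestamps, dtype=float)
    fn = _as_block_fn(block, t)
    conv = _convolved_block(fn, t, tau1, delta_t=0.0, dt=dt)
    decay = np.exp(-t / tau2) if np.isfinite(tau2) else np.ones_like(t)
    return (baseline_mass + delta_fraction * baseline_mass * conv) * decay


# ---------------------------------------------------------------------------
# noise injection
# ---------------------------------------------------------------------------


def _quadrant_gains(n_frames: int, delta: float, set_size: int) -> np.ndarray:
    """Alternating half-rotation gain per acquired frame.

    Within each contiguous set the frames alternate upper/lower quadrant
    starting upper (pattern 1,0,1,0,1 for sets of 5); gaps re-trigger the
    pattern.  The repeating length-set_size pattern puts all its spectral
    power at multiples of 1/set_size cycles per sample (0.2 and 0.4 for
    sets of 5).
    """
    j = np.arange(n_frames) % set_size
    upper = (j % 2) == 0
    return np.where(upper, 1.0 + delta / 2.0, 1.0 - delta / 2.0)


def inject_noise(series, noise: NoiseModel, seed: int, set_size: int = 5):
    """Corrupt an image or sinogram series with the instrument noise model.

    Each frame value v at wall-clock time t and sample index i becomes

        g_i * v * (1 + eps_gain_i) + drift(t) + transient(t) + eps_thermal

    with eps_thermal ~ N(0, sigma0) per element, eps_gain ~ N(0, lambda) per
    frame, and g_i the alternating quadrant gain.  Deterministic given
    ``seed`` (an explicit seed is mandatory; there is no global RNG state).
    Accepts an image series (``frames`` array attribute) or a
    :class:`~fmpi.scanner_sim.SinogramSeries`; for complex sinogram values
    the thermal term is complex with ``sigma0`` per real/imaginary part.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    rng = np.random.default_rng(seed)

    if isinstance(series, SinogramSeries):
        t = series.timestamps
        n = len(series)
        g = _quadrant_gains(n, noise.quadrant_gain_delta, set_size)
        eps_gain = rng.normal(0.0, noise.lambda_gain, n) if noise.lambda_gain else np.zeros(n)
        drift = noise.drift_linear * t + noise.drift_quadratic * t**2
        trans = noise.transient_amplitude * np.exp(-t / noise.transient_tau)
        new_values = []
        for i, frame in enumerate(series.frames):
            v = frame.values * (g[i] * (1.0 + eps_gain[i]))
            v = v + (drift[i] + trans[i])
            if noise.sigma0:
                v = v + rng.normal(0.0, noise.sigma0, frame.values.shape) + 1j * rng.normal(
                    0.0, noise.sigma0, frame.values.shape
                )
            new_values.append(v)
        return series.with_values(new_values)

    frames = np.asarray(series.frames, dtype=float)
    t = np.asarray(series.timestamps, dtype=float)
    n = frames.shape[0]
    expand = (slice(None),) + (None,) * (frames.ndim - 1)
    g = _quadrant_gains(n, noise.quadrant_gain_delta, set_size)[expand]
    eps_gain = (
        rng.normal(0.0, noise.lambda_gain, n) if noise.lambda_gain else np.zeros(n)
    )[expand]
    drift = (noise.drift_linear * t + noise.drift_quadratic * t**2)[expand]
    trans = (noise.transient_amplitude * np.exp(-t / noise.transient_tau))[expand]
    thermal = rng.normal(0.0, noise.sigma0, frames.shape) if noise.sigma0 else 0.0
    corrupted = g * frames * (1.0 + eps_gain) + drift + trans + thermal
    return series.with_frames(corrupted)


# ---------------------------------------------------------------------------
# YAML / CSV interfaces
# ---------------------------------------------------------------------------


def protocol_events(protocol: CapniaProtocol) -> pd.DataFrame:
    """State-switch table (timestamp, state) mirroring the recorded switch."""
    times = np.arange(2 * protocol.n_cycles) * protocol.state_duration
    states = protocol.block(times + protocol.state_duration / 2.0).astype(int)
    return pd.DataFrame({"timestamp": times, "state": states})
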