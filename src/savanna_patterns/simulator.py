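"""Time integration of the spatial models on periodic grids.

All nonlocal terms are convolutions against fixed kernels, evaluated
spectrally (FFT) on the periodic box; time stepping is explicit RK4.
The nonlocal operator is bounded, so there is no diffusive stiffness and
the step size is limited only by the demographic rates.  Homogeneous ODE
equilibria are exact fixed points of the discrete dynamics because
discretized kernels carry exactly unit mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import SpatialGrid
from .kernels import Kernel, convolve, discretize
from .nonspatial import ModelParams

__all__ = [
    "SpatialGrid",
    "SpectralModel",
    "Trajectory",
    "simulate",
    "mode_growth_rate",
    "perturbed_homogeneous",
]

UNDERSHOOT_ABORT = 1e-8


@dataclass
class Trajectory:
    """Sampled states of one run plus conservation diagnostics."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, n_components, *grid.shape)
    grid: SpatialGrid
    manifest: dict
    max_simplex_deviation: float
    max_undershoot: float

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


class SpectralModel:
    """Right-hand side of a spatial variant with precomputed kernel FFTs.

    The state is an array of shape ``(n_components, *grid.shape)``:
    one component (G) for ``RL-GF``, four (G, S, T, F) otherwise.
    """

    def __init__(
        self, p: ModelParams, kernels: dict[str, Kernel], grid: SpatialGrid
    ):
        self.p = p
        self.grid = grid
        self.kernels = kernels
        self._khat: dict[str, np.ndarray] = {}
        roles = ["w", "JF"] + (["JT"] if p.variant != "RL-GF" else [])
        if p.resource_limited:
            roles.append("R")
        fft = np.fft.rfft if grid.dim == 1 else np.fft.rfft2
        for role in roles:
            self._khat[role] = fft(discretize(kernels[role], grid))

    @property
    def n_components(self) -> int:
        return 1 if self.p.variant == "RL-GF" else 4

    def conv(self, role: str, f: np.ndarray) -> np.ndarray:
        g = self.grid
        if g.dim == 1:
            return np.fft.irfft(np.fft.rfft(f) * self._khat[role], n=g.n) * g.dx
        return (
            np.fft.irfft2(np.fft.rfft2(f) * self._khat[role], s=g.shape)
            * g.cell_volume
        )

    def rhs(self, u: np.ndarray) -> np.ndarray:
        p = self.p
        if p.variant == "RL-GF":
            g = u[0]
            wg = np.clip(self.conv("w", g), 0.0, 1.0)
            jg = self.conv("JF", g)
            rg = self.conv("R", g)
            dg = (1.0 - g) * p.phi(wg) - p.alpha * g * (1.0 - jg) * (
                1.0 - 1.0 / p.r + rg / p.r
            )
            return dg[None]
        g, s, t, f = u
        wg = np.clip(self.conv("w", g), 0.0, 1.0)
        jf = self.conv("JF", f)
        jt = self.conv("JT", t)
        phi_g = p.phi(wg)
        om = p.omega(wg)
        if p.resource_limited:
            growth = p.alpha * jf * (1.0 - self.conv("R", f) / p.r)
        else:
            growth = p.alpha * jf
        dg = p.mu * s + p.nu * t + phi_g * f - growth * g - p.beta * g * jt
        ds = -p.mu * s - om * s - growth * s + p.beta * g * jt
        dt = -p.nu * t + om * s - growth * t
        df = growth * (g + s + t) - phi_g * f
        return np.stack([dg, ds, dt, df])

    def stable_dt_estimate(self) -> float:
        """Crude bound from the largest demographic rate; RK4 allows ~2.8/|L|."""
        p = self.p
        slope = 0.0
        for resp in (p.phi, p.omega):
            if resp.shape == "sigmoid":
                slope = max(slope, abs(resp.right - resp.left) / (4 * resp.slope))
        rate = max(p.alpha * (1 + 1 / p.r if p.resource_limited else 1),
                   p.beta, p.mu, p.nu, slope, 1.0)
        return 2.5 / rate

    def step(self, u: np.ndarray, dt: float) -> np.ndarray:
        """One explicit RK4 step."""
        k1 = self.rhs(u)
        k2 = self.rhs(u + 0.5 * dt * k1)
        k3 = self.rhs(u + 0.5 * dt * k2)
        k4 = self.rhs(u + dt * k3)
        return u + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def perturbed_homogeneous(
    values: np.ndarray,
    grid: SpatialGrid,
    amplitude: float = 1e-2,
    mode: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Homogeneous state plus a small perturbation.

    ``mode`` seeds a single cosine mode on the first component (compensated
    on the last so the simplex is preserved); otherwise white noise from
    ``seed`` is used.  ``amplitude == 0`` returns the exact homogeneous state.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    u = np.stack([np.full(grid.shape, v) for v in values])
    if amplitude == 0.0:
        return u
    if mode is not None:
        xs = grid.x
        pert = amplitude * (
            np.cos(grid.mode_wavenumber(mode) * xs)
            if grid.dim == 1
            else np.cos(grid.mode_wavenumber(mode) * xs)[:, None]
            * np.ones(grid.n)[None, :]
        )
    else:
        rng = np.random.default_rng(seed)
        pert = amplitude * rng.standard_normal(grid.shape)
        pert -= pert.mean()
    u[0] += pert
    u[-1] -= pert if len(u) > 1 else 0.0
    if len(u) == 1:
        u[0] = np.clip(u[0], 0.0, 1.0)
    return u


def simulate(
    initial: np.ndarray,
    p: ModelParams,
    kernels: dict[str, Kernel],
    grid: SpatialGrid,
    t_final: float,
    dt: float = 1e-3,
    sample_every: int | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Integrate to ``t_final``, sampling states at a fixed stride.

    Raises if the solution develops NaNs or undershoots below
    ``-UNDERSHOOT_ABORT``; smaller negative excursions are clipped and the
    worst one recorded in the trajectory diagnostics.
    """
    model = SpectralModel(p, kernels, grid)
    if dt > model.stable_dt_estimate():
        warnings.warn(
            f"dt={dt} exceeds the stability estimate "
            f"{model.stable_dt_estimate():.3g}; the run may blow up",
            stacklevel=2,
        )
    n_steps = int(round(t_final / dt))
    if sample_every is None:
        sample_every = max(n_steps // 50, 1)
    u = np.asarray(initial, dtype=float).copy()
    times = [0.0]
    samples = [u.copy()]
    max_dev = 0.0
    max_under = 0.0
    for i in range(1, n_steps + 1):
        u = model.step(u, dt)
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(f"non-finite state at t={i * dt:.4g}")
        low = float(u.min())
        if low < -UNDERSHOOT_ABORT:
            raise FloatingPointError(
                f"cover fraction undershoot {low:.3g} at t={i * dt:.4g}; "
                "reduce dt"
            )
        if low < 0:
            max_under = max(max_under, -low)
            u = np.clip(u, 0.0, None)
        if len(u) > 1:
            max_dev = max(max_dev, float(np.max(np.abs(u.sum(axis=0) - 1.0))))
        else:
            max_dev = max(max_dev, float(max(u.max() - 1.0, -u.min(), 0.0)))
        if i % sample_every == 0 or i == n_steps:
            times.append(i * dt)
            samples.append(u.copy())
    manifest = {
        "variant": p.variant,
        "alpha": p.alpha,
        "r": p.r if p.resource_limited else None,
        "grid": {"n": grid.n, "half_width": grid.half_width, "dim": grid.dim},
        "dt": dt,
        "t_final": t_final,
        "scheme": "rk4-spectral",
        "seed": seed,
        "kernels": {
            k: {"family": v.family, "sigma": v.sigma} for k, v in kernels.items()
        },
    }
    return Trajectory(
        np.array(times), np.array(samples), grid, manifest, max_dev, max_under
    )


def mode_growth_rate(
    traj: Trajectory,
    mode: int,
    component: int = 0,
    linear_limit: float = 1e-3,
) -> float:
    """Exponential growth rate of one Fourier mode, by least squares.

    Fits the slope of ``log |amplitude|`` against time while the amplitude
    stays within the linear regime; warns and truncates the window if the
    perturbation grows beyond it.
    """
    if traj.grid.dim != 1:
        raise NotImplementedError("mode tracking is 1D only")
    amps = np.array(
        [np.abs(np.fft.rfft(s[component])[mode]) / traj.grid.n for s in traj.states]
    )
    keep = amps > 1e-15
    window = keep & (amps < linear_limit)
    if window.sum() < max(3, int(0.5 * keep.sum())):
        warnings.warn(
            "perturbation left the linear regime; fitting the early window only",
            stacklevel=2,
        )
    if window.sum() < 3:
        window = keep
    t = traj.times[window]
    y = np.log(amps[window])
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)
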