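"""Interaction kernels: fire spread, seed dispersal and resource competition.

Every spatial interaction in the model is a convolution against a
probability-density kernel.  The stability theory rests on three
hypotheses about these kernels:

* H1 — unit mass, so homogeneous ODE equilibria are exact steady states
  of the spatial model;
* H2 — evenness (isotropy), so Fourier transforms are real;
* H4 — density maximal at the origin, a convenient sufficient condition
  for a nonnegative (positive-definite) Fourier transform.

Built-in families (Gaussian, Laplace, uniform, Dirac) carry closed-form
transforms; arbitrary tabulated kernels are supported with numerical
transforms and an explicit hypothesis report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import SpatialGrid

__all__ = [
    "Kernel",
    "KernelReport",
    "make_gaussian",
    "make_laplace",
    "make_uniform",
    "make_dirac",
    "make_custom",
    "fourier_transform",
    "check_hypotheses",
    "discretize",
    "convolve",
    "direct_convolve",
]

#: number of periodic images summed when wrapping a kernel onto the box
N_WRAP_IMAGES = 3

H1_TOL = 1e-8
H2_TOL = 1e-8
POSDEF_TOL = -1e-10


@dataclass(frozen=True)
class Kernel:
    """A symmetric, normalized interaction profile.

    ``sigma`` is the standard deviation in the length unit of the domain
    (ignored for ``dirac``).  ``custom`` kernels carry tabulated values on
    the offsets of a grid (FFT order) and are renormalized on discretization.
    """

    family: str
    sigma: float = 0.0
    dim: int = 1
    values: np.ndarray | None = field(default=None, repr=False)
    grid: SpatialGrid | None = field(default=None, repr=False)

    def density(self, x: np.ndarray | float) -> np.ndarray:
        """Kernel density at displacement ``x`` (1D) or radius-vector norm (2D)."""
        x = np.asarray(x, dtype=float)
        s = self.sigma
        if self.family == "gaussian":
            norm = (2 * np.pi * s**2) ** (-self.dim / 2)
            return norm * np.exp(-(x**2) / (2 * s**2))
        if self.family == "laplace":
            b = s / np.sqrt(2.0)  # std sigma -> Laplace scale
            return np.exp(-np.abs(x) / b) / (2 * b)
        if self.family == "uniform":
            a = s * np.sqrt(3.0)  # std sigma -> half-width
            return np.where(np.abs(x) <= a, 1.0 / (2 * a), 0.0)
        if self.family == "dirac":
            raise ValueError("dirac kernel has no pointwise density")
        if self.family == "custom":
            order = np.argsort(self.grid.offsets)
            return np.interp(
                x, self.grid.offsets[order], self.values[order], left=0.0, right=0.0
            )
        raise ValueError(f"unknown kernel family {self.family!r}")


@dataclass(frozen=True)
class KernelReport:
    """Result of checking H1/H2/H4 and positive-definiteness numerically."""

    mass_deviation: float
    evenness_deviation: float
    min_fourier: float
    h4_holds: bool

    @property
    def h1_holds(self) -> bool:
        return self.mass_deviation <= H1_TOL

    @property
    def h2_holds(self) -> bool:
        return self.evenness_deviation <= H2_TOL

    @property
    def positive_definite(self) -> bool:
        return self.min_fourier >= POSDEF_TOL


def make_gaussian(sigma: float, dim: int = 1) -> Kernel:
    """Zero-mean isotropic Gaussian kernel with standard deviation ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return Kernel("gaussian", float(sigma), dim)


def make_laplace(sigma: float, dim: int = 1) -> Kernel:
    """Laplace (double-exponential) kernel with standard deviation ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if dim != 1:
        raise ValueError("laplace kernel implemented in 1D only")
    return Kernel("laplace", float(sigma), dim)


def make_uniform(sigma: float, dim: int = 1) -> Kernel:
    """Uniform (top-hat) kernel with standard deviation ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if dim != 1:
        raise ValueError("uniform kernel implemented in 1D only")
    return Kernel("uniform", float(sigma), dim)


def make_dirac(dim: int = 1) -> Kernel:
    """Dirac kernel: purely local interaction, transform identically 1."""
    return Kernel("dirac", 0.0, dim)


def make_custom(values: np.ndarray, grid: SpatialGrid) -> Kernel:
    """Kernel tabulated on the offsets of ``grid`` (FFT order), 1D only.

    Values are renormalized to unit discrete mass.  Evenness is *not*
    enforced; use :func:`check_hypotheses` before trusting transforms.
    """
    if grid.dim != 1:
        raise ValueError("custom kernels are 1D only")
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n,):
        raise ValueError("values must match the grid")
    if np.any(values < 0):
        raise ValueError("kernel density must be nonnegative")
    values = values / (values.sum() * grid.dx)
    return Kernel("custom", 0.0, 1, values=values, grid=grid)


def fourier_transform(kernel: Kernel, xi: np.ndarray | float) -> np.ndarray | float:
    """Real Fourier transform ``k_hat(|xi|)`` of a symmetric kernel.

    Closed forms for the built-in families; discrete cosine quadrature for
    tabulated kernels (rejected if they fail evenness beyond tolerance,
    since the transform would be complex).
    """
    xi = np.abs(np.asarray(xi, dtype=float))
    s = kernel.sigma
    if kernel.family == "gaussian":
        out = np.exp(-(s**2) * xi**2 / 2.0)
    elif kernel.family == "laplace":
        b = s / np.sqrt(2.0)
        out = 1.0 / (1.0 + b**2 * xi**2)
    elif kernel.family == "uniform":
        a = s * np.sqrt(3.0)
        out = np.sinc(a * xi / np.pi)  # sin(a xi)/(a xi)
    elif kernel.family == "dirac":
        out = np.ones_like(xi)
    elif kernel.family == "custom":
        if _evenness_deviation(kernel.values) > 1e-6:
            raise ValueError(
                "custom kernel is not even within tolerance; "
                "its Fourier transform would be complex"
            )
        xs = kernel.grid.offsets
        out = np.array(
            [np.sum(kernel.values * np.cos(x * xs)) * kernel.grid.dx
             for x in np.atleast_1d(xi)]
        )
        out = out.reshape(np.shape(xi))
    else:  # pragma: no cover
        raise ValueError(f"unknown kernel family {kernel.family!r}")
    return float(out) if np.isscalar(xi) or out.ndim == 0 else out


def _evenness_deviation(values: np.ndarray) -> float:
    # FFT-order tabulation: evenness means k[j] == k[-j mod N]
    n = len(values)
    return float(np.max(np.abs(values - values[(-np.arange(n)) % n])))


def check_hypotheses(
    kernel: Kernel, xi_max: float = 200.0, n_xi: int = 2001
) -> KernelReport:
    """Numerically check H1 (mass), H2 (evenness) and H4 (max at zero).

    The minimum of the Fourier transform over ``[0, xi_max]`` decides
    positive definiteness up to the scan resolution.
    """
    xi = np.linspace(0.0, xi_max, n_xi)
    if kernel.family == "dirac":
        return KernelReport(0.0, 0.0, 1.0, True)
    if kernel.family == "custom":
        mass = float(abs(np.sum(kernel.values) * kernel.grid.dx - 1.0))
        even_dev = _evenness_deviation(kernel.values)
        sym = 0.5 * (
            kernel.values + kernel.values[(-np.arange(kernel.grid.n)) % kernel.grid.n]
        )
        symk = make_custom(np.maximum(sym, 0.0), kernel.grid)
        ft = fourier_transform(symk, xi)
        h4 = bool(np.argmax(kernel.values) == 0)  # offset 0 is index 0 in FFT order
        return KernelReport(mass, even_dev, float(np.min(ft)), h4)
    # analytic families: H1/H2 exact, H4 true, transform scanned
    ft = fourier_transform(kernel, xi)
    return KernelReport(0.0, 0.0, float(np.min(ft)), True)


def discretize(kernel: Kernel, grid: SpatialGrid) -> np.ndarray:
    """Sample a kernel on the periodic grid, wrapped and renormalized.

    The density is summed over ``N_WRAP_IMAGES`` periodic images and then
    rescaled so that ``sum * cell_volume == 1`` exactly.  This enforces the
    discrete analogue of H1, making homogeneous ODE equilibria exact fixed
    points of the discretized dynamics.

    Returns the kernel in FFT order (center at index 0).
    """
    if kernel.family == "dirac":
        out = np.zeros(grid.shape)
        out[(0,) * grid.dim] = 1.0 / grid.cell_volume
        return out
    if kernel.family == "custom":
        if kernel.grid is not None and kernel.grid.n != grid.n:
            raise ValueError("custom kernel tabulated on a different grid")
        vals = kernel.values.copy()
        return vals / (vals.sum() * grid.cell_volume)
    if kernel.sigma > grid.half_width / 2:
        warnings.warn(
            f"kernel sigma={kernel.sigma} exceeds a quarter of the domain "
            f"length {grid.length}; periodic wrap-around distorts its shape",
            stacklevel=2,
        )
    offs = grid.offsets
    if grid.dim == 1:
        out = np.zeros(grid.n)
        for m in range(-N_WRAP_IMAGES, N_WRAP_IMAGES + 1):
            out += kernel.density(offs + m * grid.length)
    else:
        ox, oy = np.meshgrid(offs, offs, indexing="ij")
        out = np.zeros((grid.n, grid.n))
        for mx in range(-N_WRAP_IMAGES, N_WRAP_IMAGES + 1):
            for my in range(-N_WRAP_IMAGES, N_WRAP_IMAGES + 1):
                rad = np.hypot(ox + mx * grid.length, oy + my * grid.length)
                out += kernel.density(rad)
    return out / (out.sum() * grid.cell_volume)


def convolve(f: np.ndarray, k_disc: np.ndarray, grid: SpatialGrid) -> np.ndarray:
    """Periodic convolution ``(k * f)`` of a field with a discretized kernel."""
    if grid.dim == 1:
        return np.fft.irfft(np.fft.rfft(f) * np.fft.rfft(k_disc), n=grid.n) * grid.dx
    return (
        np.fft.irfft2(np.fft.rfft2(f) * np.fft.rfft2(k_disc), s=grid.shape)
        * grid.cell_volume
    )


def direct_convolve(f: np.ndarray, k_disc: np.ndarray, grid: SpatialGrid) -> np.ndarray:
    """Direct-sum periodic convolution (quadratic cost; oracle for the FFT path)."""
    if grid.dim != 1:
        raise NotImplementedError("direct-sum oracle is 1D only")
    n = grid.n
    out = np.empty(n)
    for i in range(n):
        out[i] = np.sum(k_disc[(i - np.arange(n)) % n] * f) * grid.dx
    return out
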