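"""Periodic spatial grids for the nonlocal vegetation models.

The models are posed on a periodic box ``[-L, L]^dim``.  All spatial
structure (kernels, fields, spectral operators) is sampled on a uniform
grid of ``N`` points per dimension; the admissible perturbation
wavenumbers are then integer multiples of the fundamental ``pi / L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpatialGrid"]


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform periodic grid on ``[-L, L]^dim``.

    Parameters
    ----------
    n : int
        Points per dimension.  A power of two >= 64 keeps the FFTs fast;
        smaller values are allowed for oracle tests.
    half_width : float
        Domain half-width ``L`` (default ``pi``, i.e. the box ``[-pi, pi]``).
    dim : int
        1 or 2.
    """

    n: int = 256
    half_width: float = np.pi
    dim: int = 1

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")
        if self.n < 4:
            raise ValueError("need at least 4 grid points")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    @property
    def length(self) -> float:
        """Period of the domain, ``2 L``."""
        return 2.0 * self.half_width

    @property
    def dx(self) -> float:
        return self.length / self.n

    @property
    def cell_volume(self) -> float:
        return self.dx**self.dim

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.n,) * self.dim

    @property
    def x(self) -> np.ndarray:
        """Grid coordinates along one axis, ``[-L, L)``."""
        return -self.half_width + self.dx * np.arange(self.n)

    @property
    def offsets(self) -> np.ndarray:
        """Signed displacements in FFT order (0, dx, ..., -dx)."""
        return np.fft.fftfreq(self.n, d=1.0 / (self.n * self.dx))

    @property
    def fundamental_wavenumber(self) -> float:
        """Smallest nonzero wavenumber supported by the box, ``pi / L``."""
        return np.pi / self.half_width

    def wavenumbers(self) -> np.ndarray:
        """FFT-ordered wavenumbers along one axis."""
        return 2 * np.pi * np.fft.fftfreq(self.n, d=self.dx)

    def mode_wavenumber(self, k: int) -> float:
        """Physical wavenumber of integer mode ``k`` on this box."""
        return k * self.fundamental_wavenumber
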