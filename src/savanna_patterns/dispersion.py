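"""Linear stability of homogeneous states in the spatial models.

A homogeneous equilibrium is perturbed by a Fourier mode of wavenumber
``xi``; the growth rate of the mode is an eigenvalue ``lambda_xi`` of a
wavenumber-dependent coefficient matrix in which every nonlocal term is
multiplied by the kernel's Fourier transform.  A Turing (pattern-forming)
instability requires ``lambda_0 < 0`` (ODE stability), ``lambda_xi > 0``
for some nonzero ``xi``, and decay of ``lambda_xi`` at large ``|xi|``.

For the resource-limited grass-forest model the spectrum is scalar,

    lambda_xi = A w_hat + B R_hat + C JF_hat + D,

with coefficients A >= 0, B < 0, C > 0, D < 0 at interior equilibria.
``A + C + D =: N`` is a kernel-independent *necessary* condition
(``N > 0``) for instability when the kernels are positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kernels import Kernel, fourier_transform
from .nonspatial import (
    Equilibrium,
    HomogeneousState,
    ModelParams,
    find_equilibria,
)

__all__ = [
    "coefficients_ABCD",
    "dispersion_gf",
    "dispersion_all_grass",
    "max_dispersion_gf",
    "necessary_condition_N",
    "sl4_matrix",
    "dispersion_sl4",
    "forest_eigenvalue_sl4",
    "reduced_block_sl4",
    "routh_hurwitz_3",
    "turing_scan",
    "turing_onset",
    "sigma_r_persistence_threshold",
    "default_xi_grid",
    "DispersionCurve",
    "TuringMap",
]


def default_xi_grid(xi_max: float = 200.0, n: int = 4000) -> np.ndarray:
    """Log-spaced positive wavenumbers for scanning the dispersion maximum."""
    return np.logspace(-2, np.log10(xi_max), n)


# ---------------------------------------------------------------------------
# grass-forest (scalar) dispersion

def coefficients_ABCD(g_bar: float, p: ModelParams) -> tuple[float, float, float, float]:
    """Coefficients of the scalar dispersion relation at an interior state.

    ``A = phi'(G)(1-G)``, ``B = -(alpha/r) G (1-G)``,
    ``C = alpha G (1-(1-G)/r)``, ``D = -alpha (1-G)(1-(1-G)/r) - phi(G)``.
    At equilibria the sign pattern is (>=0, <0, >0, <0) and
    ``A+B+C+D`` is the nonspatial growth rate ``lambda_0``.
    """
    if not 0.0 < g_bar < 1.0:
        raise ValueError(
            "coefficients are defined for interior states only; "
            "use dispersion_all_grass for the G=1 boundary state"
        )
    a, r = p.alpha, p.r
    A = p.phi.derivative(g_bar) * (1.0 - g_bar)
    B = -(a / r) * g_bar * (1.0 - g_bar)
    C = a * g_bar * (1.0 - (1.0 - g_bar) / r)
    D = -a * (1.0 - g_bar) * (1.0 - (1.0 - g_bar) / r) - p.phi(g_bar)
    return A, B, C, D


def dispersion_gf(
    g_bar: float,
    p: ModelParams,
    kernels: dict[str, Kernel],
    xi: np.ndarray | float,
) -> np.ndarray | float:
    """Scalar growth rate ``lambda_xi`` at an interior grass-forest state.

    ``kernels`` maps roles ``"w"`` (fire), ``"JF"`` (forest seed) and
    ``"R"`` (resource competition) to kernels.  Even in ``xi``; tends to
    ``D < 0`` as ``|xi| -> infinity``.
    """
    A, B, C, D = coefficients_ABCD(g_bar, p)
    out = (
        A * fourier_transform(kernels["w"], xi)
        + B * fourier_transform(kernels["R"], xi)
        + C * fourier_transform(kernels["JF"], xi)
        + D
    )
    return out


def dispersion_all_grass(
    p: ModelParams, kernels: dict[str, Kernel], xi: np.ndarray | float
) -> np.ndarray | float:
    """Growth rate at the all-grass state: ``-phi(1) + alpha JF_hat(|xi|)``.

    Its supremum over all wavenumbers is ``alpha - phi(1)``, attained at
    ``xi = 0``, so a stable all-grass state cannot lose stability to any
    positive-definite spatial interaction.
    """
    return -p.phi(1.0) + p.alpha * fourier_transform(kernels["JF"], xi)


def max_dispersion_gf(
    g_bar: float,
    p: ModelParams,
    kernels: dict[str, Kernel],
    xi: np.ndarray | None = None,
) -> float:
    """Maximum of ``lambda_xi`` over a nonzero-wavenumber grid."""
    xi = default_xi_grid() if xi is None else np.asarray(xi)
    return float(np.max(dispersion_gf(g_bar, p, kernels, xi)))


def necessary_condition_N(p: ModelParams) -> tuple[list[float], float | None]:
    """``N = A + C + D`` for every ODE-stable interior equilibrium.

    ``N > 0`` is necessary for a pattern-forming instability under
    positive-definite kernels, and does not depend on the kernels at all.
    Returns the per-equilibrium values and their maximum (the bistable-cell
    convention), or ``None`` if no stable interior equilibrium exists; the
    all-grass state is excluded (it can never destabilize spatially).
    """
    ns = []
    for eq in find_equilibria(p):
        if not eq.stable or eq.is_all_grass:
            continue
        A, _, C, D = coefficients_ABCD(eq.G, p)
        ns.append(A + C + D)
    return ns, (max(ns) if ns else None)


# ---------------------------------------------------------------------------
# four-type dispersion

def sl4_matrix(
    state: HomogeneousState,
    p: ModelParams,
    w_hat: float,
    jf_hat: float,
    jt_hat: float,
    r_hat: float = 1.0,
) -> np.ndarray:
    """Wavenumber-dependent 4x4 stability matrix of the four-type models.

    Rows/columns order the perturbations (g, s, tau, f).  For ``SL4`` the
    resource transform is ignored; for ``RL-SL4`` the forest row decouples
    and carries the grass-forest dispersion relation.  Fire-response
    derivative terms are included for sigmoid responses and vanish for
    heaviside ones.
    """
    g, s, t, f = state.as_array()
    a, b, mu, nu = p.alpha, p.beta, p.mu, p.nu
    phi_g, om = p.phi(g), p.omega(g)
    dphi, dom = p.phi.derivative(g), p.omega.derivative(g)
    if p.variant == "RL-SL4" or (p.variant == "RL-GF"):
        r = p.r
        gr = a * f * (1.0 - f / r)
        res = a * f * (jf_hat + r_hat) / r
        M = np.array(
            [
                [dphi * f * w_hat - b * t - gr, mu, nu - b * g * jt_hat,
                 phi_g - a * g * jf_hat + g * res],
                [b * t - dom * s * w_hat, -mu - om - gr, b * g * jt_hat,
                 -a * s * jf_hat + s * res],
                [dom * s * w_hat, om, -nu - gr, -a * t * jf_hat + t * res],
                [-dphi * f * w_hat, 0.0, 0.0,
                 a * (1 - f) * jf_hat - phi_g - gr - (1 - f) * res],
            ]
        )
        return M
    # standard SL4 (no resource limitation)
    M = np.array(
        [
            [dphi * f * w_hat - a * f - b * t, mu, nu - b * g * jt_hat,
             phi_g - a * g * jf_hat],
            [b * t - dom * s * w_hat, -mu - a * f - om, b * g * jt_hat,
             -a * s * jf_hat],
            [dom * s * w_hat, om, -nu - a * f, -a * t * jf_hat],
            [-dphi * f * w_hat, 0.0, 0.0, a * (1 - f) * jf_hat - a * f - phi_g],
        ]
    )
    return M


def dispersion_sl4(
    state: HomogeneousState,
    p: ModelParams,
    kernels: dict[str, Kernel],
    xi: float,
) -> np.ndarray:
    """Eigenvalues (4 complex values) of the stability matrix at wavenumber xi.

    ``kernels`` maps roles "w", "JF", "JT" and (for RL-SL4) "R".
    """
    arr = state.as_array()
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError("state off the simplex")
    w_hat = fourier_transform(kernels["w"], xi)
    jf_hat = fourier_transform(kernels["JF"], xi)
    jt_hat = fourier_transform(kernels["JT"], xi)
    r_hat = fourier_transform(kernels["R"], xi) if "R" in kernels else 1.0
    M = sl4_matrix(state, p, w_hat, jf_hat, jt_hat, r_hat)
    return np.linalg.eigvals(M)


def forest_eigenvalue_sl4(
    state: HomogeneousState,
    p: ModelParams,
    kernels: dict[str, Kernel],
    xi: np.ndarray | float,
) -> np.ndarray | float:
    """Decoupled forest component of the spectrum (heaviside responses).

    SL4:     ``alpha (1-F) JF_hat - alpha F - phi(G)``;
    RL-SL4:  ``alpha (1-F)(1-F/r) JF_hat - (alpha/r) F (1-F) R_hat
              - alpha F (1-F/r) - phi(G)`` — the grass-forest dispersion
    relation, so the scalar analysis transfers verbatim.
    """
    f, g = state.F, state.G
    a = p.alpha
    jf = fourier_transform(kernels["JF"], xi)
    if p.variant == "SL4":
        return a * (1 - f) * jf - a * f - p.phi(g)
    r = p.r
    rh = fourier_transform(kernels["R"], xi)
    return (
        a * (1 - f) * (1 - f / r) * jf
        - (a / r) * f * (1 - f) * rh
        - a * f * (1 - f / r)
        - p.phi(g)
    )


def reduced_block_sl4(
    state: HomogeneousState, p: ModelParams, jt_hat: float
) -> np.ndarray:
    """3x3 (g, s, tau) block left after factoring out the forest eigenvalue.

    Valid for heaviside fire responses (derivative terms vanish).
    """
    g, s, t, f = state.as_array()
    a, b, mu, nu = p.alpha, p.beta, p.mu, p.nu
    om = p.omega(g)
    gr = a * f * (1.0 - f / p.r) if p.resource_limited else a * f
    return np.array(
        [
            [-b * t - gr, mu, nu - b * g * jt_hat],
            [b * t, -mu - om - gr, b * g * jt_hat],
            [0.0, om, -nu - gr],
        ]
    )


def routh_hurwitz_3(a2: float, a1: float, a0: float) -> bool:
    """Stability test for ``lambda^3 + a2 lambda^2 + a1 lambda + a0``.

    True iff every root has negative real part: ``a2 > 0``, ``a0 > 0`` and
    ``a2 a1 > a0``.
    """
    return a2 > 0 and a0 > 0 and a2 * a1 > a0


# ---------------------------------------------------------------------------
# Turing scans and onset location

@dataclass(frozen=True)
class DispersionCurve:
    """Dispersion relation of one equilibrium sampled on a wavenumber grid."""

    equilibrium: Equilibrium
    xi: np.ndarray
    growth: np.ndarray  # real parts (scalar model: the value itself)

    @property
    def max_nonzero(self) -> float:
        return float(np.max(self.growth))

    @property
    def critical_xi(self) -> float:
        return float(self.xi[np.argmax(self.growth)])


@dataclass(frozen=True)
class TuringMap:
    """Per-cell dispersion maximum over stable equilibria on a parameter grid."""

    axes: tuple[str, str]
    values_1: np.ndarray
    values_2: np.ndarray
    max_growth: np.ndarray  # NaN where no stable equilibrium exists
    max_N: np.ndarray  # kernel-free necessary-condition value, NaN likewise

    @property
    def turing_space(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.max_growth > 0


def _stable_interior(p: ModelParams) -> list[Equilibrium]:
    return [e for e in find_equilibria(p) if e.stable and not e.is_all_grass]


def turing_scan(
    p: ModelParams,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    kernels: dict[str, Kernel],
    xi: np.ndarray | None = None,
) -> TuringMap:
    """Dispersion maximum over stable interior equilibria on a 2-parameter grid.

    Cells with no stable interior equilibrium are NaN (absent), not zero.
    Bistable cells take the maximum across both stable equilibria.
    """
    xi = default_xi_grid() if xi is None else np.asarray(xi)
    name1, vals1 = axis1
    name2, vals2 = axis2
    wv = fourier_transform(kernels["w"], xi)
    rv = fourier_transform(kernels["R"], xi)
    fv = fourier_transform(kernels["JF"], xi)
    mg = np.full((len(vals1), len(vals2)), np.nan)
    mn = np.full((len(vals1), len(vals2)), np.nan)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            pij = p.with_(**{name1: float(v1), name2: float(v2)})
            best_g, best_n = -np.inf, -np.inf
            for eq in _stable_interior(pij):
                A, B, C, D = coefficients_ABCD(eq.G, pij)
                lam = A * wv + B * rv + C * fv + D
                best_g = max(best_g, float(np.max(lam)))
                best_n = max(best_n, A + C + D)
            if np.isfinite(best_g):
                mg[i, j] = best_g
                mn[i, j] = best_n
    return TuringMap(
        (name1, name2), np.asarray(vals1, float), np.asarray(vals2, float), mg, mn
    )


def sigma_r_persistence_threshold(
    p: ModelParams,
    sigma_w: float,
    sigma_f: float,
    sigma_r_values: np.ndarray,
    r_values: np.ndarray,
    alpha_values: np.ndarray,
    xi: np.ndarray | None = None,
) -> tuple[float | None, dict[float, float]]:
    """Smallest resource-kernel width still producing a Turing instability.

    Gaussian kernels with fixed fire and seed widths; for every cell of the
    (r, alpha) grid the ODE-stable interior equilibria are found once and
    their dispersion coefficients cached, then the dispersion maximum is
    evaluated for each candidate ``sigma_R`` (closed-form transforms, fully
    vectorized).  Returns the smallest ``sigma_R`` with a positive maximum
    somewhere on the grid (None if there is none) and the per-width maxima.
    """
    xi = default_xi_grid(400.0, 1500) if xi is None else np.asarray(xi)
    coeffs = []
    for r in r_values:
        for a in alpha_values:
            pa = p.with_(alpha=float(a), r=float(r))
            for eq in _stable_interior(pa):
                coeffs.append(coefficients_ABCD(eq.G, pa))
    AB = np.array(coeffs)  # (m, 4)
    wv = np.exp(-(sigma_w**2) * xi**2 / 2)
    fv = np.exp(-(sigma_f**2) * xi**2 / 2)
    maxima: dict[float, float] = {}
    threshold = None
    for sr in sorted(float(s) for s in sigma_r_values):
        rv = np.exp(-(sr**2) * xi**2 / 2)
        lam = AB[:, :1] * wv + AB[:, 1:2] * rv + AB[:, 2:3] * fv + AB[:, 3:]
        maxima[sr] = float(lam.max())
        if maxima[sr] > 0 and threshold is None:
            threshold = sr
    return threshold, maxima


def _branch_max_growth(
    alpha: float, g_ref: float, p: ModelParams, kernels, xi
) -> tuple[float, float] | None:
    """Dispersion max on the stable branch nearest ``g_ref``; None if gone."""
    eqs = _stable_interior(p.with_(alpha=float(alpha)))
    if not eqs:
        return None
    eq = min(eqs, key=lambda e: abs(e.G - g_ref))
    return float(max_dispersion_gf(eq.G, p.with_(alpha=float(alpha)), kernels, xi)), eq.G


def turing_onset(
    p: ModelParams,
    kernels: dict[str, Kernel],
    alpha_range: tuple[float, float],
    n_scan: int = 141,
    xi: np.ndarray | None = None,
    tol: float = 1e-4,
    merge: float = 1e-3,
) -> list[float]:
    """Alpha values where a stable branch's dispersion maximum crosses zero.

    Every ODE-stable interior equilibrium branch is tracked by continuity
    in ``G`` across an alpha scan; sign changes of its nonzero-wavenumber
    dispersion maximum are refined by bisection to ``tol``.  Crossings from
    all branches are pooled, sorted, and merged when closer than ``merge``.
    Branch folds (where a branch appears or disappears) are not crossings.
    """
    xi = default_xi_grid() if xi is None else np.asarray(xi)
    lo, hi = alpha_range
    alphas = np.linspace(lo, hi, n_scan)
    # branch bookkeeping: {branch id: (last G, last value, last alpha)}
    crossings: list[float] = []
    prev: list[tuple[float, float, float]] = []  # (G, value, alpha)
    for a in alphas:
        pa = p.with_(alpha=float(a))
        cur = []
        for eq in _stable_interior(pa):
            val = float(max_dispersion_gf(eq.G, pa, kernels, xi))
            cur.append((eq.G, val, float(a)))
        # match to previous by nearest G and look for sign changes
        for g0, v0, a0 in prev:
            if not cur:
                continue
            gm, vm, am = min(cur, key=lambda c: abs(c[0] - g0))
            if abs(gm - g0) > 0.15:  # branch ended (fold); no crossing
                continue
            if v0 == 0.0 or vm == 0.0 or v0 * vm > 0:
                continue

            def fun(alpha: float, g_ref=0.5 * (g0 + gm)) -> float:
                out = _branch_max_growth(alpha, g_ref, p, kernels, xi)
                return out[0] if out is not None else np.nan

            crossings.append(brentq(fun, a0, am, xtol=tol))
        prev = cur
    crossings.sort()
    merged: list[float] = []
    for c in crossings:
        if merged and c - merged[-1] < merge:
            continue
        merged.append(c)
    return merged
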