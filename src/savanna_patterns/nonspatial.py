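"""Nonspatial (mean-field) Staver-Levin model variants.

Three variants share one interface:

* ``SL4`` — the four-type model: grass G, savanna saplings S, savanna
  trees T, forest trees F, with fire-dependent forest mortality ``phi(G)``
  and sapling recruitment ``omega(G)``;
* ``RL-GF`` — the grass-forest subsystem with a resource constraint
  ``r`` capping forest cover (forest growth scaled by ``1 - F/r``);
* ``RL-SL4`` — the four-type model with the same resource constraint.

States live on the simplex ``G + S + T + F = 1``; the right-hand sides
sum to zero so the simplex is invariant.  For ``RL-GF`` the dynamics
reduce to a scalar equation for G with ``F = 1 - G``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "FireResponse",
    "ModelParams",
    "HomogeneousState",
    "Equilibrium",
    "sigmoid_phi",
    "sigmoid_omega",
    "heaviside_phi",
    "heaviside_omega",
    "default_params",
    "rhs",
    "rhs_rl_gf_scalar",
    "find_equilibria",
    "jacobian",
    "jacobian4",
    "scan_2p",
]

VARIANTS = ("SL4", "RL-GF", "RL-SL4")


# ---------------------------------------------------------------------------
# fire response functions

@dataclass(frozen=True)
class FireResponse:
    """Grass-cover dependence of a demographic rate.

    ``left`` is the rate for grass cover below the threshold, ``right``
    above it.  The sigmoid shape interpolates logistically with steepness
    ``slope``; the heaviside shape is the piecewise-constant limit.  Forest
    mortality ``phi`` increases with G (``left < right``); sapling
    recruitment ``omega`` decreases (``left > right``).
    """

    shape: str  # "sigmoid" | "heaviside"
    left: float
    right: float
    threshold: float
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("sigmoid", "heaviside"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.shape == "sigmoid" and self.slope <= 0:
            raise ValueError("sigmoid slope must be positive")

    def __call__(self, g: np.ndarray | float) -> np.ndarray | float:
        g = np.asarray(g, dtype=float)
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("grass cover outside [0, 1]")
        if self.shape == "sigmoid":
            out = self.left + (self.right - self.left) * expit(
                (g - self.threshold) / self.slope
            )
        else:
            out = np.where(g < self.threshold, self.left, self.right)
        return float(out) if out.ndim == 0 else out

    def derivative(self, g: np.ndarray | float) -> np.ndarray | float:
        """d(rate)/dG; identically zero for the heaviside shape (a.e.)."""
        g = np.asarray(g, dtype=float)
        if self.shape == "heaviside":
            out = np.zeros_like(g)
        else:
            s = expit((g - self.threshold) / self.slope)
            out = (self.right - self.left) * s * (1.0 - s) / self.slope
        return float(out) if out.ndim == 0 else out


def sigmoid_phi() -> FireResponse:
    """Default sigmoid forest-mortality response (phi0=0.1, phi1=0.9)."""
    return FireResponse("sigmoid", 0.1, 0.9, 0.4, 0.05)


def sigmoid_omega() -> FireResponse:
    """Default sigmoid sapling-recruitment response (omega0=0.9, omega1=0.4)."""
    return FireResponse("sigmoid", 0.9, 0.4, 0.4, 0.01)


def heaviside_phi() -> FireResponse:
    return FireResponse("heaviside", 0.1, 0.9, 0.4)


def heaviside_omega() -> FireResponse:
    return FireResponse("heaviside", 0.9, 0.4, 0.4)


# ---------------------------------------------------------------------------
# parameters and states

@dataclass(frozen=True)
class ModelParams:
    """Demographic rates, resource constraint and fire responses."""

    variant: str = "SL4"
    alpha: float = 1.5  # forest tree birth rate
    beta: float = 0.8  # savanna tree birth rate (4-type variants)
    mu: float = 0.1  # sapling mortality
    nu: float = 0.05  # savanna tree mortality
    r: float = 1.0  # resource constraint (RL variants), in (0, 1]
    phi: FireResponse = None
    omega: FireResponse = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; use one of {VARIANTS}")
        if min(self.alpha, self.beta, self.mu, self.nu) < 0:
            raise ValueError("rates must be nonnegative")
        if self.variant != "SL4" and not 0.0 < self.r <= 1.0:
            raise ValueError("resource constraint r must lie in (0, 1]")
        if self.phi is None:
            object.__setattr__(self, "phi", sigmoid_phi())
        if self.omega is None:
            object.__setattr__(self, "omega", sigmoid_omega())

    @property
    def resource_limited(self) -> bool:
        return self.variant in ("RL-GF", "RL-SL4")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def default_params(variant: str = "SL4", heaviside: bool = False, **kw) -> ModelParams:
    """Parameters with the default fire responses (sigmoid or heaviside)."""
    fire = (
        dict(phi=heaviside_phi(), omega=heaviside_omega())
        if heaviside
        else dict(phi=sigmoid_phi(), omega=sigmoid_omega())
    )
    fire.update(kw)
    return ModelParams(variant=variant, **fire)


@dataclass(frozen=True)
class HomogeneousState:
    """Cover fractions on the simplex; S = T = 0 for the grass-forest model."""

    G: float
    S: float = 0.0
    T: float = 0.0
    F: float = 0.0

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise ValueError("cover fractions must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"state off the simplex: sum={arr.sum()}")

    @classmethod
    def from_G(cls, g: float) -> "HomogeneousState":
        return cls(G=g, F=1.0 - g)

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.S, self.T, self.F])


@dataclass(frozen=True)
class Equilibrium:
    state: HomogeneousState
    stable: bool
    eigenvalues: np.ndarray
    residual: float

    @property
    def G(self) -> float:
        return self.state.G

    @property
    def is_all_grass(self) -> bool:
        return abs(self.state.G - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# right-hand sides

def rhs(state: HomogeneousState | np.ndarray, p: ModelParams) -> np.ndarray:
    """Time derivative ``(dG, dS, dT, dF)``; components sum to zero exactly."""
    g, s, t, f = (
        state.as_array() if isinstance(state, HomogeneousState) else np.asarray(state)
    )
    phi_g = p.phi(g)
    limit = (1.0 - f / p.r) if p.resource_limited else 1.0
    if p.variant == "RL-GF":
        growth = p.alpha * g * f * limit
        dg = phi_g * f - growth
        return np.array([dg, 0.0, 0.0, -dg])
    om = p.omega(g)
    growth = p.alpha * f * limit
    dg = p.mu * s + p.nu * t + phi_g * f - growth * g - p.beta * g * t
    ds = -p.mu * s - om * s - growth * s + p.beta * g * t
    dt = -p.nu * t + om * s - growth * t
    df = growth * (g + s + t) - phi_g * f
    return np.array([dg, ds, dt, df])


def rhs_rl_gf_scalar(g: np.ndarray | float, p: ModelParams) -> np.ndarray | float:
    """Scalar reduction of the resource-limited grass-forest model (F = 1-G)."""
    g = np.asarray(g, dtype=float)
    out = (1.0 - g) * (p.phi(g) - p.alpha * g * (1.0 - (1.0 - g) / p.r))
    return float(out) if out.ndim == 0 else out


def _equilibrium_condition_gf(g: np.ndarray | float, p: ModelParams):
    """Interior steady-state equation: phi(G) = alpha G (1 - (1-G)/r)."""
    return p.phi(g) - p.alpha * g * (1.0 - (1.0 - g) / p.r)


# ---------------------------------------------------------------------------
# Jacobians

def _unconstrained_partials(state: HomogeneousState, p: ModelParams) -> np.ndarray:
    """4x4 partials of rhs w.r.t. (G, S, T, F), treating all four as free."""
    g, s, t, f = state.as_array()
    dphi = p.phi.derivative(g)
    dom = p.omega.derivative(g)
    phi_g, om = p.phi(g), p.omega(g)
    a, b, mu, nu = p.alpha, p.beta, p.mu, p.nu
    if p.resource_limited:
        lim = 1.0 - f / p.r
        dlim = -1.0 / p.r
    else:
        lim, dlim = 1.0, 0.0
    J = np.zeros((4, 4))
    if p.variant == "RL-GF":
        # dG/dt = phi(G) F - a G F lim ;  dF = -dG
        J[0, 0] = dphi * f - a * f * lim
        J[0, 3] = phi_g - a * g * (lim + f * dlim)
        J[3, 0] = -J[0, 0]
        J[3, 3] = -J[0, 3]
        return J
    gr = a * f * lim  # alpha F (1 - F/r)
    dgr = a * (lim + f * dlim)  # d(gr)/dF
    # G row
    J[0, 0] = dphi * f - gr - b * t
    J[0, 1] = mu
    J[0, 2] = nu - b * g
    J[0, 3] = phi_g - g * dgr
    # S row
    J[1, 0] = -dom * s + b * t
    J[1, 1] = -mu - om - gr
    J[1, 2] = b * g
    J[1, 3] = -s * dgr
    # T row
    J[2, 0] = dom * s
    J[2, 1] = om
    J[2, 2] = -nu - gr
    J[2, 3] = -t * dgr
    # F row
    J[3, 0] = -dphi * f + gr
    J[3, 1] = gr
    J[3, 2] = gr
    J[3, 3] = (g + s + t) * dgr - phi_g
    return J


def jacobian(state: HomogeneousState, p: ModelParams, warn: bool = True) -> np.ndarray:
    """Jacobian of the simplex-reduced dynamics at ``state``.

    RL-GF: the 1x1 derivative of the scalar equation.  Four-type variants:
    the 3x3 Jacobian of (S, T, F) with G eliminated via G = 1-S-T-F.
    Heaviside responses carry zero derivative almost everywhere; evaluation
    exactly at a threshold is rejected.
    """
    g = state.G
    for resp in (p.phi, p.omega):
        if resp.shape == "heaviside" and abs(g - resp.threshold) < 1e-12:
            raise ValueError(
                "equilibrium sits exactly at a heaviside threshold; "
                "the fire-response derivative is undefined there"
            )
    if warn and np.max(np.abs(rhs(state, p))) > 1e-6:
        warnings.warn("state is not an equilibrium; Jacobian may be meaningless",
                      stacklevel=2)
    if p.variant == "RL-GF":
        # analytic; heaviside derivative is zero a.e. via FireResponse
        dphi = p.phi.derivative(g)
        d = -(p.phi(g) - p.alpha * g * (1 - (1 - g) / p.r)) + (1 - g) * (
            dphi - p.alpha * (1 - (1 - g) / p.r) - p.alpha * g / p.r
        )
        return np.array([[d]])
    J4 = _unconstrained_partials(state, p)
    # rows S,T,F; chain rule for G = 1 - S - T - F
    return J4[1:, 1:] - J4[1:, :1]


def jacobian4(state: HomogeneousState, p: ModelParams) -> np.ndarray:
    """Constraint-substituted 4x4 linearization used by the spatial theory.

    Identical to the wavenumber-dependent stability matrix evaluated with
    every kernel transform set to one (the zero mode).
    """
    from .dispersion import sl4_matrix  # local import to avoid a cycle

    return sl4_matrix(state, p, w_hat=1.0, jf_hat=1.0, jt_hat=1.0, r_hat=1.0)


# ---------------------------------------------------------------------------
# equilibria

def _gf_interior_roots(p: ModelParams, n_brackets: int = 10_000) -> list[float]:
    """All interior equilibria of RL-GF by dense bracketing + bisection."""
    if p.phi.shape == "heaviside":
        # piecewise-constant phi: alpha G (1-(1-G)/r) = phi_level, a quadratic
        # per side of the threshold; discard roots crossing their own side
        roots = []
        th = p.phi.threshold
        for level, lo, hi in ((p.phi.left, 0.0, th), (p.phi.right, th, 1.0)):
            # (a/r) G^2 + a(1 - 1/r) G - level = 0
            coeffs = [p.alpha / p.r, p.alpha * (1 - 1 / p.r), -level]
            for root in np.roots(coeffs):
                if abs(root.imag) < 1e-12 and lo < root.real < hi and root.real < 1:
                    roots.append(float(root.real))
        return sorted(roots)
    gs = np.linspace(1e-9, 1.0 - 1e-9, n_brackets + 1)
    h = _equilibrium_condition_gf(gs, p)
    sign = np.sign(h)
    roots = []
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        roots.append(
            brentq(lambda g: _equilibrium_condition_gf(g, p), gs[i], gs[i + 1],
                   xtol=1e-14, rtol=8.9e-16)
        )
    return roots


def _rhs_stf_batch(x: np.ndarray, p: ModelParams) -> np.ndarray:
    """Reduced (S, T, F) right-hand side, vectorized over rows of ``x``."""
    s, t, f = x[:, 0], x[:, 1], x[:, 2]
    g = np.clip(1.0 - s - t - f, 0.0, 1.0)
    om = p.omega(g)
    lim = (1.0 - f / p.r) if p.resource_limited else 1.0
    gr = p.alpha * f * lim
    ds = -p.mu * s - om * s - gr * s + p.beta * g * t
    dt = -p.nu * t + om * s - gr * t
    df = gr * (g + s + t) - p.phi(g) * f
    return np.stack([ds, dt, df], axis=1)


def _jac_stf_batch(x: np.ndarray, p: ModelParams) -> np.ndarray:
    """Reduced 3x3 Jacobians (G eliminated), vectorized over rows of ``x``."""
    s, t, f = x[:, 0], x[:, 1], x[:, 2]
    g = np.clip(1.0 - s - t - f, 0.0, 1.0)
    om, dom = p.omega(g), p.omega.derivative(g)
    phi_g, dphi = p.phi(g), p.phi.derivative(g)
    a, b, mu, nu = p.alpha, p.beta, p.mu, p.nu
    if p.resource_limited:
        lim, dlim = 1.0 - f / p.r, -1.0 / p.r
    else:
        lim, dlim = np.ones_like(f), 0.0
    gr = a * f * lim
    dgr = a * (lim + f * dlim)
    m = len(x)
    J = np.zeros((m, 3, 3))
    # unconstrained partials, then chain rule dG = -(dS + dT + dF)
    dS = np.stack([-dom * s + b * t, -mu - om - gr, b * g, -s * dgr], axis=1)
    dT = np.stack([dom * s, om, -nu - gr, -t * dgr], axis=1)
    dF = np.stack([-dphi * f + gr, gr, gr, (g + s + t) * dgr - phi_g], axis=1)
    for row, part in enumerate((dS, dT, dF)):
        J[:, row, :] = part[:, 1:] - part[:, :1]
    return J


def _newton_polish_batch(x0: np.ndarray, p: ModelParams, tol: float = 1e-13,
                         max_iter: int = 60) -> np.ndarray:
    """Damped Newton on the reduced (S, T, F) system from many starts at once."""
    x = x0.copy()  # (m, 3)
    for _ in range(max_iter):
        res = _rhs_stf_batch(x, p)
        if np.max(np.abs(res)) < tol:
            break
        jac = _jac_stf_batch(x, p)
        # regularize singular cells instead of failing the whole batch
        jac = jac + 1e-14 * np.eye(3)
        try:
            step = np.linalg.solve(jac, res[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(jac[i], res[i], rcond=None)[0] for i in range(len(x))]
            )
        x = x - np.clip(step, -0.2, 0.2)
    return x


def find_equilibria(
    p: ModelParams, lattice: int = 12, dedup: float = 1e-6
) -> list[Equilibrium]:
    """All homogeneous equilibria with stability flags.

    RL-GF uses dense sign-change bracketing of the scalar steady-state
    equation on (0, 1) (closed-form quadratics for heaviside phi); the
    four-type variants run Newton from a lattice of simplex starts and
    de-duplicate.  The all-grass state is always included.
    """
    out: list[Equilibrium] = []

    def _push(state: HomogeneousState) -> None:
        res = float(np.max(np.abs(rhs(state, p))))
        try:
            ev = np.linalg.eigvals(jacobian(state, p, warn=False))
        except ValueError:
            return  # equilibrium exactly at a heaviside threshold
        out.append(Equilibrium(state, bool(np.max(ev.real) < 0), ev, res))

    if p.variant == "RL-GF":
        for g in _gf_interior_roots(p):
            st = HomogeneousState.from_G(g)
            if 1.0 - g >= p.r - 1e-12:  # F >= r cannot be a true equilibrium
                continue
            _push(st)
        _push(HomogeneousState(G=1.0))
        return sorted(out, key=lambda e: e.G)

    # four-type variants: batched Newton from a simplex lattice of (S,T,F)
    ticks = np.linspace(0.0, 1.0, lattice)
    starts = [
        (s, t, f)
        for s in ticks
        for t in ticks
        for f in ticks
        if s + t + f <= 1.0 + 1e-12
    ]
    x = _newton_polish_batch(np.array(starts), p)
    seen: list[np.ndarray] = []
    for s, t, f in x:
        g = 1.0 - s - t - f
        v = np.array([g, s, t, f])
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            continue
        v = np.clip(v, 0.0, 1.0)
        v = v / v.sum()
        st = HomogeneousState(*v)
        if float(np.max(np.abs(rhs(st, p)))) > 1e-9:
            continue
        if any(np.max(np.abs(v - w)) < dedup for w in seen):
            continue
        seen.append(v)
        _push(st)
    if not any(e.is_all_grass for e in out):
        _push(HomogeneousState(G=1.0))
    return sorted(out, key=lambda e: e.G)


# ---------------------------------------------------------------------------
# two-parameter scans

@dataclass(frozen=True)
class RegionMap:
    """Per-cell classification of a two-parameter grid."""

    axes: tuple[str, str]
    values_1: np.ndarray
    values_2: np.ndarray
    n_stable: np.ndarray
    hopf: np.ndarray
    transcritical: np.ndarray
    saddle_node: np.ndarray


def scan_2p(
    p: ModelParams,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    hopf_tol: float = 0.05,
) -> RegionMap:
    """Classify equilibria over a rectangular grid of two parameters.

    Per cell: number of stable equilibria; a Hopf proximity flag (complex
    leading pair with small real part); a transcritical flag at the
    all-grass state (its leading eigenvalue ``alpha - phi(1)`` changes sign
    between neighbouring cells); a saddle-node flag (equilibrium count
    changes along the first axis).
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    n1, n2 = len(vals1), len(vals2)
    n_stable = np.zeros((n1, n2), dtype=int)
    hopf = np.zeros((n1, n2), dtype=bool)
    trans = np.zeros((n1, n2), dtype=bool)
    sn = np.zeros((n1, n2), dtype=bool)
    counts = np.zeros((n1, n2), dtype=int)
    ag_eig = np.zeros((n1, n2))
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            pij = p.with_(**{name1: float(v1), name2: float(v2)})
            eqs = find_equilibria(pij)
            counts[i, j] = len(eqs)
            n_stable[i, j] = sum(e.stable for e in eqs)
            ag_eig[i, j] = pij.alpha - pij.phi(1.0)
            for e in eqs:
                ev = e.eigenvalues
                lead = ev[np.argmax(ev.real)]
                if abs(lead.imag) > 1e-9 and abs(lead.real) < hopf_tol:
                    hopf[i, j] = True
    if n1 > 1:
        trans[1:, :] = np.sign(ag_eig[1:, :]) != np.sign(ag_eig[:-1, :])
        sn[1:, :] = counts[1:, :] != counts[:-1, :]
    return RegionMap(
        (name1, name2), np.asarray(vals1, dtype=float),
        np.asarray(vals2, dtype=float), n_stable, hopf, trans, sn,
    )
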