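"""Steady states of the nonlocal grass-forest equation and their branches.

The scalar resource-limited grass-forest equation is discretized on a
periodic grid; all convolutions become circulant matrices, so the steady
state problem is a dense nonlinear system solved by Newton and followed
in the forest birth rate ``alpha`` by pseudo-arclength continuation
(secant predictor, bordered Newton corrector).  Folds are detected as
sign changes of ``d alpha / ds`` and refined by a local quadratic fit;
stability comes from the eigenvalues of the dense steady-state Jacobian,
with the near-zero translation eigenvalue excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import SpatialGrid
from .kernels import Kernel, discretize
from .nonspatial import ModelParams

__all__ = [
    "GFOperators",
    "steady_residual",
    "steady_jacobian",
    "newton_solve",
    "seed_from_eigenmode",
    "branch_stability",
    "continue_branch",
    "Branch",
    "BranchPoint",
    "relax_to_attractor",
    "upper_fold_of_stable_branch",
]

TRANSLATION_TOL = 1e-4


class GFOperators:
    """Dense circulant convolution operators for the scalar model."""

    def __init__(self, kernels: dict[str, Kernel], grid: SpatialGrid):
        if grid.dim != 1:
            raise ValueError("continuation is implemented in 1D")
        self.grid = grid
        self.kernels = kernels
        self.W = self._circulant(kernels["w"])
        self.J = self._circulant(kernels["JF"])
        self.R = self._circulant(kernels["R"])

    def _circulant(self, kernel: Kernel) -> np.ndarray:
        k = discretize(kernel, self.grid) * self.grid.dx
        n = self.grid.n
        idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
        return k[idx]


def steady_residual(
    g: np.ndarray, alpha: float, p: ModelParams, ops: GFOperators
) -> np.ndarray:
    """Right-hand side of the scalar spatial equation; zero at steady states."""
    p = p.with_(alpha=float(alpha))
    wg = np.clip(ops.W @ g, 0.0, 1.0)
    return (1.0 - g) * p.phi(wg) - alpha * g * (1.0 - ops.J @ g) * (
        1.0 - 1.0 / p.r + (ops.R @ g) / p.r
    )


def steady_jacobian(
    g: np.ndarray, alpha: float, p: ModelParams, ops: GFOperators
) -> np.ndarray:
    """Dense analytic Jacobian of :func:`steady_residual` w.r.t. the field."""
    wg = np.clip(ops.W @ g, 0.0, 1.0)
    v = 1.0 - ops.J @ g
    c = 1.0 - 1.0 / p.r + (ops.R @ g) / p.r
    jac = np.diag(-p.phi(wg)) + ((1.0 - g) * p.phi.derivative(wg))[:, None] * ops.W
    jac -= alpha * (
        np.diag(v * c) - (g * c)[:, None] * ops.J + (g * v)[:, None] * ops.R / p.r
    )
    return jac


def _dresidual_dalpha(g: np.ndarray, p: ModelParams, ops: GFOperators) -> np.ndarray:
    return -g * (1.0 - ops.J @ g) * (1.0 - 1.0 / p.r + (ops.R @ g) / p.r)


def newton_solve(
    g0: np.ndarray,
    alpha: float,
    p: ModelParams,
    ops: GFOperators,
    tol: float = 1e-11,
    max_iter: int = 50,
    damped: bool = True,
) -> tuple[np.ndarray, bool]:
    """Newton iteration for a steady field from an initial guess."""
    g = np.asarray(g0, dtype=float).copy()
    for _ in range(max_iter):
        res = steady_residual(g, alpha, p, ops)
        err = float(np.max(np.abs(res)))
        if err < tol:
            return g, True
        try:
            step = np.linalg.solve(steady_jacobian(g, alpha, p, ops), res)
        except np.linalg.LinAlgError:
            return g, False
        lam = 1.0
        if damped:
            while lam > 1e-3:
                trial = g - lam * step
                if np.max(np.abs(steady_residual(trial, alpha, p, ops))) < err:
                    break
                lam *= 0.5
        g = g - lam * step
        if not np.all(np.isfinite(g)):
            return g, False
    return g, float(np.max(np.abs(steady_residual(g, alpha, p, ops)))) < tol


def seed_from_eigenmode(
    g_bar: float, grid: SpatialGrid, mode: int, amplitude: float = 0.05
) -> np.ndarray:
    """Homogeneous state plus a cosine of integer mode ``mode`` on the box."""
    return g_bar + amplitude * np.cos(grid.mode_wavenumber(mode) * grid.x)


def branch_stability(
    g: np.ndarray, alpha: float, p: ModelParams, ops: GFOperators
) -> tuple[np.ndarray, bool, float]:
    """Leading eigenvalues of the steady-state linearization and a verdict.

    The periodic domain carries a translation mode whose eigenvalue sits at
    zero up to discretization error; for genuinely heterogeneous states the
    single eigenvalue closest to zero (within ``TRANSLATION_TOL``) is
    excluded from the stability call.  Returns (eigenvalues sorted by
    descending real part, stable flag, leading non-translation real part).
    """
    ev = np.linalg.eigvals(steady_jacobian(g, alpha, p, ops))
    ev = ev[np.argsort(ev.real)[::-1]]
    lead = ev.real.copy()
    if float(np.ptp(g)) > 1e-8:
        i = int(np.argmin(np.abs(lead)))
        if abs(lead[i]) < TRANSLATION_TOL:
            lead[i] = -np.inf
    top = float(np.max(lead))
    return ev, bool(top < 0), top


@dataclass(frozen=True)
class BranchPoint:
    alpha: float
    field: np.ndarray
    l1_norm: float  # L1 norm of G over the domain
    leading_real: float
    stable: bool


@dataclass
class Branch:
    points: list[BranchPoint] = field(default_factory=list)
    folds: list[float] = field(default_factory=list)
    termination: str = ""

    @property
    def alphas(self) -> np.ndarray:
        return np.array([pt.alpha for pt in self.points])

    @property
    def norms(self) -> np.ndarray:
        return np.array([pt.l1_norm for pt in self.points])


def _refine_fold(alphas: list[float]) -> float:
    """Quadratic fit of alpha against arclength index around a turning point."""
    a = np.array(alphas[-3:])
    if len(a) < 3:
        return float(a[-1])
    # parabola through the last three points in (index, alpha); vertex alpha
    i = np.arange(3, dtype=float)
    coef = np.polyfit(i, a, 2)
    if abs(coef[0]) < 1e-15:
        return float(a[-1])
    vertex = -coef[1] / (2 * coef[0])
    return float(np.polyval(coef, np.clip(vertex, 0.0, 2.0)))


def continue_branch(
    g0: np.ndarray,
    alpha0: float,
    p: ModelParams,
    ops: GFOperators,
    direction: float = 1.0,
    ds: float = 0.02,
    ds_max: float = 0.04,
    ds_min: float = 1e-9,
    alpha_range: tuple[float, float] = (0.5, 12.0),
    max_points: int = 6000,
    corrector_tol: float = 1e-10,
    compute_stability: bool = True,
    stability_stride: int = 1,
    stop_at_fold: int | None = None,
    stop_if_homogeneous: bool = True,
) -> Branch:
    """Pseudo-arclength continuation of a steady state in ``alpha``.

    Secant predictor with a bordered Newton corrector; the step adapts to
    corrector failures.  Folds (sign changes of ``d alpha/ds``) are refined
    by a quadratic fit and collected in ``Branch.folds``; continuation can
    stop after a prescribed number of folds, or when the branch collapses
    onto the homogeneous one (spatial amplitude below 1e-3).
    """
    n = ops.grid.n
    g, ok = newton_solve(g0, alpha0, p, ops, tol=corrector_tol)
    if not ok:
        raise RuntimeError("seed point did not converge")
    branch = Branch()

    def record(gv: np.ndarray, av: float, idx: int) -> None:
        if compute_stability and idx % stability_stride == 0:
            _, stab, lead = branch_stability(gv, av, p, ops)
        else:
            stab, lead = False, np.nan
        branch.points.append(
            BranchPoint(float(av), gv.copy(), float(np.sum(np.abs(gv)) * ops.grid.dx),
                        lead, stab)
        )

    a = float(alpha0)
    record(g, a, 0)
    gdot = np.zeros(n)
    adot = float(np.sign(direction))
    step = ds
    prev_da = None
    for it in range(1, max_points + 1):
        gp = g + step * gdot
        ap = a + step * adot
        converged = False
        for _ in range(25):
            res = steady_residual(gp, ap, p, ops)
            con = gdot @ (gp - g) + adot * (ap - a) - step
            if max(float(np.max(np.abs(res))), abs(con)) < corrector_tol:
                converged = True
                break
            M = np.empty((n + 1, n + 1))
            M[:n, :n] = steady_jacobian(gp, ap, p, ops)
            M[:n, n] = _dresidual_dalpha(gp, p, ops)
            M[n, :n] = gdot
            M[n, n] = adot
            try:
                delta = np.linalg.solve(M, np.concatenate([res, [con]]))
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(M, np.concatenate([res, [con]]),
                                        rcond=None)[0]
            gp = gp - delta[:n]
            ap = ap - delta[n]
            if not np.all(np.isfinite(gp)):
                break
        if not converged:
            step *= 0.4
            if step < ds_min:
                branch.termination = "step collapse"
                break
            continue
        da = ap - a
        if prev_da is not None and prev_da * da < 0:
            branch.folds.append(
                _refine_fold([pt.alpha for pt in branch.points] + [float(ap)])
            )
            if stop_at_fold is not None and len(branch.folds) >= stop_at_fold:
                record(gp, ap, it)
                branch.termination = "fold"
                break
        prev_da = da
        norm = float(np.sqrt(np.sum((gp - g) ** 2) + da**2))
        gdot = (gp - g) / norm
        adot = da / norm
        g, a = gp, float(ap)
        record(g, a, it)
        step = min(step * 1.3, ds_max)
        if not alpha_range[0] <= a <= alpha_range[1]:
            branch.termination = "alpha range"
            break
        if stop_if_homogeneous and float(np.ptp(g)) < 1e-3:
            branch.termination = "collapsed to homogeneous"
            break
    else:
        branch.termination = "max points"
    return branch


# ---------------------------------------------------------------------------
# stable-branch following helpers

def relax_to_attractor(
    g0: np.ndarray,
    alpha: float,
    p: ModelParams,
    ops: GFOperators,
    t_relax: float = 2500.0,
    dt: float = 0.05,
    seed: int | None = None,
    noise: float = 0.0,
) -> tuple[np.ndarray, bool]:
    """Time-step the scalar equation to its attractor, then Newton-polish."""
    from .simulator import SpectralModel, simulate  # cycle-free local import

    g = np.clip(np.asarray(g0, dtype=float).copy(), 0.0, 1.0)
    if noise > 0:
        rng = np.random.default_rng(seed)
        g = np.clip(g + noise * rng.standard_normal(g.shape), 0.0, 1.0)
    traj = simulate(
        g[None], p.with_(alpha=float(alpha)), ops.kernels, ops.grid,
        t_final=t_relax, dt=dt, sample_every=10**9, seed=seed,
    )
    return newton_solve(traj.final[0], alpha, p, ops)


def upper_fold_of_stable_branch(
    g0: np.ndarray,
    alpha0: float,
    p: ModelParams,
    ops: GFOperators,
    seed: int | None = None,
    eig_tol: float = 1e-3,
    **cont_kw,
) -> tuple[float, Branch]:
    """Fold terminating the branch of *stable* patterned states above alpha0.

    Continues upward in alpha.  If the branch under continuation acquires a
    positive non-translation eigenvalue before folding (a secondary,
    symmetry-breaking bifurcation), the state is perturbed along the
    unstable eigenvector, relaxed back onto the attractor by time stepping,
    and continuation resumes from the recovered stable state.  Returns the
    first genuine fold of the stable patterned branch.
    """
    g, alpha = np.asarray(g0, float).copy(), float(alpha0)
    for _round in range(6):
        branch = continue_branch(
            g, alpha, p, ops, direction=+1.0, stop_at_fold=1,
            compute_stability=True, **cont_kw,
        )
        # find the first point (beyond the start) that went unstable pre-fold
        unstable_at = None
        for pt in branch.points[1:]:
            if not pt.stable and np.isfinite(pt.leading_real) and pt.leading_real > eig_tol:
                unstable_at = pt
                break
        # accept the fold when no genuine instability precedes it (the
        # eigenvalue grazes zero right at a fold; allow a small margin)
        if branch.folds and (
            unstable_at is None or branch.folds[0] <= unstable_at.alpha + 0.05
        ):
            return branch.folds[0], branch
        if unstable_at is None:
            raise RuntimeError(
                f"no fold found up to alpha={branch.points[-1].alpha:.3f} "
                f"({branch.termination})"
            )
        # secondary bifurcation: hop onto the nearby stable attractor
        jac = steady_jacobian(unstable_at.field, unstable_at.alpha, p, ops)
        ev, vec = np.linalg.eig(jac)
        lead = np.argmax(ev.real)
        direction_vec = np.real(vec[:, lead])
        g_pert = unstable_at.field + 0.02 * direction_vec / np.max(np.abs(direction_vec))
        g_new, ok = relax_to_attractor(g_pert, unstable_at.alpha, p, ops, seed=seed)
        if not ok or float(np.ptp(g_new)) < 1e-3:
            raise RuntimeError("relaxation lost the patterned state")
        g, alpha = g_new, float(unstable_at.alpha)
    raise RuntimeError("stable branch did not terminate within the round limit")
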