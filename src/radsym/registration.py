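"""Control-point diffeomorphic surface registration by geodesic shooting.

The deformation model is the control-point (landmark) Hamiltonian system: a
set of control points ``c`` carries momenta ``alpha``; the velocity field is
``v(x) = sum_j K(x, c_j) alpha_j`` with a Gaussian kernel
``K(x, y) = exp(-|x - y|^2 / sigma_V^2)`` (no factor 2 in the denominator —
the kernel width is interpreted accordingly everywhere). Geodesic shooting
integrates the Hamiltonian equations

    dc_i/dt = sum_j K(c_i, c_j) alpha_j
    da_i/dt = (2 / sigma_V^2) sum_j K(c_i, c_j) (c_i - c_j) (alpha_i . alpha_j)

over unit time with a midpoint (RK2) scheme on ``T`` time points; mesh
vertices are transported through the same flow. Registration minimises

    C(alpha_0) = d_W^2(flow(source), target) / (2 sigma_eps^2) + H(c_0, alpha_0)

where ``d_W^2`` is the unoriented varifold discrepancy and ``H`` the kinetic
energy (regularity). Gradients are exact discrete adjoints: each RK2 step is
back-propagated with hand-derived vector–Jacobian products of the kernel
sums, so the gradient matches central finite differences of the discrete
cost to near machine precision. Optimisation uses L-BFGS with a Wolfe line
search (plain steepest descent stalls far from point-to-point accuracy under
the heavily weighted data term); control points stay frozen on a regular
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _fastops as _fast
from .mesh import SurfaceMesh
from .varifold import varifold_distance_sq, varifold_grad

__all__ = [
    "DeformationParams",
    "DeformationState",
    "RegistrationResult",
    "gaussian_kernel",
    "make_control_grid",
    "hamiltonian",
    "shoot",
    "flow_points",
    "register",
    "deterministic_atlas",
]


@dataclass
class DeformationParams:
    """Hyperparameters of the deformation model and optimiser.

    ``kernel_width`` (sigma_V, mm) controls deformation smoothness;
    ``attachment_width`` (sigma_W, mm) the varifold kernel;
    ``noise_std`` (sigma_eps, mm) weights the data term as 1/(2 sigma_eps^2).
    """

    kernel_width: float = 2.0
    attachment_width: float = 4.0
    noise_std: float = 5e-4
    n_time_points: int = 10
    convergence_tol: float = 1e-4
    max_iterations: int = 200
    freeze_control_points: bool = True
    freeze_template: bool = True
    optimizer: str = "gradient_descent"  # or "lbfgs"

    def __post_init__(self):
        if self.kernel_width <= 0 or self.attachment_width <= 0 or self.noise_std <= 0:
            raise ValueError("kernel widths and noise std must be positive")
        if self.n_time_points < 2:
            raise ValueError("need at least 2 time points")
        if self.convergence_tol <= 0:
            raise ValueError("convergence tolerance must be positive")


@dataclass
class DeformationState:
    """Control points (K, 3), momenta (K, 3) and the parameters binding them."""

    control_points: np.ndarray
    momenta: np.ndarray
    params: DeformationParams = field(default_factory=DeformationParams)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.momenta = np.asarray(self.momenta, dtype=float)
        if self.control_points.shape != self.momenta.shape:
            raise ValueError("control points and momenta must have identical shape")

    def kinetic_energy(self) -> float:
        return hamiltonian(self.control_points, self.momenta, self.params.kernel_width)


@dataclass
class RegistrationResult:
    state: DeformationState
    deformed_source: SurfaceMesh
    final_cost: float
    final_attachment: float
    final_regularity: float
    n_iterations: int
    converged: bool
    cost_history: List[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kernels and control grids
# ---------------------------------------------------------------------------


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """Gram matrix exp(-|x_i - y_j|^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError("kernel width must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d2 = np.sum(x**2, axis=1)[:, None] + np.sum(y**2, axis=1)[None, :] - 2.0 * (x @ y.T)
    return np.exp(-np.maximum(d2, 0.0) / sigma**2)


def make_control_grid(
    mesh: SurfaceMesh, spacing: float, prune_distance: Optional[float] = None
) -> np.ndarray:
    """Regular grid over the padded bounding box, pruned to near-surface points.

    Grid step equals ``spacing``; the box is padded by one spacing on each
    side and points farther than ``prune_distance`` (default 2x spacing) from
    the surface are discarded — control points outside a couple of kernel
    widths exert no useful velocity on the surface.
    """
    from scipy.spatial import cKDTree

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if prune_distance is None:
        prune_distance = 2.0 * spacing
    lo, hi = mesh.bounds
    axes = [np.arange(lo[d] - spacing, hi[d] + spacing + 0.5 * spacing, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist, _ = cKDTree(mesh.vertices).query(grid, k=1)
    keep = dist <= prune_distance
    return grid[keep]


def hamiltonian(c: np.ndarray, a: np.ndarray, sigma: float) -> float:
    """Kinetic energy 0.5 * sum_ij K(c_i, c_j) (a_i . a_j)."""
    K = gaussian_kernel(c, c, sigma)
    return float(0.5 * np.sum(K * (a @ a.T)))


# ---------------------------------------------------------------------------
# Forward dynamics (RK2 midpoint) and exact discrete adjoints
# ---------------------------------------------------------------------------


_MAX_CACHED_KERNEL = 4_000_000  # entries; ~32 MB per stored Gram matrix


def _rhs(c, a, x, sigma, kernels_out=None):
    if _fast.HAVE_NUMBA:
        xx = x if x is not None else np.zeros((0, 3))
        Kcc = gaussian_kernel(c, c, sigma)
        Kxc = gaussian_kernel(xx, c, sigma) if len(xx) else np.zeros((0, len(c)))
        dc, da, dx = _fast.rhs_fused(c, a, xx, Kcc, Kxc, sigma)
        if kernels_out is not None:
            if Kcc.size <= _MAX_CACHED_KERNEL:
                kernels_out.append((Kcc, Kxc))
            else:
                kernels_out.append((None, None))
        return dc, da, (dx if x is not None else None)
    s2 = sigma**2
    Kcc = gaussian_kernel(c, c, sigma)
    dc = Kcc @ a
    S = a @ a.T
    W = Kcc * S
    da = (2.0 / s2) * (c * W.sum(axis=1)[:, None] - W @ c)
    if x is not None:
        Kxc = gaussian_kernel(x, c, sigma)
        dx = Kxc @ a
    else:
        Kxc = None
        dx = None
    if kernels_out is not None:
        kernels_out.append((Kcc, Kxc))
    return dc, da, dx


def _rhs_vjp(c, a, x, sigma, wc, wa, wx, kernels=None):
    """Vector-Jacobian products of ``_rhs`` — hand-derived, FD-verified."""
    if _fast.HAVE_NUMBA and wc is not None and wa is not None and (x is None) == (wx is None):
        xx = x if x is not None else np.zeros((0, 3))
        wxx = wx if wx is not None else np.zeros((0, 3))
        if kernels is not None and kernels[0] is not None:
            Kcc, Kxc = kernels
        else:
            Kcc = gaussian_kernel(c, c, sigma)
            Kxc = gaussian_kernel(xx, c, sigma) if len(xx) else np.zeros((0, len(c)))
        gc, ga, gx = _fast.vjp_fused(c, a, xx, wc, wa, wxx, Kcc, Kxc, sigma)
        return gc, ga, (gx if x is not None else None)
    s2 = sigma**2
    Kcc = (
        kernels[0]
        if kernels is not None and kernels[0] is not None
        else gaussian_kernel(c, c, sigma)
    )
    gc = np.zeros_like(c)
    ga = np.zeros_like(a)
    gx = np.zeros_like(x) if x is not None else None

    if wc is not None:
        ga += Kcc @ wc
        B = Kcc * (wc @ a.T)
        gc += (-2.0 / s2) * (
            c * (B.sum(axis=1) + B.sum(axis=0))[:, None] - B @ c - B.T @ c
        )
    if wa is not None:
        gamma = 2.0 / s2
        S = a @ a.T
        WD = (wa * c).sum(axis=1)[:, None] - wa @ c.T  # wa_i . (c_i - c_j)
        E = Kcc * WD
        ga += gamma * (E @ a + E.T @ a)
        SK = Kcc * S
        P = (-2.0 / s2) * gamma * SK * WD
        gc += (
            c * P.sum(axis=1)[:, None]
            - P @ c
            + gamma * wa * SK.sum(axis=1)[:, None]
            - (P.T @ c - c * P.sum(axis=0)[:, None] + gamma * SK @ wa)
        )
    if wx is not None and x is not None:
        Kxc = (
            kernels[1]
            if kernels is not None and kernels[1] is not None
            else gaussian_kernel(x, c, sigma)
        )
        ga += Kxc.T @ wx
        Bx = Kxc * (wx @ a.T)
        gx += (-2.0 / s2) * (x * Bx.sum(axis=1)[:, None] - Bx @ c)
        gc += (2.0 / s2) * (Bx.T @ x - c * Bx.sum(axis=0)[:, None])
    return gc, ga, gx


def _integrate(c0, a0, x0, sigma, n_time_points, store=False):
    """RK2 midpoint integration of (c, a, x) over unit time.

    With ``store`` the per-step node/midpoint states and the Gaussian kernel
    matrices evaluated at them are kept for the exact adjoint pass.
    """
    h = 1.0 / (n_time_points - 1)
    c, a = c0.copy(), a0.copy()
    x = x0.copy() if x0 is not None else None
    nodes, mids = [(c.copy(), a.copy(), None if x is None else x.copy())], []
    kern_nodes, kern_mids = [], []
    for _ in range(n_time_points - 1):
        dc1, da1, dx1 = _rhs(c, a, x, sigma, kernels_out=kern_nodes if store else None)
        cm = c + 0.5 * h * dc1
        am = a + 0.5 * h * da1
        xm = x + 0.5 * h * dx1 if x is not None else None
        dc2, da2, dx2 = _rhs(cm, am, xm, sigma, kernels_out=kern_mids if store else None)
        c = c + h * dc2
        a = a + h * da2
        if x is not None:
            x = x + h * dx2
        if not np.isfinite(c).all() or not np.isfinite(a).all():
            raise FloatingPointError(
                "geodesic shooting diverged; use more time points or smaller momenta"
            )
        if store:
            mids.append((cm, am, xm))
            nodes.append((c.copy(), a.copy(), None if x is None else x.copy()))
    if store:
        return nodes, mids, kern_nodes, kern_mids
    return c, a, x


def shoot(state: DeformationState):
    """Integrate the Hamiltonian flow; returns the (c, a) trajectory with the
    stored midpoint stages needed to transport additional points."""
    nodes, mids, _, _ = _integrate(
        state.control_points,
        state.momenta,
        None,
        state.params.kernel_width,
        state.params.n_time_points,
        store=True,
    )
    return {
        "nodes": [(c, a) for c, a, _ in nodes],
        "mids": [(c, a) for c, a, _ in mids],
        "sigma": state.params.kernel_width,
        "n_time_points": state.params.n_time_points,
    }


def flow_points(points: np.ndarray, trajectory) -> np.ndarray:
    """Transport points through a precomputed control-point trajectory with
    the same midpoint scheme used by :func:`shoot`."""
    x = np.asarray(points, dtype=float).copy()
    sigma = trajectory["sigma"]
    h = 1.0 / (trajectory["n_time_points"] - 1)
    for (c, a), (cm, am) in zip(trajectory["nodes"][:-1], trajectory["mids"]):
        k1 = gaussian_kernel(x, c, sigma) @ a
        xm = x + 0.5 * h * k1
        k2 = gaussian_kernel(xm, cm, sigma) @ am
        x = x + h * k2
    return x


# ---------------------------------------------------------------------------
# Cost and gradient
# ---------------------------------------------------------------------------


def _cost_parts(a0, c0, source: SurfaceMesh, target: SurfaceMesh, params: DeformationParams):
    _, _, xT = _integrate(c0, a0, source.vertices, params.kernel_width, params.n_time_points)
    deformed = SurfaceMesh(xT, source.faces)
    attachment = varifold_distance_sq(deformed, target, params.attachment_width)
    regularity = hamiltonian(c0, a0, params.kernel_width)
    cost = attachment / (2.0 * params.noise_std**2) + regularity
    return cost, attachment, regularity, deformed


def _cost_and_grad(a0, c0, source: SurfaceMesh, target: SurfaceMesh, params: DeformationParams):
    sigma = params.kernel_width
    nodes, mids, kern_nodes, kern_mids = _integrate(
        c0, a0, source.vertices, sigma, params.n_time_points, store=True
    )
    cT, aT, xT = nodes[-1]
    deformed = SurfaceMesh(xT, source.faces)
    attachment, gA = varifold_grad(deformed, target, params.attachment_width)
    regularity = hamiltonian(c0, a0, sigma)
    cost = attachment / (2.0 * params.noise_std**2) + regularity

    h = 1.0 / (params.n_time_points - 1)
    wc = np.zeros_like(c0)
    wa = np.zeros_like(a0)
    wx = gA / (2.0 * params.noise_std**2)
    for k in range(len(mids) - 1, -1, -1):
        ck, ak, xk = nodes[k]
        cm, am, xm = mids[k]
        gc_m, ga_m, gx_m = _rhs_vjp(
            cm, am, xm, sigma, h * wc, h * wa, h * wx, kernels=kern_mids[k]
        )
        gc_k, ga_k, gx_k = _rhs_vjp(
            ck, ak, xk, sigma, 0.5 * h * gc_m, 0.5 * h * ga_m, 0.5 * h * gx_m,
            kernels=kern_nodes[k],
        )
        wc = wc + gc_m + gc_k
        wa = wa + ga_m + ga_k
        wx = wx + gx_m + gx_k
    Kcc = gaussian_kernel(c0, c0, sigma)
    grad_a0 = wa + Kcc @ a0  # adjoint of data term + regularity gradient
    return cost, attachment, regularity, deformed, grad_a0, wx


# ---------------------------------------------------------------------------
# Registration and deterministic atlas
# ---------------------------------------------------------------------------


def register(
    source: SurfaceMesh,
    target: SurfaceMesh,
    params: Optional[DeformationParams] = None,
    control_points: Optional[np.ndarray] = None,
    initial_momenta: Optional[np.ndarray] = None,
) -> RegistrationResult:
    """Deform ``source`` onto ``target`` by optimising initial momenta.

    The default optimiser is steepest descent with a backtracking line
    search (halve the step after a cost increase, grow it 1.5x after a
    success), the first step sized so the initial momenta update is at most
    0.1 sigma_V. It stops when the relative cost change over an accepted
    step falls below the convergence tolerance. This mirrors the plain
    gradient scheme reference implementations use and, together with the
    tolerance, avoids over-fitting the attachment to triangulation noise.
    ``optimizer="lbfgs"`` swaps in quasi-Newton minimisation, which drives
    the attachment much lower (useful for oracle recovery tests) at the
    price of larger tangential drift on coarse meshes.

    A non-converged run is returned flagged, not raised.
    """
    params = params or DeformationParams()
    c0 = (
        np.asarray(control_points, dtype=float)
        if control_points is not None
        else make_control_grid(source, params.kernel_width)
    )
    a0 = (
        np.asarray(initial_momenta, dtype=float).copy()
        if initial_momenta is not None
        else np.zeros_like(c0)
    )
    if params.optimizer == "lbfgs":
        a, cost_info, n_it, converged, history = _optimize_lbfgs(a0, c0, source, target, params)
    elif params.optimizer == "gradient_descent":
        a, cost_info, n_it, converged, history = _optimize_gd(a0, c0, source, target, params)
    else:
        raise ValueError(f"unknown optimizer {params.optimizer!r}")
    cost, attach, reg, deformed = cost_info
    state = DeformationState(c0, a, params)
    return RegistrationResult(
        state=state,
        deformed_source=deformed,
        final_cost=cost,
        final_attachment=attach,
        final_regularity=reg,
        n_iterations=n_it,
        converged=converged,
        cost_history=history,
    )


def _optimize_gd(a0, c0, source, target, params):
    a = a0.copy()
    cost, attach, reg, deformed, grad, _ = _cost_and_grad(a, c0, source, target, params)
    history = [cost]
    gmax = float(np.abs(grad).max())
    if gmax == 0:
        return a, (cost, attach, reg, deformed), 0, True, history
    step = 0.1 * params.kernel_width / gmax
    converged = False
    n_done = 0
    for _ in range(params.max_iterations):
        accepted = False
        while step > 1e-20:
            a_try = a - step * grad
            try:
                cost_try, attach_try, reg_try, deformed_try = _cost_parts(
                    a_try, c0, source, target, params
                )
            except FloatingPointError:
                step *= 0.5
                continue
            if cost_try <= cost:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        n_done += 1
        rel_change = abs(cost - cost_try) / max(abs(cost), 1e-30)
        a, cost, attach, reg, deformed = a_try, cost_try, attach_try, reg_try, deformed_try
        history.append(cost)
        if rel_change < params.convergence_tol:
            converged = True
            break
        _, _, _, _, grad, _ = _cost_and_grad(a, c0, source, target, params)
        step *= 1.5
    return a, (cost, attach, reg, deformed), n_done, converged, history


def _optimize_lbfgs(a0, c0, source, target, params):
    from scipy.optimize import minimize

    K = len(c0)
    history: List[float] = []
    last_eval = {}

    def fun(v):
        a = v.reshape(K, 3)
        try:
            cost, attach, reg, deformed, grad, _ = _cost_and_grad(a, c0, source, target, params)
        except FloatingPointError:
            return np.inf, np.zeros(3 * K)
        last_eval[v.tobytes()] = cost
        if len(last_eval) > 8:
            last_eval.pop(next(iter(last_eval)))
        return cost, grad.ravel()

    def record(xk):
        c = last_eval.get(xk.tobytes())
        if c is not None:
            history.append(float(c))

    opt = minimize(
        fun,
        a0.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={
            "maxiter": params.max_iterations,
            "ftol": params.convergence_tol,
            "gtol": 1e-12,
            "maxcor": 20,
        },
    )
    a = opt.x.reshape(K, 3)
    cost, attach, reg, deformed, grad, _ = _cost_and_grad(a, c0, source, target, params)
    converged = bool(opt.success) or "REL_REDUCTION" in str(opt.message).upper()
    return a, (cost, attach, reg, deformed), int(opt.nit), converged, history


def deterministic_atlas(
    template: SurfaceMesh,
    targets: Sequence[SurfaceMesh],
    params: Optional[DeformationParams] = None,
    n_template_rounds: int = 5,
    control_points: Optional[np.ndarray] = None,
) -> Tuple[SurfaceMesh, List[DeformationState], List[RegistrationResult]]:
    """Joint template/momenta estimation against a set of target surfaces.

    One control-point grid (built on the template) is shared by all subjects;
    per-target momenta are optimised to deform the template toward each
    target. With ``freeze_template`` (the default) this reduces to a bank of
    independent registrations from the common template. When the template is
    free, momenta optimisation alternates with gradient steps on the template
    vertices (summing each subject's adjoint vertex gradient).
    """
    if len(targets) == 0:
        raise ValueError("need at least one target")
    params = params or DeformationParams()
    c0 = (
        np.asarray(control_points, dtype=float)
        if control_points is not None
        else make_control_grid(template, params.kernel_width)
    )

    if params.freeze_template:
        results = [
            register(template, tgt, params=params, control_points=c0) for tgt in targets
        ]
        return template, [r.state for r in results], results

    # free template: joint quasi-Newton optimisation over all per-target
    # momenta and the template vertices (alternating schemes stall once the
    # heavily weighted data term saturates, because the template is then
    # pinned at fixed momenta)
    from scipy.optimize import minimize

    K = len(c0)
    n_t = len(targets)
    N = template.n_vertices
    x0_init = template.vertices.copy()

    def unpack(v):
        alphas = v[: n_t * K * 3].reshape(n_t, K, 3)
        x0 = v[n_t * K * 3 :].reshape(N, 3)
        return alphas, x0

    def fun(v):
        alphas, x0 = unpack(v)
        tmpl = SurfaceMesh(x0, template.faces)
        total = 0.0
        g = np.zeros_like(v)
        gx_total = np.zeros((N, 3))
        for i, tgt in enumerate(targets):
            try:
                cost, _, _, _, ga, gx0 = _cost_and_grad(alphas[i], c0, tmpl, tgt, params)
            except FloatingPointError:
                return np.inf, np.zeros_like(v)
            total += cost
            g[i * K * 3 : (i + 1) * K * 3] = ga.ravel()
            gx_total += gx0
        g[n_t * K * 3 :] = gx_total.ravel()
        return total, g

    v0 = np.concatenate([np.zeros(n_t * K * 3), x0_init.ravel()])
    opt = minimize(
        fun,
        v0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": params.max_iterations * max(n_template_rounds, 1),
            "ftol": params.convergence_tol * 1e-2,
            "gtol": 1e-12,
        },
    )
    alphas, x0 = unpack(opt.x)
    tmpl = SurfaceMesh(x0, template.faces)
    results = []
    for i, tgt in enumerate(targets):
        cost, attach, reg, deformed, _, _ = _cost_and_grad(alphas[i], c0, tmpl, tgt, params)
        state = DeformationState(c0, alphas[i], params)
        results.append(
            RegistrationResult(
                state=state,
                deformed_source=deformed,
                final_cost=cost,
                final_attachment=attach,
                final_regularity=reg,
                n_iterations=int(opt.nit),
                converged=bool(opt.success),
            )
        )
    return tmpl, [r.state for r in results], results
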