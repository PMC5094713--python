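"""Convex enzyme cost minimization and tolerance ranges.

The optimum solves ``min_{x in P} q(x, v) + lambda * ||x - x_hat||^2`` over
the free metabolite log-concentrations, where P is the metabolite polytope.
The squared-norm regularizer (default weight 1e-6 times the cost at the MDF
profile, default anchor the midpoint of the log-bounds) is a tie-breaker for
tiers whose cost is not strictly convex (EMC0/EMC1, and EMC2 which depends on
x only through the driving forces); it leaves strictly convex tiers unchanged
within solver tolerance.

Optimization runs in the free coordinates only, started at the MDF profile
(the interior point with maximal minimum driving-force slack), using a
trust-region method with the E-face constraints kept feasible throughout;
the cost itself diverges at the E-faces and acts as a natural barrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, NonlinearConstraint, minimize

from .exceptions import ConvergenceError
from .ratelaws import demand_of_reaction, enzyme_cost
from .thermo import max_min_driving_force

_GTOL = 1e-9
_XTOL = 1e-12


@dataclass
class ECMSolution:
    """Optimal state of the enzyme cost minimization problem."""

    x_opt: np.ndarray          # full-length ln(mM)
    c_opt: np.ndarray          # mM
    E_opt: np.ndarray          # mM per reaction (0 for inactive)
    q_opt: float               # pure enzyme cost at the optimum
    breakdown: object
    regularizer: tuple         # (lambda, x_hat in free coordinates)
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ToleranceRanges:
    """Metabolite and enzyme intervals reachable at cost <= (1+alpha) q_opt.

    Metabolite ranges and enzyme lower endpoints are computed exactly
    (convex subproblems); enzyme upper endpoints are a heuristic maximum over
    candidate profiles plus local ascent, tagged ``'heuristic'``.
    """

    alpha: float
    metabolite_ids: list
    x_ranges: np.ndarray       # (m, 2) ln mM, free metabolites
    reaction_ids: list
    E_ranges: np.ndarray       # (n_active, 2) mM
    enzyme_upper_method: list  # per enzyme: 'exact' | 'heuristic'


def _objective(poly, net, par, flux, spec, lam, x_hat):
    def f(xf):
        q, grad, _ = enzyme_cost(poly.lift(xf), net, par, flux, spec,
                                 with_breakdown=False)
        dx = xf - x_hat
        return q + lam * dx @ dx, grad[poly.free_index] + 2 * lam * dx
    return f


def _minimize(fun_grad, x0, poly, extra_constraints=(), maxiter=2000, gtol=_GTOL):
    import warnings

    cons = []
    if poly.A.shape[0] and poly.n_free:
        cons.append(LinearConstraint(poly.A, poly.epsilon - poly.b0, np.inf,
                                     keep_feasible=True))
    cons.extend(extra_constraints)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Singular Jacobian")
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        warnings.filterwarnings("ignore", message="invalid value encountered")
        res = minimize(
            lambda z: fun_grad(z)[0], x0, jac=lambda z: fun_grad(z)[1],
            method="trust-constr",
            bounds=Bounds(poly.x_min, poly.x_max, keep_feasible=True),
            constraints=cons,
            options={"gtol": gtol, "xtol": _XTOL, "maxiter": maxiter},
        )
    return res


def ecm_solve(poly, net, par, flux, spec, lam=None, x_hat=None, seed=None):
    """Solve the enzyme cost minimization problem on the polytope ``poly``.

    ``lam``/``x_hat`` configure the quadratic regularizer (defaults: 1e-6
    times the cost at the MDF profile; midpoint of the log-bounds). ``seed``
    is used only if a fallback multi-start is triggered. Deterministic given
    identical inputs.
    """
    from .ratelaws import validate_spec
    validate_spec(spec, net, par, flux)
    mdf, x_mdf = max_min_driving_force(poly)
    x0 = poly.restrict(x_mdf)
    if x_hat is None:
        x_hat = poly.midpoint()
    x_hat = np.asarray(x_hat, dtype=float)
    q_mdf, _, _ = enzyme_cost(x_mdf, net, par, flux, spec, with_breakdown=False)
    if lam is None:
        lam = 1e-6 * max(q_mdf, 1e-12)
    if poly.n_free == 0:
        x_full = poly.lift(np.zeros(0))
        q, _, breakdown = enzyme_cost(x_full, net, par, flux, spec)
        E = np.zeros(net.n_reactions)
        E[poly.active_reactions] = breakdown.demand
        return ECMSolution(x_full, np.exp(x_full), E, q, breakdown, (lam, x_hat),
                           {"status": "fixed-point", "mdf": mdf})

    fg = _objective(poly, net, par, flux, spec, lam, x_hat)
    res = _minimize(fg, x0, poly)
    best = res
    if not res.success and res.status not in (1, 2):  # not gtol/xtol converged
        rng = np.random.default_rng(seed)
        for _ in range(5):
            w = rng.uniform(0.2, 0.8)
            trial_x0 = w * x0 + (1 - w) * (poly.x_min + rng.random(poly.n_free)
                                           * (poly.x_max - poly.x_min))
            if not poly.contains(trial_x0):
                trial_x0 = 0.5 * (trial_x0 + x0)
                if not poly.contains(trial_x0):
                    continue
            res2 = _minimize(fg, trial_x0, poly)
            if res2.fun < best.fun:
                best = res2
        if not best.success and best.status not in (1, 2):
            raise ConvergenceError(
                f"ECM optimizer did not converge: {best.message}", last_x=best.x)
    x_full = poly.lift(best.x)
    q, _, breakdown = enzyme_cost(x_full, net, par, flux, spec)
    E = np.zeros(net.n_reactions)
    E[poly.active_reactions] = breakdown.demand
    diagnostics = {
        "status": best.message,
        "iterations": int(best.niter),
        "final_gradient_norm": float(np.max(np.abs(best.grad))) if best.grad is not None else None,
        "mdf": float(mdf),
        "objective": float(best.fun),
        "active_lower_bounds": [net.metabolite_ids[poly.free_index[j]]
                                for j in np.where(best.x - poly.x_min < 1e-7)[0]],
        "active_upper_bounds": [net.metabolite_ids[poly.free_index[j]]
                                for j in np.where(poly.x_max - best.x < 1e-7)[0]],
    }
    return ECMSolution(x_full, np.exp(x_full), E, q, breakdown, (lam, x_hat),
                       diagnostics)


# ---------------------------------------------------------------------------
# Tolerance ranges
# ---------------------------------------------------------------------------


class _ReducedPoly:
    """Polytope with one free coordinate eliminated at a fixed value
    (duck-typed for ``_minimize``)."""

    def __init__(self, poly, j, t):
        keep = np.array([k for k in range(poly.n_free) if k != j])
        self._poly = poly
        self._j = j
        self._t = t
        self._keep = keep
        self.A = poly.A[:, keep]
        self.b0 = poly.b0 + poly.A[:, j] * t
        self.epsilon = poly.epsilon
        self.x_min = poly.x_min[keep]
        self.x_max = poly.x_max[keep]
        self.n_free = len(keep)

    def expand(self, x_red):
        xf = np.empty(self._poly.n_free)
        xf[self._keep] = x_red
        xf[self._j] = self._t
        return xf

    def contains(self, x_red, tol=0.0):
        return (np.all(self.A @ x_red + self.b0 >= self.epsilon - tol)
                and np.all(x_red >= self.x_min - tol)
                and np.all(x_red <= self.x_max + tol))

    def midpoint(self):
        return 0.5 * (self.x_min + self.x_max)


def _min_cost_with_pinned_coord(poly, net, par, flux, spec, j, t, x_start,
                                gtol=1e-8):
    """min q over the polytope with free coordinate j fixed at t.

    The pinned coordinate is eliminated from the subproblem. Returns
    ``(min_cost, argmin_free_coords)`` or ``(inf, None)`` when the slab is
    empty.
    """
    from .thermo import _solve_mdf_lp

    red = _ReducedPoly(poly, j, t)
    if red.n_free == 0:
        xf = red.expand(np.zeros(0))
        if not poly.contains(xf):
            return np.inf, None
        q, _, _ = enzyme_cost(poly.lift(xf), net, par, flux, spec,
                              with_breakdown=False)
        return q, xf
    x0 = np.asarray(x_start, dtype=float)[red._keep]
    if not red.contains(x0, tol=1e-12):
        mdf, x_w = _solve_mdf_lp(red)
        if mdf < poly.epsilon:
            return np.inf, None
        x0 = x_w
    fg_full = _objective(poly, net, par, flux, spec, 0.0, np.zeros(poly.n_free))

    def fg(x_red):
        q, g = fg_full(red.expand(x_red))
        return q, g[red._keep]

    res = _minimize(fg, x0, red, gtol=gtol)
    return res.fun, red.expand(res.x)


def tolerance_ranges(sol, poly, net, par, flux, spec, alpha=0.01,
                     rel_tol=1e-7):
    """Ranges of metabolite and enzyme levels with cost <= (1 + alpha) q_opt.

    Metabolite endpoints are found by bisection on the coordinate value with
    a convex feasibility check (minimum cost at the pinned coordinate versus
    the tolerable cost). Enzyme lower endpoints minimize the convex demand
    over the convex tolerable region; upper endpoints take the maximum over
    the metabolite-endpoint profiles plus a local ascent, and are tagged
    heuristic.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    q_tol = (1.0 + alpha) * sol.q_opt
    x_opt_f = poly.restrict(sol.x_opt)
    m = poly.n_free
    x_ranges = np.tile(x_opt_f.reshape(-1, 1), (1, 2)) if m else np.zeros((0, 2))
    endpoint_profiles = [x_opt_f]

    def min_cost(j, t):
        q, xarg = _min_cost_with_pinned_coord(poly, net, par, flux, spec, j, t, x_opt_f)
        return q, xarg

    for j in range(m):
        for side, limit in ((1, poly.x_max[j]), (0, poly.x_min[j])):
            lo_t, hi_t = (x_opt_f[j], limit) if side == 1 else (limit, x_opt_f[j])
            if alpha == 0:
                x_ranges[j, side] = x_opt_f[j]
                continue
            q_limit, x_limit = min_cost(j, limit)
            if q_limit <= q_tol:
                x_ranges[j, side] = limit
                if x_limit is not None:
                    endpoint_profiles.append(x_limit)
                continue
            # bisection: g(t) = min-cost(t) - q_tol is monotone away from opt
            a, b = (x_opt_f[j], limit) if side == 1 else (limit, x_opt_f[j])
            if side == 0:
                a, b = b, a  # walk from optimum toward the limit
            t_in, t_out = a, b
            x_arg = x_opt_f
            for _ in range(80):
                t_mid = 0.5 * (t_in + t_out)
                q_mid, x_mid = min_cost(j, t_mid)
                if q_mid <= q_tol:
                    t_in, x_arg = t_mid, x_mid
                else:
                    t_out = t_mid
                if abs(q_mid - q_tol) <= rel_tol * q_tol or abs(t_out - t_in) < 1e-12:
                    if q_mid <= q_tol:
                        t_in, x_arg = t_mid, x_mid
                    break
            x_ranges[j, side] = t_in
            if x_arg is not None:
                endpoint_profiles.append(np.asarray(x_arg))

    # enzyme ranges over active reactions
    active = poly.active_reactions
    E_ranges = np.zeros((len(active), 2))
    methods = []
    q_cons = NonlinearConstraint(
        lambda xf: enzyme_cost(poly.lift(xf), net, par, flux, spec,
                               with_breakdown=False)[0],
        -np.inf, q_tol,
        jac=lambda xf: enzyme_cost(poly.lift(xf), net, par, flux, spec,
                                   with_breakdown=False)[1][poly.free_index].reshape(1, -1),
    )
    for k, l in enumerate(active):
        E_at_opt = sol.E_opt[l]
        if alpha == 0 or m == 0:
            E_ranges[k] = (E_at_opt, E_at_opt)
            methods.append("exact")
            continue

        def e_fun(xf, sign=1.0, l=l):
            E, gE = demand_of_reaction(poly.lift(xf), l, net, par, flux, spec)
            return sign * E, sign * gE[poly.free_index]

        res_lo = _minimize(lambda z: e_fun(z, 1.0), x_opt_f, poly,
                           extra_constraints=(q_cons,), maxiter=500)
        E_lo = min(E_at_opt, res_lo.fun) if res_lo.fun is not None else E_at_opt
        # heuristic upper endpoint: candidates + local ascent
        E_hi = E_at_opt
        for cand in endpoint_profiles:
            Ec, _ = e_fun(cand)
            E_hi = max(E_hi, Ec)
            res_hi = _minimize(lambda z: e_fun(z, -1.0), cand, poly,
                               extra_constraints=(q_cons,), maxiter=200)
            E_hi = max(E_hi, -res_hi.fun)
        E_ranges[k] = (E_lo, E_hi)
        methods.append("heuristic")
    return ToleranceRanges(
        alpha=alpha,
        metabolite_ids=[net.metabolite_ids[i] for i in poly.free_index],
        x_ranges=x_ranges,
        reaction_ids=[net.reaction_ids[l] for l in active],
        E_ranges=E_ranges,
        enzyme_upper_method=methods,
    )
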