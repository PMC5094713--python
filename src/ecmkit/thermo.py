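"""Thermodynamic driving forces, the metabolite polytope, and the
max-min driving force (MDF) linear program.

The driving force of reaction l at log-concentrations x is
``Theta_l = -DeltaG'_l / RT = ln K_eq,l - sum_i n_il x_i``; a reaction can
carry positive (oriented) flux iff Theta_l > 0. Concentration bounds define
P-faces of the polytope, the driving-force constraints define E-faces, and
strict positivity is encoded as ``Theta_l >= epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .exceptions import ThermodynamicInfeasibilityError

DEFAULT_EPSILON = 1e-9


@dataclass
class DrivingForces:
    """Per-reaction driving forces Theta in RT units (unitless)."""

    reaction_ids: list
    theta: np.ndarray


def driving_forces(x, net, par):
    """Driving forces Theta_l = ln K_eq,l - sum_i n_il x_i at the profile ``x``.

    ``x`` is a full-length log-concentration vector (ln mM, fixed metabolites
    substituted). Equivalently Theta = ln(K_eq / Q) with Q the mass-action
    ratio, or -(DeltaG'0/RT + sum n x).
    """
    x = np.asarray(x, dtype=float)
    theta = par.ln_keq() - net.stoichiometry.T @ x
    return DrivingForces(list(net.reaction_ids), theta)


@dataclass
class MetabolitePolytope:
    """Feasible log-concentration region of the free metabolites.

    Constraints are ``A @ x_free + b0 >= epsilon`` (one row per active
    reaction; fixed metabolites are folded into the offsets ``b0``) together
    with the box ``x_min <= x_free <= x_max``. ``witness`` is an interior
    point maximizing the minimum driving-force slack (the MDF profile).
    """

    free_index: np.ndarray
    x_min: np.ndarray
    x_max: np.ndarray
    A: np.ndarray
    b0: np.ndarray
    epsilon: float
    active_reactions: np.ndarray
    reaction_ids: list
    fixed_log_values: np.ndarray  # full-length; NaN on free coordinates
    witness: np.ndarray | None = None  # full-length
    mdf: float | None = None

    @property
    def n_free(self):
        return len(self.free_index)

    def lift(self, x_free):
        """Embed free coordinates into a full-length log-concentration vector."""
        x = self.fixed_log_values.copy()
        x[self.free_index] = x_free
        return x

    def restrict(self, x_full):
        return np.asarray(x_full, dtype=float)[self.free_index]

    def theta(self, x_free):
        return self.A @ np.asarray(x_free, dtype=float) + self.b0

    def contains(self, x_free, tol=0.0):
        x_free = np.asarray(x_free, dtype=float)
        return (np.all(self.theta(x_free) >= self.epsilon - tol)
                and np.all(x_free >= self.x_min - tol)
                and np.all(x_free <= self.x_max + tol))

    def midpoint(self):
        return 0.5 * (self.x_min + self.x_max)


def build_polytope(net, par, flux, bounds, epsilon=DEFAULT_EPSILON,
                   min_driving_forces=None, require_feasible=True):
    """Construct the metabolite polytope for an oriented model.

    ``min_driving_forces`` optionally sets per-reaction lower bounds on
    Theta (defaults to ``epsilon`` everywhere). Raises
    :class:`ThermodynamicInfeasibilityError` (reporting an irreducible
    infeasible constraint subset) if the polytope is empty, unless
    ``require_feasible`` is false.
    """
    if np.any(flux.v < 0):
        raise ValueError("reactions must be oriented (all active fluxes positive)")
    free = np.where(~net.fixed_mask)[0]
    fixed_log = np.full(net.n_metabolites, np.nan)
    fixed_log[net.fixed_mask] = np.log(net.fixed_values[net.fixed_mask])
    active = np.where(flux.active_mask)[0]
    N = net.stoichiometry
    A = -N[free][:, active].T
    b0 = par.ln_keq()[active].copy()
    for l_pos, l in enumerate(active):
        fixed_part = N[net.fixed_mask, l] @ fixed_log[net.fixed_mask]
        b0[l_pos] -= fixed_part
    eps_vec = np.full(len(active), epsilon)
    if min_driving_forces is not None:
        eps_vec = np.maximum(eps_vec, np.asarray(min_driving_forces)[active])
    poly = MetabolitePolytope(
        free_index=free,
        x_min=np.log(bounds.lb[free]),
        x_max=np.log(bounds.ub[free]),
        A=A,
        b0=b0 - (eps_vec - epsilon),  # fold per-reaction minima into offsets
        epsilon=epsilon,
        active_reactions=active,
        reaction_ids=[net.reaction_ids[l] for l in active],
        fixed_log_values=fixed_log,
    )
    mdf, x_mdf_free = _solve_mdf_lp(poly)
    poly.mdf = mdf
    poly.witness = poly.lift(x_mdf_free)
    if require_feasible and mdf < epsilon:
        subset = _irreducible_infeasible_subset(poly)
        raise ThermodynamicInfeasibilityError(
            "the given flux directions are thermodynamically infeasible within "
            "the concentration bounds: the metabolite polytope is empty "
            f"(max-min driving force {mdf:.3g} < epsilon). Irreducible "
            f"infeasible driving-force constraints: {subset}",
            infeasible_reactions=subset,
        )
    return poly


def _solve_mdf_lp(poly, rows=None):
    """Maximize t subject to A x + b0 >= t and the box bounds."""
    m = poly.n_free
    if rows is None:
        rows = np.arange(poly.A.shape[0])
    A, b0 = poly.A[rows], poly.b0[rows]
    if len(rows) == 0:
        return np.inf, poly.midpoint()
    # variables (x_free, t); minimize -t
    c = np.zeros(m + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-A, np.ones((len(rows), 1))])
    b_ub = b0
    lp_bounds = [(lo, hi) for lo, hi in zip(poly.x_min, poly.x_max)] + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=lp_bounds, method="highs")
    if not res.success:
        raise ThermodynamicInfeasibilityError(
            f"MDF linear program failed: {res.message}")
    return -res.fun, res.x[:m]


def max_min_driving_force(poly):
    """Max-min driving force over the polytope's constraints.

    Returns ``(mdf, x_mdf)`` where ``x_mdf`` is a full-length log-concentration
    profile attaining ``min_l Theta_l = mdf``. The polytope is nonempty (at
    margin epsilon) iff ``mdf >= epsilon``.
    """
    if poly.mdf is not None and poly.witness is not None:
        return poly.mdf, poly.witness.copy()
    mdf, x_free = _solve_mdf_lp(poly)
    return mdf, poly.lift(x_free)


def _irreducible_infeasible_subset(poly):
    """Deletion-filter an irreducible infeasible subset of E-face constraints."""
    rows = list(range(poly.A.shape[0]))

    def feasible(subset):
        mdf, _ = _solve_mdf_lp(poly, rows=np.array(subset, dtype=int))
        return mdf >= poly.epsilon

    if feasible(rows):
        return []
    keep = list(rows)
    for r in rows:
        trial = [k for k in keep if k != r]
        if trial and not feasible(trial):
            keep = trial
    return [poly.reaction_ids[r] for r in keep]


def extreme_points(poly):
    """Coordinate-wise extreme points of the polytope.

    Returns 2m full-length profiles (m = number of free metabolites), each
    minimizing or maximizing one free coordinate; with m = 0 a single point
    (the fixed profile) is returned.
    """
    m = poly.n_free
    if m == 0:
        return [poly.lift(np.zeros(0))]
    points = []
    lp_bounds = [(lo, hi) for lo, hi in zip(poly.x_min, poly.x_max)]
    A_ub = -poly.A
    b_ub = poly.b0 - poly.epsilon
    for j in range(m):
        for sign in (+1.0, -1.0):
            c = np.zeros(m)
            c[j] = sign
            res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=lp_bounds, method="highs")
            if not res.success:
                raise ThermodynamicInfeasibilityError(
                    f"extreme-point LP failed: {res.message}")
            points.append(poly.lift(res.x))
    return points
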