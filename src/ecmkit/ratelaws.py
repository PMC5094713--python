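"""Separable rate-law efficiency factors and the tiered enzyme cost functions.

An oriented reaction with flux v, enzyme level E and forward turnover kcat+
factorizes as ``v = E * kcat+ * eta_rev * eta_sat * eta_reg`` with all
efficiency factors in (0, 1]:

* ``eta_rev = 1 - exp(-Theta)`` — fraction of the forward flux surviving the
  microscopic backward flux, a function of the driving force alone;
* ``eta_sat`` — saturation factor, S / D with mass-action terms
  ``S = prod_i (s_i/K_M,i)^{|n_i|}`` and ``P = prod_j (p_j/K_M,j)^{|n_j|}``
  and a variant-specific denominator D;
* ``eta_reg`` — allosteric factor, here the noncompetitive-inhibition
  prefactor ``1/(1 + c_I/K_I)``.

The tiers (``CostFunctionSpec.variant``):

========  =========================================================
EMC0      sum of fluxes (uniform weights; constant in x)
EMC1      capacity-based, q = sum h_E v / kcat+ (constant in x)
EMC2S     reversibility-based, denominator D = S, eta_sat = 1
EMC2SP    reversibility-based, D = S + P; via the Haldane substitution
          eta_sat = 1 / (1 + exp(-Theta) * kcat+/kcat-)
EMC3S     saturation-based, D = 1 + S
EMC3SP    saturation-based, D = 1 + S + P
EMC4CM    common modular rate law,
          D = prod_i (1+s_i/K)^{|n|} + prod_j (1+p_j/K)^{|n|} - 1
========  =========================================================

Each tier is a lower bound on the next; enzyme cost is convex in the
metabolite log-concentrations for every tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InfeasiblePointError, MissingParameterError

VARIANTS = ("EMC0", "EMC1", "EMC2S", "EMC2SP", "EMC3S", "EMC3SP", "EMC4CM")
BURDEN_MODES = ("uniform", "protein_mass", "chain_length", "custom")


@dataclass
class CostFunctionSpec:
    """Choice of cost tier, regulation handling, and burden weighting.

    ``burden_mode='custom'`` (default) takes the per-reaction burdens h_E from
    the parameter set (which default to 1, i.e. uniform); ``protein_mass``
    uses the protein mass in Da so that the cost is in mg protein per liter;
    ``chain_length`` uses mass divided by the median mass (a proxy for amino
    acid chain length over its median). ``extra_regulation`` may hold a
    callable ``f(x_full) -> (eta, grad_minus_ln_eta)`` per reaction index with
    0 < eta <= 1 and -ln eta convex, multiplied into eta_reg.
    """

    variant: str = "EMC4CM"
    include_regulation: bool = True
    burden_mode: str = "custom"
    extra_regulation: dict = field(default_factory=dict)
    burden_function: object = None  # optional convex scalar h(E); default linear

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown cost variant {self.variant!r}; choose from {VARIANTS}")
        if self.burden_mode not in BURDEN_MODES:
            raise ValueError(f"unknown burden mode {self.burden_mode!r}")

    @property
    def tier(self):
        return int(self.variant[3])


@dataclass
class EfficiencyBreakdown:
    """Per-active-reaction efficiency factors, demands and costs."""

    reaction_ids: list
    eta_rev: np.ndarray
    eta_sat: np.ndarray
    eta_reg: np.ndarray
    demand: np.ndarray  # enzyme level E_l in mM
    cost: np.ndarray    # q_l = h_El * E_l
    total_cost: float


def burdens(spec, par):
    """Per-reaction burden weights h_E for the chosen mode."""
    if spec.burden_mode == "uniform":
        return np.ones_like(par.burden)
    if spec.burden_mode == "custom":
        return par.burden.copy()
    mass = par.protein_mass
    if not np.all(np.isfinite(mass)):
        raise MissingParameterError(
            f"burden mode {spec.burden_mode!r} requires protein masses for all reactions")
    if spec.burden_mode == "protein_mass":
        return mass.copy()
    return mass / np.median(mass)  # chain_length: length ratio == mass ratio


def validate_spec(spec, net, par, flux):
    """Fail fast if parameters required by the cost tier are absent."""
    active = np.where(flux.active_mask)[0]
    if spec.tier >= 1 and not np.all(np.isfinite(par.kcat_fwd[active])):
        raise MissingParameterError("kcat+ required for every active reaction")
    if spec.tier >= 2 and not np.all(np.isfinite(par.K_eq[active])):
        raise MissingParameterError("K_eq required for every active reaction")
    if spec.variant == "EMC2SP" and not np.all(np.isfinite(par.kcat_rev[active])):
        raise MissingParameterError("EMC2SP requires kcat- (or a balanced parameter set)")
    if spec.tier >= 3:
        for l in active:
            idx = np.where(net.stoichiometry[:, l] != 0)[0]
            if not np.all(np.isfinite(par.K_M[idx, l])):
                raise MissingParameterError(
                    f"K_M required for all reactants of {net.reaction_ids[l]!r} "
                    f"under {spec.variant}")
    burdens(spec, par)


def eta_rev(theta):
    """Reversibility efficiency ``1 - exp(-Theta)``, clipped to 0 for Theta <= 0."""
    theta = np.asarray(theta, dtype=float)
    out = -np.expm1(-theta)
    return np.where(theta > 0, out, 0.0) if out.ndim else (out if theta > 0 else 0.0)


def eta_kin(x, l, net, par, variant, spec=None):
    """Kinetic efficiency factor (saturation part) of reaction ``l`` at ``x``."""
    e, _ = _kin_terms(np.asarray(x, dtype=float), l, net, par, variant)
    return e


def _reg_terms(x, l, par, spec):
    """(eta_reg, gradient of -ln eta_reg) for reaction ``l`` at full profile x."""
    eta = 1.0
    grad = np.zeros_like(x)
    if not spec.include_regulation:
        return eta, grad
    for (rl, i, ki, mech) in par.modifiers:
        if rl != l:
            continue
        ratio = np.exp(x[i]) / ki  # c_I / K_I, noncompetitive prefactor
        eta /= 1.0 + ratio
        grad[i] += ratio / (1.0 + ratio)
    fn = spec.extra_regulation.get(l)
    if fn is not None:
        e, g = fn(x)
        eta *= e
        grad += g
    return eta, grad


def _kin_terms(x, l, net, par, variant):
    """(eta_sat, gradient of -ln eta_sat) for reaction ``l``.

    Stoichiometric coefficients enter the mass-action terms with exponent
    |n_il|. Returns eta_sat = 1 with zero gradient for tiers without a
    saturation term (EMC0/1/2S).
    """
    n = net.stoichiometry[:, l]
    grad = np.zeros_like(x)
    if variant in ("EMC0", "EMC1", "EMC2S"):
        return 1.0, grad
    subs = np.where(n < 0)[0]
    prods = np.where(n > 0)[0]
    if variant == "EMC2SP":
        theta = np.log(par.K_eq[l]) - n @ x
        r = par.kcat_fwd[l] / par.kcat_rev[l]
        z = np.exp(-theta) * r
        eta = 1.0 / (1.0 + z)
        grad[subs] += (z / (1.0 + z)) * n[subs]
        grad[prods] += (z / (1.0 + z)) * n[prods]
        return eta, grad
    a = -n[subs]  # positive exponents
    b = n[prods]
    ln_s_ratio = x[subs] - np.log(par.K_M[subs, l])
    ln_p_ratio = x[prods] - np.log(par.K_M[prods, l])
    S = np.exp(a @ ln_s_ratio)
    P = np.exp(b @ ln_p_ratio)
    if variant == "EMC3S":
        D = 1.0 + S
        grad[subs] += (S / D) * a - a
        return S / D, grad
    if variant == "EMC3SP":
        D = 1.0 + S + P
        grad[subs] += (S / D) * a - a
        grad[prods] += (P / D) * b
        return S / D, grad
    # EMC4CM: common modular denominator
    u = np.exp(ln_s_ratio)  # s_i / K_M
    wv = np.exp(ln_p_ratio)
    DS = np.prod((1.0 + u) ** a)
    DP = np.prod((1.0 + wv) ** b)
    D = DS + DP - 1.0
    grad[subs] += (DS / D) * a * (u / (1.0 + u)) - a
    grad[prods] += (DP / D) * b * (wv / (1.0 + wv))
    return S / D, grad


def _demand_terms(x, l, net, par, flux, spec, h):
    """Cost q_l, demand E_l, factors and gradient of ln q_l for one reaction."""
    n = net.stoichiometry[:, l]
    v = flux.v[l]
    if spec.variant == "EMC0":
        return v, v, (1.0, 1.0, 1.0), np.zeros_like(x)
    cap = h[l] * v / par.kcat_fwd[l]
    if spec.variant == "EMC1":
        return cap, v / par.kcat_fwd[l], (1.0, 1.0, 1.0), np.zeros_like(x)
    theta = np.log(par.K_eq[l]) - n @ x
    if theta <= 0:
        raise InfeasiblePointError(
            f"non-positive driving force ({theta:.3g}) in active reaction "
            f"{net.reaction_ids[l]!r}: metabolite profile is outside the polytope")
    erev = -np.expm1(-theta)
    grad = np.zeros_like(x)
    grad += (np.exp(-theta) / erev) * n  # d(-ln eta_rev)/dx
    esat, gsat = _kin_terms(x, l, net, par, spec.variant)
    ereg, greg = _reg_terms(x, l, par, spec)
    grad += gsat + greg
    E = v / (par.kcat_fwd[l] * erev * esat * ereg)
    if spec.burden_function is not None:
        q_l = spec.burden_function(E)
    else:
        q_l = h[l] * E
    return q_l, E, (erev, esat, ereg), grad


def enzyme_demand(x, net, par, flux, spec):
    """Per-reaction enzyme demand E_l (mM) at the full log-profile ``x``.

    ``E_l = v_l / (kcat+ eta_rev eta_sat eta_reg)``; inactive reactions get 0.
    Raises :class:`InfeasiblePointError` if any active reaction has a
    non-positive driving force (tiers >= EMC2).
    """
    x = np.asarray(x, dtype=float)
    h = burdens(spec, par)
    E = np.zeros(net.n_reactions)
    for l in np.where(flux.active_mask)[0]:
        _, E[l], _, _ = _demand_terms(x, l, net, par, flux, spec, h)
    return E


def enzyme_cost(x, net, par, flux, spec, with_breakdown=True):
    """Total enzyme cost, its gradient in x, and the efficiency breakdown.

    Returns ``(q, dq_dx, EfficiencyBreakdown)``; the gradient is with respect
    to the full log-concentration vector (restrict to free coordinates for
    optimization). Cost is constant in x for EMC0/EMC1.
    """
    x = np.asarray(x, dtype=float)
    h = burdens(spec, par)
    active = np.where(flux.active_mask)[0]
    grad = np.zeros_like(x)
    q = 0.0
    rows = []
    for l in active:
        q_l, E_l, (erev, esat, ereg), g_lnq = _demand_terms(x, l, net, par, flux, spec, h)
        q += q_l
        if spec.burden_function is not None:
            # chain rule through the nonlinear burden; central difference for h'
            dE = 1e-7 * max(E_l, 1.0)
            hprime = (spec.burden_function(E_l + dE) - spec.burden_function(E_l - dE)) / (2 * dE)
            grad += hprime * E_l * g_lnq
        else:
            grad += q_l * g_lnq  # dq_l/dx = q_l * d(ln q_l)/dx (linear burden)
        rows.append((erev, esat, ereg, E_l, q_l))
    if not with_breakdown:
        return q, grad, None
    arr = np.array(rows) if rows else np.zeros((0, 5))
    breakdown = EfficiencyBreakdown(
        reaction_ids=[net.reaction_ids[l] for l in active],
        eta_rev=arr[:, 0], eta_sat=arr[:, 1], eta_reg=arr[:, 2],
        demand=arr[:, 3], cost=arr[:, 4], total_cost=q,
    )
    return q, grad, breakdown


def demand_of_reaction(x, l, net, par, flux, spec):
    """(E_l, dE_l/dx) for a single active reaction; used for tolerance ranges."""
    h = burdens(spec, par)
    q_l, E_l, _, g_lnq = _demand_terms(np.asarray(x, dtype=float), l, net, par, flux, spec, h)
    return E_l, E_l * g_lnq


def flux_burden(x, net, par, flux, spec):
    """Flux-specific enzyme costs a_vl = q_l / v_l and their lower bound a_cat.

    ``a_vl = h_E / (kcat+ eta_rev eta_sat eta_reg) >= a_cat = h_E / kcat+``;
    ``sum_l a_vl v_l`` reproduces the total enzyme cost. Returns
    ``(a_v, a_cat)`` arrays over active reactions.
    """
    x = np.asarray(x, dtype=float)
    h = burdens(spec, par)
    active = np.where(flux.active_mask)[0]
    a_v = np.zeros(len(active))
    for k, l in enumerate(active):
        q_l, _, _, _ = _demand_terms(x, l, net, par, flux, spec, h)
        a_v[k] = q_l / flux.v[l]
    a_cat = h[active] / par.kcat_fwd[active]
    if spec.variant == "EMC0":
        a_cat = np.ones(len(active))
    return a_v, a_cat


def pathway_specific_activity(flux_pw, q_mass):
    """Pathway specific activity A_pw = v_pw / q.

    With mass-based burdens (h_E = protein mass in Da) the cost q is in
    mg protein per liter, so for a pathway flux in mM/s the ratio is in
    mmol per second per mg of enzyme. Doubling all enzyme levels at fixed
    flux halves the activity.
    """
    if flux_pw == 0:
        return 0.0
    if q_mass <= 0:
        raise ValueError("mass-based enzyme cost must be positive")
    return flux_pw / q_mass
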