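"""Monte-Carlo sensitivity analysis and the cost-optimality test.

Parameter uncertainty is propagated by sampling the free kinetic basis —
per-metabolite formation energies, ln K_M, ln kcat+ — with independent
normals in log space and deriving K_eq and kcat- from it, so every sampled
parameter set satisfies the Haldane relationships exactly. Fluxes are
perturbed multiplicatively (redrawing any sample that would flip a flux
sign, since orientation must be preserved) and fixed metabolite levels
uniformly within a relative range.

The cost-optimality test compares enzyme predictions from the cost optimum
with predictions from metabolite profiles sampled (i) locally around the
optimum in ln space and (ii) broadly, as flat-Dirichlet convex combinations
of the polytope's coordinate-wise extreme points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EcmError, MissingParameterError
from .model_io import KineticParameters, FluxProfile, fitted_formation_energies
from .ratelaws import enzyme_demand
from .reporting import prediction_metrics
from .solver import ecm_solve
from .thermo import build_polytope, extreme_points

LN10 = np.log(10.0)


@dataclass
class SamplingConfig:
    """Noise magnitudes and bookkeeping for all Monte-Carlo operations.

    Defaults: log10-sd 0.2 for K_M and kcat+, 0.05 RT for formation
    energies, 15% relative flux error, +/-5% range on fixed metabolite
    levels, and ln-sd 0.05 for local metabolite sampling.
    """

    n_samples: int = 100
    seed: int = 0
    log10_sd_km: float = 0.2
    log10_sd_kcat: float = 0.2
    sd_formation_rt: float = 0.05
    flux_rel_sd: float = 0.15
    fixed_conc_rel_range: float = 0.05
    local_ln_sd: float = 0.05

    def __post_init__(self):
        for name in ("log10_sd_km", "log10_sd_kcat", "sd_formation_rt",
                     "flux_rel_sd", "fixed_conc_rel_range", "local_ln_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def sample_parameters(net, par, config):
    """Draw ``n_samples`` Haldane-consistent kinetic parameter sets.

    Requires a balanced base set (formation energies present or derivable
    from K_eq). Zero standard deviations reproduce the base set exactly;
    draws are reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    g0 = fitted_formation_energies(net, par)
    lnkm0 = np.log(par.K_M)
    lnkf0 = np.log(par.kcat_fwd)
    reactant = net.stoichiometry != 0
    out = []
    for _ in range(config.n_samples):
        g = g0 + rng.normal(0.0, config.sd_formation_rt, size=g0.shape)
        lnkm = np.where(reactant,
                        lnkm0 + rng.normal(0.0, LN10 * config.log10_sd_km,
                                           size=lnkm0.shape),
                        np.nan)
        lnkf = lnkf0 + rng.normal(0.0, LN10 * config.log10_sd_kcat, size=lnkf0.shape)
        ln_keq = -net.stoichiometry.T @ g
        ln_krev = lnkf - ln_keq + np.nansum(
            net.stoichiometry * np.where(reactant, lnkm, 0.0), axis=0)
        out.append(KineticParameters(
            np.exp(lnkf), np.exp(ln_krev), np.exp(lnkm), np.exp(ln_keq), -ln_keq,
            par.burden.copy(), par.protein_mass.copy(), modifiers=list(par.modifiers),
            km_default_mask=par.km_default_mask.copy(), formation_energies=g,
            kcat_inf=par.kcat_inf,
        ))
    return out


def _sample_flux(flux, rng, rel_sd, max_tries=1000):
    v = flux.v.copy()
    for l in np.where(flux.active_mask)[0]:
        for _ in range(max_tries):
            cand = flux.v[l] * (1.0 + rng.normal(0.0, rel_sd))
            if cand * flux.v[l] > 0:
                v[l] = cand
                break
        else:
            raise EcmError("could not sample a sign-preserving flux")
    return FluxProfile(v, flux.active_mask.copy())


@dataclass
class MonteCarloResult:
    summary: pd.DataFrame          # per active reaction: median, q25, q75
    enzyme_samples: np.ndarray     # (n_feasible, n_active)
    solutions: list
    n_samples: int = 0
    n_infeasible: int = 0
    warn_majority_infeasible: bool = False
    seed: int = 0


def monte_carlo_ecm(net, par, flux, bounds, spec, config):
    """Propagate parameter, flux and boundary-level noise through ECM.

    Solves ECM for each sampled condition; infeasible samples are counted
    and reported (a warning flag is set if they exceed half the draws).
    Summaries are medians with 25%/75% quantiles of the enzyme levels.
    """
    par_samples = sample_parameters(net, par, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    active = np.where(flux.active_mask)[0]
    rows, sols = [], []
    n_infeasible = 0
    for par_s in par_samples:
        flux_s = _sample_flux(flux, rng, config.flux_rel_sd)
        net_s = _perturb_fixed(net, rng, config.fixed_conc_rel_range)
        try:
            poly = build_polytope(net_s, par_s, flux_s, bounds)
            sol = ecm_solve(poly, net_s, par_s, flux_s, spec, seed=config.seed)
        except EcmError:
            n_infeasible += 1
            continue
        rows.append(sol.E_opt[active])
        sols.append(sol)
    E = np.array(rows) if rows else np.zeros((0, len(active)))
    if len(rows):
        summary = pd.DataFrame({
            "reaction": [net.reaction_ids[l] for l in active],
            "median": np.median(E, axis=0),
            "q25": np.quantile(E, 0.25, axis=0),
            "q75": np.quantile(E, 0.75, axis=0),
        })
    else:
        summary = pd.DataFrame(columns=["reaction", "median", "q25", "q75"])
    return MonteCarloResult(summary, E, sols, n_samples=config.n_samples,
                            n_infeasible=n_infeasible,
                            warn_majority_infeasible=n_infeasible > config.n_samples / 2,
                            seed=config.seed)


def _perturb_fixed(net, rng, rel_range):
    from .model_io import NetworkModel
    values = net.fixed_values.copy()
    fixed = np.where(net.fixed_mask)[0]
    values[fixed] *= 1.0 + rng.uniform(-rel_range, rel_range, size=len(fixed))
    return NetworkModel(list(net.metabolite_ids), list(net.reaction_ids),
                        net.stoichiometry.copy(), net.fixed_mask.copy(), values)


def sample_metabolite_profiles(poly, x_opt=None, mode="broad", config=None):
    """Sample feasible metabolite log-profiles from the polytope.

    ``mode='local'`` adds normal noise (sd ``config.local_ln_sd``) to the
    optimum on the free coordinates, rejecting infeasible draws (an error is
    raised if fewer than 1% of draws are accepted); ``mode='broad'`` draws
    flat-Dirichlet convex combinations of the coordinate-wise extreme
    points. Returns a list of full-length profiles, reproducible per seed.
    """
    config = config or SamplingConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_samples
    if mode == "local":
        if x_opt is None:
            raise ValueError("local mode requires the optimal profile")
        xf0 = poly.restrict(x_opt)
        out = []
        attempts = 0
        max_attempts = max(1000, 200 * n)
        while len(out) < n:
            if attempts >= max_attempts and len(out) < attempts / 100:
                raise EcmError(
                    "local-mode rejection rate exceeds 99%; decrease local_ln_sd")
            xf = xf0 + rng.normal(0.0, config.local_ln_sd, size=poly.n_free)
            attempts += 1
            if poly.contains(xf):
                out.append(poly.lift(xf))
        return out
    if mode != "broad":
        raise ValueError("mode must be 'local' or 'broad'")
    pts = extreme_points(poly)
    P = np.array([poly.restrict(p) for p in pts])
    W = rng.dirichlet(np.ones(len(pts)), size=n)
    return [poly.lift(w @ P) for w in W]


def cost_optimality_test(net, par, flux, bounds, spec, measured, config=None):
    """Compare enzyme predictions at the cost optimum against sampled profiles.

    Requires measured enzyme levels for at least two active reactions.
    Returns a table with one row per profile — classes ``optimum``, ``local``
    and ``broad`` — carrying the total enzyme cost and the RMSE (log10) of
    the predicted versus measured enzyme levels.
    """
    config = config or SamplingConfig()
    active = np.where(flux.active_mask)[0]
    have = np.isfinite(measured.enzyme_conc[active])
    if have.sum() < 2:
        missing = [net.reaction_ids[l] for l in active[~have]]
        raise MissingParameterError(
            f"cost-optimality test needs measured enzyme levels for >= 2 active "
            f"reactions; missing: {missing}")
    poly = build_polytope(net, par, flux, bounds)
    sol = ecm_solve(poly, net, par, flux, spec, seed=config.seed)
    meas = pd.Series(measured.enzyme_conc[active],
                     index=[net.reaction_ids[l] for l in active])

    def rmse_of(E_active):
        pred = pd.Series(E_active, index=meas.index)
        return prediction_metrics(pred, meas).rmse_log10

    from .ratelaws import enzyme_cost
    rows = [("optimum", sol.q_opt, rmse_of(sol.E_opt[active]))]
    for mode in ("local", "broad"):
        for x in sample_metabolite_profiles(poly, sol.x_opt, mode, config):
            E = enzyme_demand(x, net, par, flux, spec)
            q, _, _ = enzyme_cost(x, net, par, flux, spec, with_breakdown=False)
            rows.append((mode, q, rmse_of(E[active])))
    return pd.DataFrame(rows, columns=["profile_class", "cost", "enzyme_rmse"])
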