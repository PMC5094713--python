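"""Built-in models: the three-reaction toy pathway, random thermodynamically
consistent models, and synthetic measured data.

The toy pathway X <=> A <=> B <=> Y has all equilibrium constants, catalytic
constants, Michaelis constants and burdens equal to 1, boundary levels
[X] = 1 mM and [Y] = 0.01 mM fixed (so the total driving force is ln 100),
the intermediates A and B free within 1e-3 to 10 mM, and a unit pathway flux.
It is the canonical end-to-end test surface: its parameters are
Haldane-consistent by construction and its polytope is nonempty iff
[X] > [Y].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EcmError
from .model_io import (
    ConcentrationBounds,
    FluxProfile,
    KineticParameters,
    MeasurementSet,
    NetworkModel,
)


@dataclass
class ToySpec:
    """Study conditions of the toy pathway (concentrations mM, flux mM/s)."""

    conc_x: float = 1.0
    conc_y: float = 0.01
    flux: float = 1.0
    bound_lo: float = 1e-3
    bound_hi: float = 10.0
    protein_mass_da: float = 40000.0

    def __post_init__(self):
        if self.conc_x <= 0 or self.conc_y <= 0:
            raise ValueError("boundary concentrations must be positive")


def toy_pathway(spec=None):
    """Model bundle for the linear pathway X <=> A <=> B <=> Y.

    Returns ``(net, par, flux, bounds, measurements)`` with all kinetic
    constants equal to 1 and an empty measurement set.
    """
    spec = spec or ToySpec()
    mets = ["X", "A", "B", "Y"]
    rxns = ["R1", "R2", "R3"]
    N = np.array([
        [-1.0, 0.0, 0.0],
        [1.0, -1.0, 0.0],
        [0.0, 1.0, -1.0],
        [0.0, 0.0, 1.0],
    ])
    fixed = np.array([True, False, False, True])
    fixed_values = np.array([spec.conc_x, np.nan, np.nan, spec.conc_y])
    net = NetworkModel(mets, rxns, N, fixed, fixed_values)
    K_M = np.where(N != 0, 1.0, np.nan)
    par = KineticParameters(
        kcat_fwd=np.ones(3), kcat_rev=np.ones(3), K_M=K_M,
        K_eq=np.ones(3), dG0_over_RT=np.zeros(3),
        burden=np.ones(3), protein_mass=np.full(3, spec.protein_mass_da),
        formation_energies=np.zeros(4),
    )
    flux = FluxProfile(np.full(3, spec.flux))
    lb = np.full(4, spec.bound_lo)
    ub = np.full(4, spec.bound_hi)
    lb[fixed] = np.minimum(lb[fixed], fixed_values[fixed])
    ub[fixed] = np.maximum(ub[fixed], fixed_values[fixed])
    bounds = ConcentrationBounds(lb, ub)
    return net, par, flux, bounds, MeasurementSet.empty(4, 3)


def random_model(n_metabolites, topology="chain", seed=0, max_tries=100):
    """Random thermodynamically consistent model bundle.

    Formation energies are drawn first and equilibrium constants derived
    from them (hence Wegscheider-consistent); K_M and kcat+ are log-normal
    and kcat- follows from the Haldane relationship. Boundary concentrations
    are redrawn until the flux profile is thermodynamically feasible within
    the bounds (checked before returning). Deterministic per seed.

    ``topology='chain'`` builds a linear pathway with fixed end metabolites;
    ``'branched'`` splits the flux halfway into a branch toward an extra
    fixed sink.
    """
    if n_metabolites < 3:
        raise ValueError("need at least 3 metabolites")
    rng = np.random.default_rng(seed)
    mets = [f"M{i}" for i in range(n_metabolites)]
    if topology == "chain":
        edges = [(i, i + 1) for i in range(n_metabolites - 1)]
        fixed_idx = [0, n_metabolites - 1]
        v = np.ones(len(edges))
    elif topology == "branched":
        chain_len = n_metabolites - 1  # last metabolite is the branch sink
        bp = max(1, (chain_len - 1) // 2)
        edges = [(i, i + 1) for i in range(chain_len - 1)]
        edges.append((bp, n_metabolites - 1))
        fixed_idx = [0, chain_len - 1, n_metabolites - 1]
        v = np.array([1.0 if i <= bp - 1 else 0.5 for i in range(chain_len - 1)]
                     + [0.5])
    else:
        raise ValueError("topology must be 'chain' or 'branched'")
    n_rxn = len(edges)
    N = np.zeros((n_metabolites, n_rxn))
    for l, (i, j) in enumerate(edges):
        N[i, l] = -1.0
        N[j, l] = 1.0
    g = rng.normal(0.0, 1.5, size=n_metabolites)
    ln_keq = -N.T @ g
    K_M = np.where(N != 0,
                   10.0 ** rng.normal(-1.0, 0.5, size=N.shape),
                   np.nan)
    kcat_fwd = 10.0 ** rng.normal(1.0, 0.5, size=n_rxn)
    reactant = N != 0
    ln_krev = (np.log(kcat_fwd) - ln_keq
               + np.nansum(N * np.where(reactant, np.log(K_M), 0.0), axis=0))
    par = KineticParameters(kcat_fwd, np.exp(ln_krev), K_M,
                            np.exp(ln_keq), -ln_keq,
                            np.ones(n_rxn), np.full(n_rxn, np.nan),
                            formation_energies=g)
    flux = FluxProfile(v)
    fixed_mask = np.zeros(n_metabolites, dtype=bool)
    fixed_mask[fixed_idx] = True
    lb = np.full(n_metabolites, 1e-4)
    ub = np.full(n_metabolites, 20.0)
    bounds = ConcentrationBounds(lb, ub)

    from .thermo import build_polytope
    from .exceptions import ThermodynamicInfeasibilityError
    source = fixed_idx[0]
    sinks = fixed_idx[1:]
    for _ in range(max_tries):
        fixed_values = np.full(n_metabolites, np.nan)
        fixed_values[source] = 10.0 ** rng.uniform(0.0, 1.0)   # 1-10 mM source
        for s in sinks:
            fixed_values[s] = 10.0 ** rng.uniform(-3.0, -1.0)  # low sinks
        net = NetworkModel(mets, [f"R{l + 1}" for l in range(n_rxn)], N,
                           fixed_mask, fixed_values)
        try:
            poly = build_polytope(net, par, flux, bounds)
        except ThermodynamicInfeasibilityError:
            continue
        if poly.mdf > 0.05:  # require a comfortably nonempty polytope
            return net, par, flux, bounds, MeasurementSet.empty(n_metabolites, n_rxn)
    raise EcmError(
        f"no thermodynamically feasible boundary concentrations found in "
        f"{max_tries} draws for topology {topology!r}")


def synthetic_measurements(net, flux, sol, noise_log10_sd, seed=0):
    """Synthetic measured data: the solution's own predictions times
    log-normal noise (log10-sd ``noise_log10_sd``), per entity, seeded.
    """
    if noise_log10_sd < 0:
        raise ValueError("noise_log10_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    met = sol.c_opt * 10.0 ** rng.normal(0.0, noise_log10_sd, size=net.n_metabolites)
    enz = np.full(net.n_reactions, np.nan)
    active = np.where(flux.active_mask)[0]
    enz[active] = (sol.E_opt[active]
                   * 10.0 ** rng.normal(0.0, noise_log10_sd, size=len(active)))
    return MeasurementSet(met, enz)
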