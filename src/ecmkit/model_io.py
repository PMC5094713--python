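"""Model containers, SBtab-dialect TSV input/output, reaction orientation,
and thermodynamic consistency (Haldane balancing) of kinetic parameter sets.

Internal unit conventions
-------------------------
Concentrations are carried in mM, fluxes in mM/s, catalytic constants in 1/s,
and log-concentrations as x = ln(c / 1 mM), i.e. relative to the standard
concentration c_sigma = 1 mM. Equilibrium constants are unitless at that
standard; standard reaction Gibbs energies are carried divided by RT
(RT = 2.4790 kJ/mol at 25 degrees C).

A "model bundle" is the 5-tuple returned by :func:`load_model`:
``(NetworkModel, KineticParameters, FluxProfile, ConcentrationBounds,
MeasurementSet)``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    CrossReferenceError,
    MissingParameterError,
    ModelFormatError,
    ParameterConflictError,
    UnderdeterminedError,
)

RT_KJ_PER_MOL = 2.4790
DEFAULT_KM_MM = 0.1
KCAT_INF = 1e8

_ARROW = "<=>"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class NetworkModel:
    """Stoichiometric network with fixed-metabolite annotations.

    ``stoichiometry`` has shape (n_metabolites, n_reactions); substrates carry
    negative coefficients. ``fixed_values`` holds concentrations in mM where
    ``fixed_mask`` is true and NaN elsewhere.
    """

    metabolite_ids: list
    reaction_ids: list
    stoichiometry: np.ndarray
    fixed_mask: np.ndarray
    fixed_values: np.ndarray

    def __post_init__(self):
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        self.fixed_values = np.asarray(self.fixed_values, dtype=float)
        n_met, n_rxn = self.stoichiometry.shape
        if len(self.metabolite_ids) != n_met or len(self.reaction_ids) != n_rxn:
            raise ModelFormatError("stoichiometry shape does not match identifier lists")
        if len(set(self.metabolite_ids)) != n_met or len(set(self.reaction_ids)) != n_rxn:
            raise ModelFormatError("identifiers must be unique")
        if np.any(np.all(self.stoichiometry == 0, axis=0)):
            raise ModelFormatError("a reaction column is all-zero")
        ok = np.isfinite(self.fixed_values) == self.fixed_mask
        if not np.all(ok):
            raise ModelFormatError("fixed_values must be present exactly where fixed_mask is true")

    @property
    def n_metabolites(self):
        return len(self.metabolite_ids)

    @property
    def n_reactions(self):
        return len(self.reaction_ids)

    def metabolite_index(self, met_id):
        try:
            return self.metabolite_ids.index(met_id)
        except ValueError:
            raise CrossReferenceError(f"unknown metabolite identifier {met_id!r}") from None

    def reaction_index(self, rxn_id):
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise CrossReferenceError(f"unknown reaction identifier {rxn_id!r}") from None

    def substrates(self, l):
        """Indices of substrates (negative stoichiometry) of reaction ``l``."""
        return np.where(self.stoichiometry[:, l] < 0)[0]

    def products(self, l):
        return np.where(self.stoichiometry[:, l] > 0)[0]


@dataclass
class KineticParameters:
    """Kinetic and thermodynamic constants plus enzyme cost weights.

    ``K_M`` is a dense (n_metabolites, n_reactions) matrix in mM with NaN for
    non-reactant pairs. ``K_eq`` is unitless at the 1 mM standard and
    ``dG0_over_RT = -ln K_eq``. ``km_default_mask`` flags K_M entries filled
    with the default prior so that saturation-based results can be audited.
    ``modifiers`` lists ``(reaction_index, metabolite_index, K_I_mM,
    'noncompetitive')`` tuples. ``formation_energies`` (per metabolite,
    RT units) are set by :func:`balance_haldane` and make the equilibrium
    constants Wegscheider-consistent by construction.
    """

    kcat_fwd: np.ndarray
    kcat_rev: np.ndarray
    K_M: np.ndarray
    K_eq: np.ndarray
    dG0_over_RT: np.ndarray
    burden: np.ndarray
    protein_mass: np.ndarray
    modifiers: list = field(default_factory=list)
    km_default_mask: np.ndarray | None = None
    formation_energies: np.ndarray | None = None
    kcat_inf: float = KCAT_INF

    def __post_init__(self):
        for name in ("kcat_fwd", "kcat_rev", "K_eq", "dG0_over_RT", "burden", "protein_mass"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.K_M = np.asarray(self.K_M, dtype=float)
        if self.km_default_mask is None:
            self.km_default_mask = np.zeros_like(self.K_M, dtype=bool)

    def ln_keq(self):
        return np.log(self.K_eq)


@dataclass
class FluxProfile:
    """Reaction fluxes in mM/s; ``active_mask`` marks nonzero entries."""

    v: np.ndarray
    active_mask: np.ndarray = None

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.active_mask is None:
            self.active_mask = self.v != 0
        self.active_mask = np.asarray(self.active_mask, dtype=bool)


@dataclass
class MeasurementSet:
    """Optional measured concentrations for validation; NaN marks missing."""

    metabolite_conc: np.ndarray
    enzyme_conc: np.ndarray

    def __post_init__(self):
        self.metabolite_conc = np.asarray(self.metabolite_conc, dtype=float)
        self.enzyme_conc = np.asarray(self.enzyme_conc, dtype=float)
        for a in (self.metabolite_conc, self.enzyme_conc):
            if np.any(a[np.isfinite(a)] < 0):
                raise ModelFormatError("measured concentrations must be nonnegative")

    @classmethod
    def empty(cls, n_metabolites, n_reactions):
        return cls(np.full(n_metabolites, np.nan), np.full(n_reactions, np.nan))


@dataclass
class ConcentrationBounds:
    """Per-metabolite physiological concentration bounds in mM."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self):
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if np.any(self.lb <= 0) or np.any(self.ub < self.lb):
            raise ModelFormatError("bounds must satisfy 0 < lb <= ub")


DEFAULT_BOUNDS_MM = (1e-6, 100.0)


# ---------------------------------------------------------------------------
# Reaction formula grammar:  "2 A + B <=> C"
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def parse_reaction_formula(formula):
    """Parse ``"2 A + B <=> C"`` into a dict metabolite -> signed coefficient."""
    if _ARROW not in formula:
        raise ModelFormatError(f"reaction formula lacks '{_ARROW}': {formula!r}")
    left, right = formula.split(_ARROW)
    coeffs = {}

    def add_side(side, sign):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            m = _TERM_RE.match(term)
            if m is None:
                raise ModelFormatError(f"malformed term {term!r} in formula {formula!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            coeffs[met] = coeffs.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    coeffs = {k: v for k, v in coeffs.items() if v != 0}
    if not coeffs:
        raise ModelFormatError(f"reaction formula is empty or balanced to zero: {formula!r}")
    return coeffs


def format_reaction_formula(net, l):
    def side(idx, sign):
        parts = []
        for i in idx:
            coeff = abs(net.stoichiometry[i, l])
            name = net.metabolite_ids[i]
            parts.append(name if coeff == 1 else f"{coeff:g} {name}")
        return " + ".join(parts)

    return f"{side(net.substrates(l), -1)} {_ARROW} {side(net.products(l), +1)}"


# ---------------------------------------------------------------------------
# SBtab-dialect parsing
# ---------------------------------------------------------------------------

_SBTAB_ATTR_RE = re.compile(r"(\w+)='([^']*)'")


def _split_tables(text):
    """Split a multi-table SBtab-dialect file into (attrs, DataFrame) pairs."""
    blocks = []
    current = None
    for line in text.splitlines():
        if line.startswith("!!SBtab"):
            current = {"attrs": dict(_SBTAB_ATTR_RE.findall(line)), "lines": []}
            blocks.append(current)
        elif current is not None and line.strip():
            current["lines"].append(line)
    tables = {}
    for block in blocks:
        name = block["attrs"].get("TableName") or block["attrs"].get("TableType")
        if not block["lines"]:
            tables[name] = pd.DataFrame()
            continue
        df = pd.read_csv(io.StringIO("\n".join(block["lines"])), sep="\t", dtype=str)
        df.columns = [c.lstrip("!") for c in df.columns]
        tables[name] = df
    return tables


def read_sbtab_tables(path):
    """Read all SBtab-dialect tables from a file or from a directory of .tsv files."""
    path = Path(path)
    if path.is_dir():
        text = "\n".join(p.read_text() for p in sorted(path.glob("*.tsv")))
    else:
        text = path.read_text()
    tables = _split_tables(text)
    if not tables:
        raise ModelFormatError(f"no SBtab table declarations found in {path}")
    return tables


_CONC_UNIT = {"mM": 1.0, "M": 1e3, "uM": 1e-3, "µM": 1e-3, "nM": 1e-6}


def _to_mm(value, unit):
    if unit is None or unit != unit or unit in ("", "mM"):
        return value
    try:
        return value * _CONC_UNIT[unit]
    except KeyError:
        raise ModelFormatError(f"unknown concentration unit {unit!r}") from None


_QT_KEQ = "equilibrium constant"
_QT_KCAT_GEO = "catalytic rate constant geometric mean"
_QT_KCAT_FWD = "substrate catalytic rate constant"
_QT_KCAT_REV = "product catalytic rate constant"
_QT_KM = "Michaelis constant"
_QT_KI = "inhibitory constant"
_QT_DG0 = "reaction gibbs energy"
_QT_MASS = "protein molecular mass"
_QT_BURDEN = "enzyme burden"


def _float(value, default=np.nan):
    if value is None or value != value or value == "":
        return default
    return float(value)


def load_model(path_or_tables):
    """Load a model bundle from SBtab-dialect tables.

    Accepts a path (file or directory) or a pre-parsed ``{name: DataFrame}``
    mapping. Returns ``(net, par, flux, bounds, measurements)`` in internal
    units; missing K_M values of reactants are filled with the 0.1 mM default
    prior and flagged in ``par.km_default_mask``.
    """
    if isinstance(path_or_tables, dict):
        tables = path_or_tables
    else:
        tables = read_sbtab_tables(path_or_tables)

    rxn_tab = tables.get("Reaction")
    if rxn_tab is None or rxn_tab.empty:
        raise ModelFormatError("Reaction table is missing or empty")
    cpd_tab = tables.get("Compound")
    if cpd_tab is None or cpd_tab.empty:
        raise ModelFormatError("Compound table is missing or empty")

    met_ids = list(cpd_tab["ID"])
    rxn_ids = list(rxn_tab["ID"])
    if len(set(met_ids)) != len(met_ids):
        raise ModelFormatError("duplicate compound identifiers")
    if len(set(rxn_ids)) != len(rxn_ids):
        raise ModelFormatError("duplicate reaction identifiers")
    n_met, n_rxn = len(met_ids), len(rxn_ids)
    met_index = {m: i for i, m in enumerate(met_ids)}

    N = np.zeros((n_met, n_rxn))
    for l, formula in enumerate(rxn_tab["ReactionFormula"]):
        for met, coeff in parse_reaction_formula(formula).items():
            if met not in met_index:
                raise CrossReferenceError(
                    f"Reaction table row {rxn_ids[l]!r} references unknown compound {met!r}"
                )
            N[met_index[met], l] = coeff

    # Compound table: fixed levels and bounds
    fixed_mask = np.zeros(n_met, dtype=bool)
    fixed_values = np.full(n_met, np.nan)
    lb = np.full(n_met, DEFAULT_BOUNDS_MM[0])
    ub = np.full(n_met, DEFAULT_BOUNDS_MM[1])
    for i, row in cpd_tab.iterrows():
        if str(row.get("IsConstant", "")).strip().lower() in ("1", "true", "yes"):
            fixed_mask[i] = True
            conc = _float(row.get("Concentration"))
            if not np.isfinite(conc):
                raise ModelFormatError(
                    f"Compound {met_ids[i]!r} is constant but has no !Concentration"
                )
            fixed_values[i] = conc
        lo = _float(row.get("Concentration:Min"))
        hi = _float(row.get("Concentration:Max"))
        if np.isfinite(lo):
            lb[i] = lo
        if np.isfinite(hi):
            ub[i] = hi

    net = NetworkModel(met_ids, rxn_ids, N, fixed_mask, fixed_values)
    bounds = ConcentrationBounds(lb, ub)

    # Parameter table
    kcat_fwd = np.full(n_rxn, np.nan)
    kcat_rev = np.full(n_rxn, np.nan)
    kcat_geo = np.full(n_rxn, np.nan)
    K_eq = np.full(n_rxn, np.nan)
    dg0 = np.full(n_rxn, np.nan)
    K_M = np.full((n_met, n_rxn), np.nan)
    burden = np.ones(n_rxn)
    mass = np.full(n_rxn, np.nan)
    modifiers = []
    seen = set()
    par_tab = tables.get("Parameter")
    if par_tab is not None and not par_tab.empty:
        for _, row in par_tab.iterrows():
            qt = row["QuantityType"].strip()
            rxn = row.get("Reaction:SBML:reaction:id")
            cpd = row.get("Compound:SBML:species:id")
            value = float(row["Value"])
            unit = row.get("Unit")
            key = (qt, rxn, cpd if qt in (_QT_KM, _QT_KI) else None)
            if key in seen:
                raise ParameterConflictError(
                    f"duplicate parameter {qt!r} for reaction {rxn!r}, compound {cpd!r}"
                )
            seen.add(key)
            if rxn is None or rxn != rxn:
                raise CrossReferenceError(f"parameter row {qt!r} lacks a reaction id")
            if rxn not in rxn_ids:
                raise CrossReferenceError(
                    f"Parameter table references reaction {rxn!r} absent from Reaction table"
                )
            l = rxn_ids.index(rxn)
            if qt == _QT_KEQ:
                K_eq[l] = value
            elif qt == _QT_DG0:
                dg0[l] = value / RT_KJ_PER_MOL  # kJ/mol -> RT units
            elif qt == _QT_KCAT_FWD:
                kcat_fwd[l] = value
            elif qt == _QT_KCAT_REV:
                kcat_rev[l] = value
            elif qt == _QT_KCAT_GEO:
                kcat_geo[l] = value
            elif qt in (_QT_KM, _QT_KI):
                if cpd not in met_index:
                    raise CrossReferenceError(
                        f"Parameter table references compound {cpd!r} absent from Compound table"
                    )
                i = met_index[cpd]
                if qt == _QT_KM:
                    K_M[i, l] = _to_mm(value, unit)
                else:
                    modifiers.append((l, i, _to_mm(value, unit), "noncompetitive"))
            elif qt == _QT_MASS:
                mass[l] = value
            elif qt == _QT_BURDEN:
                burden[l] = value
            else:
                raise ModelFormatError(f"unknown quantity type {qt!r}")

    # K_eq / dG0 reconciliation
    for l in range(n_rxn):
        if np.isfinite(K_eq[l]) and np.isfinite(dg0[l]):
            if abs(np.log(K_eq[l]) + dg0[l]) > 1e-6:
                raise ParameterConflictError(
                    f"K_eq and reaction Gibbs energy disagree for {rxn_ids[l]!r}"
                )
        elif np.isfinite(dg0[l]):
            K_eq[l] = np.exp(-dg0[l])
        elif np.isfinite(K_eq[l]):
            dg0[l] = -np.log(K_eq[l])

    # Default K_M prior for reactants lacking a value
    km_default = np.zeros_like(K_M, dtype=bool)
    reactant = N != 0
    fill = reactant & ~np.isfinite(K_M)
    K_M[fill] = DEFAULT_KM_MM
    km_default[fill] = True
    if np.any(np.isfinite(K_M) & ~reactant):
        raise CrossReferenceError("Michaelis constant given for a non-reactant pair")

    # Flux table
    v = np.zeros(n_rxn)
    flux_tab = tables.get("Flux")
    if flux_tab is not None and not flux_tab.empty:
        for _, row in flux_tab.iterrows():
            rxn = row["Reaction"]
            if rxn not in rxn_ids:
                raise CrossReferenceError(
                    f"Flux table references reaction {rxn!r} absent from Reaction table"
                )
            v[rxn_ids.index(rxn)] = float(row["Value"])
    flux = FluxProfile(v)

    # Resolve kcat_fwd from the geometric mean where possible
    par = KineticParameters(
        kcat_fwd, kcat_rev, K_M, K_eq, -np.log(K_eq), burden, mass,
        modifiers=modifiers, km_default_mask=km_default,
    )
    for l in range(n_rxn):
        if not np.isfinite(par.kcat_fwd[l]) and np.isfinite(kcat_geo[l]):
            ratio = _ln_kcat_ratio(net, par, l)  # ln(kcat+/kcat-) from Haldane
            if np.isfinite(ratio):
                par.kcat_fwd[l] = kcat_geo[l] * np.exp(ratio / 2)
                par.kcat_rev[l] = kcat_geo[l] * np.exp(-ratio / 2)
    missing = flux.active_mask & ~np.isfinite(par.kcat_fwd)
    if np.any(missing):
        bad = [rxn_ids[l] for l in np.where(missing)[0]]
        raise MissingParameterError(
            f"missing forward catalytic rate constant for active reaction(s) {bad}"
        )
    # Fill kcat_rev from Haldane where absent
    for l in range(n_rxn):
        if not np.isfinite(par.kcat_rev[l]) and np.isfinite(par.kcat_fwd[l]):
            ratio = _ln_kcat_ratio(net, par, l)
            if np.isfinite(ratio):
                par.kcat_rev[l] = par.kcat_fwd[l] * np.exp(-ratio)

    # Measurements
    meas = MeasurementSet.empty(n_met, n_rxn)
    conc_tab = tables.get("ConcentrationData")
    if conc_tab is not None and not conc_tab.empty:
        for _, row in conc_tab.iterrows():
            cpd = row["Compound"]
            if cpd not in met_index:
                raise CrossReferenceError(f"ConcentrationData references unknown compound {cpd!r}")
            meas.metabolite_conc[met_index[cpd]] = float(row["Value"])
    enz_tab = tables.get("EnzymeData")
    if enz_tab is not None and not enz_tab.empty:
        for _, row in enz_tab.iterrows():
            rxn = row["Reaction"]
            if rxn not in rxn_ids:
                raise CrossReferenceError(f"EnzymeData references unknown reaction {rxn!r}")
            meas.enzyme_conc[rxn_ids.index(rxn)] = float(row["Value"])

    return net, par, flux, bounds, meas


def _ln_kcat_ratio(net, par, l):
    """ln(kcat+/kcat-) from the Haldane relationship for reaction ``l``."""
    n = net.stoichiometry[:, l]
    idx = np.where(n != 0)[0]
    lnkm = np.log(par.K_M[idx, l])
    if not np.all(np.isfinite(lnkm)) or not np.isfinite(par.K_eq[l]):
        return np.nan
    # K_eq = (k+/k-) * prod_i K_M_i^{n_i}
    return np.log(par.K_eq[l]) - np.dot(n[idx], lnkm)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _tab(name, table_type, header, rows):
    lines = [f"!!SBtab TableName='{name}' TableType='{table_type}'"]
    lines.append("\t".join("!" + h for h in header))
    for row in rows:
        lines.append("\t".join("" if x is None else str(x) for x in row))
    return "\n".join(lines)


def _g(value):
    return f"{value:.17g}"


def write_model(path, net, par, flux, bounds, measurements=None):
    """Write a model bundle as a single SBtab-dialect TSV file."""
    blocks = []
    blocks.append(_tab("Reaction", "Reaction", ["ID", "ReactionFormula"],
                       [[r, format_reaction_formula(net, l)]
                        for l, r in enumerate(net.reaction_ids)]))
    rows = []
    for i, m in enumerate(net.metabolite_ids):
        rows.append([
            m,
            "True" if net.fixed_mask[i] else "False",
            _g(bounds.lb[i]), _g(bounds.ub[i]),
            _g(net.fixed_values[i]) if net.fixed_mask[i] else "",
        ])
    blocks.append(_tab("Compound", "Compound",
                       ["ID", "IsConstant", "Concentration:Min", "Concentration:Max",
                        "Concentration"], rows))
    prows = []

    def prow(qt, rxn, cpd, value, unit):
        prows.append([qt, rxn, cpd, _g(value), unit])

    for l, r in enumerate(net.reaction_ids):
        if np.isfinite(par.kcat_fwd[l]):
            prow(_QT_KCAT_FWD, r, "", par.kcat_fwd[l], "1/s")
        if np.isfinite(par.kcat_rev[l]):
            prow(_QT_KCAT_REV, r, "", par.kcat_rev[l], "1/s")
        if np.isfinite(par.K_eq[l]):
            prow(_QT_KEQ, r, "", par.K_eq[l], "dimensionless")
        if np.isfinite(par.protein_mass[l]):
            prow(_QT_MASS, r, "", par.protein_mass[l], "Da")
        prow(_QT_BURDEN, r, "", par.burden[l], "dimensionless")
        for i in np.where(net.stoichiometry[:, l] != 0)[0]:
            if np.isfinite(par.K_M[i, l]) and not par.km_default_mask[i, l]:
                prow(_QT_KM, r, net.metabolite_ids[i], par.K_M[i, l], "mM")
    for (l, i, ki, _mech) in par.modifiers:
        prow(_QT_KI, net.reaction_ids[l], net.metabolite_ids[i], ki, "mM")
    blocks.append(_tab("Parameter", "Quantity",
                       ["QuantityType", "Reaction:SBML:reaction:id",
                        "Compound:SBML:species:id", "Value", "Unit"], prows))
    blocks.append(_tab("Flux", "Quantity", ["Reaction", "Value", "Unit"],
                       [[r, _g(flux.v[l]), "mM/s"] for l, r in enumerate(net.reaction_ids)]))
    if measurements is not None:
        crows = [[m, _g(measurements.metabolite_conc[i]), "mM"]
                 for i, m in enumerate(net.metabolite_ids)
                 if np.isfinite(measurements.metabolite_conc[i])]
        if crows:
            blocks.append(_tab("ConcentrationData", "Quantity",
                               ["Compound", "Value", "Unit"], crows))
        erows = [[r, _g(measurements.enzyme_conc[l]), "mM"]
                 for l, r in enumerate(net.reaction_ids)
                 if np.isfinite(measurements.enzyme_conc[l])]
        if erows:
            blocks.append(_tab("EnzymeData", "Quantity",
                               ["Reaction", "Value", "Unit"], erows))
    Path(path).write_text("\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------


def orient_reactions(net, par, flux):
    """Flip reactions so every active flux is positive.

    For each flipped reaction the stoichiometry column is negated, the
    catalytic constants are swapped, K_eq is inverted and the Gibbs energy
    negated; K_M values keep their metabolite assignment (substrate/product
    roles swap with the stoichiometry sign). Zero-flux reactions are marked
    inactive. Returns a new ``(net, par, flux)`` triple.
    """
    flip = flux.v < 0
    N = net.stoichiometry.copy()
    N[:, flip] *= -1
    net2 = NetworkModel(list(net.metabolite_ids), list(net.reaction_ids), N,
                        net.fixed_mask.copy(), net.fixed_values.copy())
    kf = np.where(flip, par.kcat_rev, par.kcat_fwd)
    kr = np.where(flip, par.kcat_fwd, par.kcat_rev)
    keq = np.where(flip, 1.0 / par.K_eq, par.K_eq)
    g = None if par.formation_energies is None else par.formation_energies.copy()
    par2 = KineticParameters(kf, kr, par.K_M.copy(), keq, -np.log(keq),
                             par.burden.copy(), par.protein_mass.copy(),
                             modifiers=list(par.modifiers),
                             km_default_mask=par.km_default_mask.copy(),
                             formation_energies=g, kcat_inf=par.kcat_inf)
    flux2 = FluxProfile(np.abs(flux.v), flux.v != 0)
    return net2, par2, flux2


# ---------------------------------------------------------------------------
# Haldane balancing (log-space constrained least squares)
# ---------------------------------------------------------------------------


def haldane_residuals(net, par):
    """Per-reaction residual ln K_eq - ln(kcat+/kcat-) - sum_i n_i ln K_M_i."""
    res = np.zeros(net.n_reactions)
    for l in range(net.n_reactions):
        n = net.stoichiometry[:, l]
        idx = np.where(n != 0)[0]
        res[l] = (np.log(par.K_eq[l]) - np.log(par.kcat_fwd[l]) + np.log(par.kcat_rev[l])
                  - np.dot(n[idx], np.log(par.K_M[idx, l])))
    return res


_DEFAULT_WEIGHTS = {"kcat_fwd": 1.0, "kcat_rev": 1.0, "K_M": 1.0, "K_eq": 1.0,
                    "K_M_default": 0.01}


def balance_haldane(net, par, weights=None, prior_weight=0.0):
    """Project log-parameters onto the Haldane-consistent manifold.

    Solves a precision-weighted least squares fit in log-parameter space over
    the free basis (per-metabolite formation energies, ln K_M, ln kcat+);
    equilibrium constants and reverse catalytic constants are derived from the
    basis, so the output satisfies the Haldane relationship (and Wegscheider
    cycle conditions) exactly. Deterministic and idempotent.

    ``weights`` maps quantity names (``kcat_fwd``, ``kcat_rev``, ``K_M``,
    ``K_eq``, ``K_M_default``) to precision weights. With ``prior_weight > 0``
    weak prior rows tie every free variable to its input (or default) value,
    regularizing under-determined systems.
    """
    w = dict(_DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    n_met, n_rxn = net.n_metabolites, net.n_reactions
    km_entries = [(i, l) for l in range(n_rxn)
                  for i in np.where(net.stoichiometry[:, l] != 0)[0]]
    km_pos = {e: k for k, e in enumerate(km_entries)}
    n_var = n_met + len(km_entries) + n_rxn  # g, lnKM, lnk+
    off_km = n_met
    off_kf = n_met + len(km_entries)

    rows, targets, row_w = [], [], []

    def obs(row, y, weight):
        rows.append(row)
        targets.append(y)
        row_w.append(weight)

    def var_row(j):
        r = np.zeros(n_var)
        r[j] = 1.0
        return r

    def lnkeq_row(l):
        r = np.zeros(n_var)
        r[:n_met] = -net.stoichiometry[:, l]
        return r

    def lnkrev_row(l):
        # ln k- = ln k+ - ln K_eq + sum_i n_i ln K_M_i
        r = np.zeros(n_var)
        r[off_kf + l] = 1.0
        r[:n_met] = net.stoichiometry[:, l]
        for i in np.where(net.stoichiometry[:, l] != 0)[0]:
            r[off_km + km_pos[(i, l)]] += net.stoichiometry[i, l]
        return r

    for l in range(n_rxn):
        if np.isfinite(par.kcat_fwd[l]):
            obs(var_row(off_kf + l), np.log(par.kcat_fwd[l]), w["kcat_fwd"])
        if np.isfinite(par.kcat_rev[l]):
            obs(lnkrev_row(l), np.log(par.kcat_rev[l]), w["kcat_rev"])
        if np.isfinite(par.K_eq[l]):
            obs(lnkeq_row(l), np.log(par.K_eq[l]), w["K_eq"])
    for (i, l) in km_entries:
        if np.isfinite(par.K_M[i, l]):
            wkey = "K_M_default" if par.km_default_mask[i, l] else "K_M"
            obs(var_row(off_km + km_pos[(i, l)]), np.log(par.K_M[i, l]), w[wkey])
    if prior_weight > 0:
        for j in range(n_var):
            if j < n_met:
                y0 = 0.0
            elif j < off_kf:
                i, l = km_entries[j - off_km]
                y0 = np.log(par.K_M[i, l]) if np.isfinite(par.K_M[i, l]) else np.log(DEFAULT_KM_MM)
            else:
                l = j - off_kf
                y0 = np.log(par.kcat_fwd[l]) if np.isfinite(par.kcat_fwd[l]) else 0.0
            obs(var_row(j), y0, prior_weight)

    if not rows:
        raise UnderdeterminedError("no kinetic observations to balance; supply priors")
    D = np.array(rows)
    y = np.array(targets)
    sw = np.sqrt(np.array(row_w))
    zeta, *_ = np.linalg.lstsq(D * sw[:, None], y * sw, rcond=None)

    # Determinedness: every derived output must lie in the row space of D.
    U, s, Vt = np.linalg.svd(D * sw[:, None], full_matrices=False)
    rank_mask = s > max(D.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    V = Vt[rank_mask]
    out_rows = ([var_row(off_kf + l) for l in range(n_rxn)]
                + [lnkrev_row(l) for l in range(n_rxn)]
                + [lnkeq_row(l) for l in range(n_rxn)]
                + [var_row(off_km + k) for k in range(len(km_entries))])
    for r in out_rows:
        proj = V.T @ (V @ r)
        if np.linalg.norm(r - proj) > 1e-8 * max(1.0, np.linalg.norm(r)):
            raise UnderdeterminedError(
                "balancing system is under-determined; supply priors "
                "(prior_weight > 0) or more measured parameters"
            )

    g = zeta[:n_met]
    lnkm = zeta[off_km:off_kf]
    lnkf = zeta[off_kf:]
    K_M = np.full((n_met, n_rxn), np.nan)
    for k, (i, l) in enumerate(km_entries):
        K_M[i, l] = np.exp(lnkm[k])
    ln_keq = np.array([lnkeq_row(l)[:n_met] @ g for l in range(n_rxn)])
    ln_krev = lnkf - ln_keq + np.array(
        [sum(net.stoichiometry[i, l] * lnkm[km_pos[(i, l)]]
             for i in np.where(net.stoichiometry[:, l] != 0)[0])
         for l in range(n_rxn)])
    return KineticParameters(
        np.exp(lnkf), np.exp(ln_krev), K_M, np.exp(ln_keq), -ln_keq,
        par.burden.copy(), par.protein_mass.copy(), modifiers=list(par.modifiers),
        km_default_mask=par.km_default_mask.copy(), formation_energies=g,
        kcat_inf=par.kcat_inf,
    )


def fitted_formation_energies(net, par):
    """Formation energies (RT units) reproducing ln K_eq in least squares."""
    if par.formation_energies is not None:
        return par.formation_energies
    g, *_ = np.linalg.lstsq(-net.stoichiometry.T, np.log(par.K_eq), rcond=None)
    return g
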