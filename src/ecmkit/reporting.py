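"""Validation metrics and the multiplicative cost-breakdown report.

Prediction quality is scored on log10 scale: the root mean squared error of
log10(predicted/measured) over overlapping pairs, its associated typical
fold error 10^RMSE, and the Pearson correlation of the log10 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EcmError


@dataclass
class PredictionMetrics:
    rmse_log10: float
    fold_error: float
    pearson_r: float  # NaN when undefined (constant vector)
    n_pairs: int
    excluded: list


def prediction_metrics(predicted, measured):
    """Compare predicted and measured concentrations (mM) on log10 scale.

    Inputs are pandas Series (or dicts) indexed by entity identifier;
    entries missing (NaN) on either side are excluded and listed, never
    imputed. Requires at least two overlapping pairs; nonpositive values
    among the overlap raise an error naming the entity. The Pearson
    correlation is reported as NaN when either vector is constant.
    """
    pred = pd.Series(predicted, dtype=float)
    meas = pd.Series(measured, dtype=float)
    idx = pred.index.union(meas.index)
    pred = pred.reindex(idx)
    meas = meas.reindex(idx)
    overlap = pred.notna() & meas.notna()
    excluded = list(idx[~overlap])
    pred = pred[overlap]
    meas = meas[overlap]
    for name, series in (("predicted", pred), ("measured", meas)):
        bad = series.index[series <= 0]
        if len(bad):
            raise EcmError(f"nonpositive {name} value for entity {bad[0]!r}")
    if len(pred) < 2:
        raise EcmError(f"need >= 2 overlapping positive pairs, got {len(pred)}")
    lp = np.log10(pred.to_numpy())
    lm = np.log10(meas.to_numpy())
    rmse = float(np.sqrt(np.mean((lp - lm) ** 2)))
    if np.ptp(lp) == 0 or np.ptp(lm) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(lp, lm).statistic)
    return PredictionMetrics(rmse, float(10.0 ** rmse), r, len(pred), excluded)


def cost_breakdown_report(breakdown, flux, par, spec=None):
    """Per-reaction multiplicative cost terms on natural-log scale.

    For each active reaction the capacity term ln(h_E v / kcat+) and the
    efficiency penalties -ln eta_rev, -ln eta_sat, -ln eta_reg sum to
    ln q_l; factors equal to 1 contribute exactly 0.
    """
    rev = -np.log(breakdown.eta_rev)
    sat = -np.log(breakdown.eta_sat)
    reg = -np.log(breakdown.eta_reg)
    # the capacity term ln(h_E v / kcat+) is the residual of ln q_l after the
    # efficiency penalties; computing it that way keeps the additivity exact
    capacity = np.log(breakdown.cost) - rev - sat - reg
    return pd.DataFrame({
        "reaction": breakdown.reaction_ids,
        "capacity_term": capacity,
        "reversibility_term": rev,
        "saturation_term": sat,
        "regulation_term": reg,
        "ln_cost": capacity + rev + sat + reg,
        "cost": breakdown.cost,
    })
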