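"""Species-level thermal physiology traits from raw experimental series.

Two traits are produced:

* ``T_pref`` — preferred body temperature: the mean of per-minute body
  temperatures selected on a photothermal gradient (20–55 °C), discarding an
  initial acclimation window (default 15 min) during which body temperature
  is still rising from room temperature.
* ``IWL`` — instantaneous evaporative water loss: mean hourly body-mass loss
  under dry constant conditions, size-corrected by regressing individual loss
  on an allometric estimate of body surface area,
  ``ln(SA) = 2.36 + 0.69 · ln(mass)``.

Species values are medians over individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SA_INTERCEPT",
    "SA_SLOPE",
    "estimate_surface_area",
    "iwl_from_weights",
    "size_correct_iwl",
    "tpref_from_series",
    "build_trait_table",
]

#: Intercept and slope of the ln-ln surface-area allometry.
SA_INTERCEPT = 2.36
SA_SLOPE = 0.69


def estimate_surface_area(mass: float) -> float:
    """Allometric body surface area: ``exp(2.36 + 0.69 * ln(mass))``.

    Mass in grams; surface area in the allometry's own units (only relative
    comparisons are used downstream).
    """
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    out = np.exp(SA_INTERCEPT + SA_SLOPE * np.log(mass))
    return float(out) if out.ndim == 0 else out


def iwl_from_weights(series: list[tuple[float, float]]) -> float:
    """Mean hourly weight loss from an (hour, grams) series.

    Each interval contributes its loss rate (Δweight/Δtime); the rates are
    averaged.  Intervals showing weight gain are kept but logged.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 weight measurements")
    t = np.asarray([p[0] for p in series], dtype=float)
    w = np.asarray([p[1] for p in series], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    rates = -np.diff(w) / np.diff(t)
    if np.any(rates < 0):
        logger.warning("%d interval(s) show weight gain; kept in the average", int(np.sum(rates < 0)))
    return float(np.mean(rates))


def size_correct_iwl(
    losses: dict[str, float],
    masses: dict[str, float],
    species: dict[str, str] | None = None,
    method: str = "residual",
) -> tuple[dict[str, float], dict[str, float] | None]:
    """Size-correct hourly water loss against estimated body surface area.

    ``method='residual'`` (default): OLS of loss on surface area across all
    individuals; the corrected value is the residual plus the grand-mean loss
    (a size-independent scale).  ``method='ratio'``: loss per unit surface
    area.  With fewer than 3 individuals the regression is infeasible and the
    ratio is used with a warning.

    Returns ``(per-individual corrected values, per-species medians or None)``.
    """
    ids = sorted(losses)
    if set(ids) != set(masses):
        raise ValueError("losses and masses must cover the same individuals")
    y = np.array([losses[i] for i in ids], dtype=float)
    sa = np.array([estimate_surface_area(masses[i]) for i in ids], dtype=float)

    if method == "ratio" or len(ids) < 3:
        if method != "ratio":
            logger.warning("fewer than 3 individuals: falling back to loss/surface-area ratio")
        corrected = y / sa
    elif method == "residual":
        X = np.column_stack([np.ones_like(sa), sa])
        if np.ptp(sa) == 0:
            # zero leverage: regression is just the mean; residual + mean = raw value
            corrected = y.copy()
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            corrected = y - X @ beta + np.mean(y)
    else:
        raise ValueError(f"unknown method {method!r}")

    per_ind = dict(zip(ids, corrected.tolist()))
    per_species = None
    if species is not None:
        df = pd.DataFrame({"iwl": [per_ind[i] for i in ids], "species": [species[i] for i in ids]})
        per_species = df.groupby("species")["iwl"].median().to_dict()
    return per_ind, per_species


def tpref_from_series(series: list[tuple[float, float]], acclimation: float = 15.0) -> float:
    """Preferred temperature: mean of measurements taken after the acclimation
    window (minutes strictly greater than ``acclimation``)."""
    t = np.asarray([p[0] for p in series], dtype=float)
    v = np.asarray([p[1] for p in series], dtype=float)
    keep = t > acclimation
    if not np.any(keep):
        raise ValueError(f"series does not extend beyond the {acclimation}-min acclimation window")
    return float(np.mean(v[keep]))


def build_trait_table(raw: pd.DataFrame, acclimation: float = 15.0, iwl_method: str = "residual") -> pd.DataFrame:
    """Species trait table from long-format raw records.

    ``raw`` columns: individual, species, mass, stream ('weight'|'temp'), t, value.
    Returns one row per species: tpref, iwl, n_tpref, n_iwl, body_mass (medians).
    """
    required = {"individual", "species", "mass", "stream", "t", "value"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw table must have columns {sorted(required)}")

    ind_species = raw.groupby("individual")["species"].first().to_dict()
    ind_mass = raw.groupby("individual")["mass"].first().to_dict()

    tpref_ind: dict[str, float] = {}
    loss_ind: dict[str, float] = {}
    for ind, grp in raw.groupby("individual"):
        temps = grp[grp["stream"] == "temp"].sort_values("t")
        if len(temps):
            tpref_ind[ind] = tpref_from_series(list(zip(temps["t"], temps["value"])), acclimation)
        weights = grp[grp["stream"] == "weight"].sort_values("t")
        if len(weights) >= 2:
            loss_ind[ind] = iwl_from_weights(list(zip(weights["t"], weights["value"])))

    iwl_species: dict[str, float] = {}
    if loss_ind:
        _, iwl_species = size_correct_iwl(
            loss_ind,
            {i: ind_mass[i] for i in loss_ind},
            species={i: ind_species[i] for i in loss_ind},
            method=iwl_method,
        )

    rows = []
    for sp in sorted(set(ind_species.values())):
        sp_inds = [i for i, s in ind_species.items() if s == sp]
        tvals = [tpref_ind[i] for i in sp_inds if i in tpref_ind]
        nw = sum(i in loss_ind for i in sp_inds)
        rows.append(
            {
                "species": sp,
                "tpref": float(np.median(tvals)) if tvals else np.nan,
                "iwl": iwl_species.get(sp, np.nan),
                "n_tpref": len(tvals),
                "n_iwl": nw,
                "body_mass": float(np.median([ind_mass[i] for i in sp_inds])),
            }
        )
    return pd.DataFrame(rows).set_index("species")
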