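"""Bundled literature DRH measurements and regression-table builders.

The measurement columns (gravimetric vapor-sorption DRH and equilibrium
water activity of saturated solutions, both in % RH at 298.15 K) are
shipped so that predicted values can be scored against experiment with
the average relative deviation (ARD) without any external data.

``reproduce_single_component_table`` and ``reproduce_mixture_table``
recompute the Raoult and PC-SAFT prediction columns from the parameter
database and attach the measured columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .components import ComponentSet, builtin_components
from .equilibria import (SolidFormChoice, ard, parse_solid, predict_drh,
                         predict_drh_mixture)

log = logging.getLogger(__name__)

T_TABLE = 298.15

#: Single crystals: label -> (solid spec, measured gravimetric DRH %,
#: measured saturated-solution water activity %).  None = not reported.
SINGLE_MEASUREMENTS: dict[str, tuple[str, float | None, float | None]] = {
    "ascorbic acid": ("ascorbic acid", 97.5, 97.0),
    "citric acid": ("citric acid", 75.0, 78.0),
    "citric acid hydrate": ("citric acid:hydrate", 78.0, 78.0),
    "fructose": ("fructose", 62.0, 61.0),
    "glucose": ("glucose", 91.0, 90.0),
    "nicotinamide": ("nicotinamide", 94.5, None),
    "lactose": ("lactose", 95.0, 97.0),
    "saccharin": ("saccharin", None, None),
    "sucrose": ("sucrose", 85.0, 85.0),
}

#: Crystal mixtures: label -> (comma-separated solid specs, DRH %, a_w %).
MIXTURE_MEASUREMENTS: dict[str, tuple[str, float | None, float | None]] = {
    "AA-CA": ("ascorbic acid,citric acid", 74.4, 73.5),
    "AA-CA hydrate": ("ascorbic acid,citric acid:hydrate", 74.0, 75.0),
    "AA-fructose": ("ascorbic acid,fructose", 58.9, 58.9),
    "AA-sucrose": ("ascorbic acid,sucrose", 85.0, 83.0),
    "CA-fructose": ("citric acid,fructose", 48.0, 47.0),
    "CA hydrate-fructose": ("citric acid:hydrate,fructose", 52.0, 48.0),
    "CA-glucose": ("citric acid,glucose", 68.0, 67.0),
    "CA hydrate-glucose": ("citric acid:hydrate,glucose", None, 68.0),
    "CA-sucrose": ("citric acid,sucrose", 64.0, 60.0),
    "CA hydrate-sucrose": ("citric acid:hydrate,sucrose", 65.0, 56.0),
    "fructose-glucose": ("fructose,glucose", 60.0, 54.0),
    "fructose-NA": ("fructose,nicotinamide", 55.3, None),
    "fructose-saccharin": ("fructose,saccharin", 61.5, None),
    "fructose-sucrose": ("fructose,sucrose", 58.0, 56.0),
    "glucose-sucrose": ("glucose,sucrose", 79.0, 78.0),
    "sucrose-NA": ("sucrose,nicotinamide", 80.0, None),
    "AA-CA-fructose": ("ascorbic acid,citric acid,fructose", 47.9, 47.9),
    "AA-CA hydrate-sucrose":
        ("ascorbic acid,citric acid:hydrate,sucrose", 56.0, 56.0),
    "CA-fructose-glucose": ("citric acid,fructose,glucose", 50.0, 43.0),
    "CA hydrate-fructose-glucose":
        ("citric acid:hydrate,fructose,glucose", None, 47.0),
    "CA-fructose-sucrose": ("citric acid,fructose,sucrose", 55.0, 44.0),
    "CA-glucose-sucrose": ("citric acid,glucose,sucrose", 64.0, 59.0),
    "fructose-glucose-sucrose": ("fructose,glucose,sucrose", 58.0, 53.0),
    "CA-fructose-glucose-sucrose":
        ("citric acid,fructose,glucose,sucrose", 54.0, 48.0),
    "CA hydrate-fructose-glucose-sucrose":
        ("citric acid:hydrate,fructose,glucose,sucrose", None, 44.0),
}


def _solids(spec: str) -> list[SolidFormChoice]:
    return [parse_solid(s) for s in spec.split(",")]


def reproduce_single_component_table(cs: ComponentSet | None = None,
                                     T: float = T_TABLE) -> pd.DataFrame:
    """Recompute the single-component DRH comparison table at T."""
    cs = cs or builtin_components()
    rows = []
    for label, (spec, drh_meas, aw_meas) in SINGLE_MEASUREMENTS.items():
        solids = _solids(spec)
        row = {"system": label, "T_K": T}
        for method in ("raoult", "pcsaft"):
            try:
                row[method] = round(predict_drh(solids, T, cs, method).drh, 1)
            except Exception as exc:      # recorded per row, not fatal
                log.warning("prediction failed for %s (%s): %s",
                            label, method, exc)
                row[method] = np.nan
        row["measured_drh"] = drh_meas
        row["measured_aw"] = aw_meas
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_mixture_table(cs: ComponentSet | None = None,
                            T: float = T_TABLE) -> pd.DataFrame:
    """Recompute the crystal-mixture DRH comparison table at T."""
    cs = cs or builtin_components()
    rows = []
    for label, (spec, drh_meas, aw_meas) in MIXTURE_MEASUREMENTS.items():
        solids = _solids(spec)
        row = {"system": label, "T_K": T,
               "n_crystals": len(solids)}
        for method in ("raoult", "pcsaft"):
            try:
                row[method] = round(
                    predict_drh_mixture(solids, T, cs, method).drh, 1)
            except Exception as exc:
                log.warning("prediction failed for %s (%s): %s",
                            label, method, exc)
                row[method] = np.nan
        row["measured_drh"] = drh_meas
        row["measured_aw"] = aw_meas
        rows.append(row)
    return pd.DataFrame(rows)


def table_ards(table: pd.DataFrame) -> dict[str, float]:
    """ARD of each prediction column against the gravimetric DRH rows."""
    sub = table.dropna(subset=["measured_drh"])
    out = {}
    for method in ("raoult", "pcsaft"):
        ok = sub.dropna(subset=[method])
        out[method] = ard(ok[method].to_numpy(),
                          ok["measured_drh"].to_numpy())
        out[f"n_{method}"] = len(ok)
    return out
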