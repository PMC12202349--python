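"""Field-measurement transforms for cassava trials.

Leaf-area allometry from central-lobe dimensions and lobe count, leaf area
index from leaf counts and plant spacing, storage-root dry weight from fresh
weight and dry-matter content, the one-third dry-aboveground rule, and
phyllochron estimation from repeated node counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .growth_model import DEFAULT_SPECIES, SpeciesConfig, WeatherSeries

__all__ = [
    "LeafScan",
    "AllometryFit",
    "fit_leaf_allometry",
    "predict_leaf_area",
    "compute_lai",
    "storage_root_dry_weight",
    "dry_aboveground",
    "estimate_phyllochron",
    "estimate_forking_thermal_time",
    "thermal_time_to_date",
    "leaf_scans_from_csv",
    "leaf_scans_to_csv",
]


@dataclass(frozen=True)
class LeafScan:
    """One scanned leaf: central-lobe length/width (cm), lobe count, and the
    reference area measured from the scan (cm2), when available."""

    lobe_length: float
    lobe_width: float
    n_lobes: int
    measured_area: float | None = None

    def __post_init__(self) -> None:
        if self.lobe_length <= 0 or self.lobe_width <= 0:
            raise ValueError("lobe dimensions must be positive")
        if int(self.n_lobes) != self.n_lobes or self.n_lobes < 1:
            raise ValueError("n_lobes must be a positive integer")

    @property
    def predictor(self) -> float:
        """The allometric predictor: lobe length x lobe width x lobe count."""
        return self.lobe_length * self.lobe_width * self.n_lobes


@dataclass(frozen=True)
class AllometryFit:
    """OLS fit of leaf area on the lobe product predictor."""

    intercept: float
    slope: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("allometry fit needs at least two leaves")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError("r2 must lie in [0, 1]")


def fit_leaf_allometry(scans: list[LeafScan]) -> AllometryFit:
    """Ordinary least squares of measured leaf area on the lobe product.

    Pools all leaves and fits both intercept and slope.  Raises on a
    degenerate design (constant predictor) or fewer than three measured
    leaves.
    """
    usable = [s for s in scans if s.measured_area is not None]
    if len(usable) < 3:
        raise ValueError("need at least three scans with a measured area")
    x = np.array([s.predictor for s in usable], dtype=float)
    y = np.array([s.measured_area for s in usable], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant across scans; cannot fit allometry")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return AllometryFit(intercept=float(res.intercept), slope=float(res.slope),
                        r2=min(max(r2, 0.0), 1.0), n=len(usable))


def predict_leaf_area(lobe_length: float, lobe_width: float, n_lobes: int,
                      fit: AllometryFit) -> float:
    """Predicted single-leaf area (cm2), floored at zero."""
    x = lobe_length * lobe_width * n_lobes
    return max(0.0, fit.intercept + fit.slope * x)


def compute_lai(n_leaves: float, mean_leaf_area_cm2: float, occupied_area_m2: float) -> float:
    """Leaf area index: leaves per plant x mean leaf area / ground area per plant."""
    if occupied_area_m2 <= 0:
        raise ValueError("occupied area must be positive")
    return n_leaves * (mean_leaf_area_cm2 * 1e-4) / occupied_area_m2


def storage_root_dry_weight(fresh_t_ha: float, dmc: float) -> float:
    """Storage-root dry weight (t ha-1) = fresh weight x dry-matter content."""
    if not 0 < dmc <= 1:
        raise ValueError("dry-matter content must be in (0, 1]")
    return fresh_t_ha * dmc


def dry_aboveground(fresh_t_ha: float) -> float:
    """Dry aboveground biomass taken as one third of the fresh biomass."""
    if fresh_t_ha < 0:
        raise ValueError("fresh biomass must be non-negative")
    return fresh_t_ha / 3.0


def estimate_phyllochron(nodes_t1: float, nodes_t2: float, tt_between: float) -> float:
    """Thermal time per node (degCd/node) from node counts at two timepoints."""
    if tt_between <= 0:
        raise ValueError("thermal time between counts must be positive")
    if nodes_t2 <= nodes_t1:
        raise ValueError("node count must increase between timepoints")
    return tt_between / (nodes_t2 - nodes_t1)


def estimate_forking_thermal_time(
    section_height_cm: float,
    nodlt_cm: float,
    phyllochron: float,
    internode_count: float | None = None,
) -> float:
    """Heuristic back-estimate of the thermal time of a forking event.

    The number of nodes in the stem section below the fork is taken as
    section height divided by the mean internode length (or the counted
    internodes, when available), and multiplied by the phyllochron.  This is
    a clearly approximate reconstruction used only when fork dates were not
    observed directly.
    """
    if phyllochron <= 0:
        raise ValueError("phyllochron must be positive")
    if internode_count is not None:
        nodes = float(internode_count)
    else:
        if nodlt_cm <= 0 or section_height_cm < 0:
            raise ValueError("need positive internode length and non-negative height")
        nodes = section_height_cm / nodlt_cm
    return nodes * phyllochron


def thermal_time_to_date(
    target_tt: float,
    weather: WeatherSeries,
    planting_date: _date,
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> _date:
    """First calendar date on which cumulative thermal time from planting
    reaches ``target_tt``; raises if the series ends before that."""
    w = weather.slice(planting_date, weather.end)
    cum = w.cumulative_thermal_time(species)
    idx = int(np.searchsorted(cum, target_tt))
    if idx >= len(cum):
        raise ValueError("weather series ends before the target thermal time is reached")
    return planting_date + timedelta(days=idx)


_SCAN_COLUMNS = ["cultivar", "plant", "position", "lobe_length", "lobe_width", "n_lobes", "area_cm2"]


def leaf_scans_to_csv(table: pd.DataFrame, path) -> None:
    table.loc[:, _SCAN_COLUMNS].to_csv(path, index=False)


def leaf_scans_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"leaf-scan table missing columns: {missing}")
    return df


def scans_from_table(table: pd.DataFrame) -> list[LeafScan]:
    """Convert a leaf-scan table (``lobe_length``, ``lobe_width``,
    ``n_lobes``, optional ``area_cm2``) to :class:`LeafScan` records."""
    has_area = "area_cm2" in table.columns
    out = []
    for row in table.itertuples(index=False):
        area = getattr(row, "area_cm2", None) if has_area else None
        if area is not None and (isinstance(area, float) and math.isnan(area)):
            area = None
        out.append(
            LeafScan(
                lobe_length=float(row.lobe_length),
                lobe_width=float(row.lobe_width),
                n_lobes=int(row.n_lobes),
                measured_area=None if area is None else float(area),
            )
        )
    return out
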