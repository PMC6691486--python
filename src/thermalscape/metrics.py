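"""Landscape-level summaries of thermal and physiological heterogeneity.

The central statistic is the roughness family: Rq (metrology-style RMS
deviation of elevation from the mean plane, in metres), its thermal
analogue RqT (RMS spatial deviation of surface temperature from the
site mean at one timestamp, degC) and the performance analogue RqP
(dimensionless). On top of these sit derived maps: micro-refugia
(exposed cells below a temperature threshold), thermal corridors
(persistence/loss/gain of a stress category between two hours),
two-species favourability partitions, and frequency distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .microclimate import TemperatureField
from .physiology import (
    LETHAL,
    OPTIMAL,
    SUBOPTIMAL,
    PerformanceField,
    ThermalPerformanceCurve,
    classify_performance,
)

__all__ = [
    "RefugiaResult",
    "CorridorResult",
    "InteractionMap",
    "thermal_roughness",
    "performance_roughness",
    "refugia_area",
    "corridor_map",
    "species_interaction_map",
    "frequency_distribution",
]

INTERACTION_CLASSES = ("both_favourable", "prey_only_refugium", "predator_only", "neither")
BOTH, PREY_ONLY, PREDATOR_ONLY, NEITHER = range(4)


@dataclass
class RefugiaResult:
    threshold: float
    refugium_mask: np.ndarray
    refugia_area: float  # m^2
    exposed_area: float  # m^2

    @property
    def fraction(self) -> float:
        return self.refugia_area / self.exposed_area


@dataclass
class CorridorResult:
    persistent: np.ndarray
    lost: np.ndarray
    gained: np.ndarray
    persistent_area: float
    lost_area: float
    gained_area: float


@dataclass
class InteractionMap:
    classes: np.ndarray  # codes per INTERACTION_CLASSES, -1 invalid/submerged
    areas: dict[str, float]


def _rms_deviation(values: np.ndarray, mask: np.ndarray) -> float:
    v = values[mask & np.isfinite(values)]
    if v.size < 2:
        raise ValueError("roughness needs at least 2 valid exposed cells")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def thermal_roughness(temps: TemperatureField, include_submerged: bool = False) -> float:
    """RqT (degC): RMS of spatial temperature deviations from the site mean.

    Computed over aerially exposed cells by default, matching maps that
    blank submerged cells; ``include_submerged`` adds submerged cells at
    water temperature for sensitivity analyses.
    """
    mask = np.ones_like(temps.exposure) if include_submerged else temps.exposure
    return _rms_deviation(temps.temperature, mask)


def performance_roughness(perf: PerformanceField, include_submerged: bool = False) -> float:
    """RqP (dimensionless): RMS of spatial performance deviations."""
    mask = np.ones_like(perf.exposure) if include_submerged else perf.exposure
    return _rms_deviation(perf.performance, mask)


def refugia_area(
    temps: TemperatureField,
    threshold: float,
    min_patch_cells: int = 0,
) -> RefugiaResult:
    """Micro-refugia: exposed cells strictly cooler than ``threshold``.

    Areas are cell counts times the cell area. ``min_patch_cells`` drops
    4-connected refugium patches smaller than the given size (a body-size
    proxy); default keeps every cell.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    valid = temps.exposure & np.isfinite(temps.temperature)
    if not valid.any():
        raise ValueError("no exposed cells")
    refugium = valid & (temps.temperature < threshold)
    if min_patch_cells > 1:
        labels, n = ndimage.label(refugium)
        sizes = ndimage.sum_labels(refugium, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_patch_cells) + 1
        refugium &= ~np.isin(labels, small)
    cell_area = temps.cell_size**2
    return RefugiaResult(
        threshold=threshold,
        refugium_mask=refugium,
        refugia_area=float(refugium.sum() * cell_area),
        exposed_area=float(valid.sum() * cell_area),
    )


def corridor_map(
    perf_t1: PerformanceField,
    perf_t2: PerformanceField,
    category: int = OPTIMAL,
) -> CorridorResult:
    """Persistence, loss and gain of a stress category between two hours.

    The persistent/lost/gained masks partition the union of the two
    category masks; their areas are in m^2.
    """
    if perf_t1.category.shape != perf_t2.category.shape:
        raise ValueError("performance fields must share a grid")
    m1 = (perf_t1.category == category) & perf_t1.exposure
    m2 = (perf_t2.category == category) & perf_t2.exposure
    cell_area = perf_t1.cell_size**2
    persistent = m1 & m2
    lost = m1 & ~m2
    gained = ~m1 & m2
    return CorridorResult(
        persistent=persistent,
        lost=lost,
        gained=gained,
        persistent_area=float(persistent.sum() * cell_area),
        lost_area=float(lost.sum() * cell_area),
        gained_area=float(gained.sum() * cell_area),
    )


def _favourable(
    temperature: np.ndarray, tpc: ThermalPerformanceCurve, mode: str
) -> np.ndarray:
    cat = classify_performance(temperature, tpc)
    if mode == "persistence":
        return (cat >= SUBOPTIMAL) & (cat != LETHAL)
    if mode == "performance":
        return (cat == SUBOPTIMAL) | (cat == OPTIMAL)
    raise ValueError(f"unknown favourability mode {mode!r}")


def species_interaction_map(
    temps: TemperatureField,
    tpc_dominant: ThermalPerformanceCurve,
    tpc_subordinate: ThermalPerformanceCurve,
    favourability: str = "persistence",
) -> InteractionMap:
    """Four-way partition of exposed cells by two species' favourability.

    With the default ``favourability='persistence'`` a cell counts as
    favourable to a species when it can survive there (temperature at or
    below its lethal limit); ``'performance'`` restricts favourability to
    the suboptimal/optimal bands. The ecologically loaded class is the
    prey-only refugium: survivable for the subordinate (prey) species but
    lethal for the dominant predator or competitor, so the prey persists
    free of the dominant — e.g. a 33 degC cell with predator lethal limit
    32 degC and prey limit 35 degC.
    """
    valid = temps.exposure & np.isfinite(temps.temperature)
    fav_dom = _favourable(temps.temperature, tpc_dominant, favourability)
    fav_sub = _favourable(temps.temperature, tpc_subordinate, favourability)
    classes = np.full(temps.temperature.shape, -1, dtype=np.int8)
    classes[valid & fav_dom & fav_sub] = BOTH
    classes[valid & ~fav_dom & fav_sub] = PREY_ONLY
    classes[valid & fav_dom & ~fav_sub] = PREDATOR_ONLY
    classes[valid & ~fav_dom & ~fav_sub] = NEITHER
    cell_area = temps.cell_size**2
    areas = {
        name: float((classes == code).sum() * cell_area)
        for code, name in enumerate(INTERACTION_CLASSES)
    }
    return InteractionMap(classes=classes, areas=areas)


def frequency_distribution(field, bin_edges) -> np.ndarray:
    """Counts of exposed valid cells per half-open bin [e_i, e_{i+1}).

    ``field`` is a TemperatureField or PerformanceField. Values outside
    [first_edge, last_edge) are not counted; with edges covering the data
    range the counts sum to the number of exposed cells.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    values = field.temperature if isinstance(field, TemperatureField) else field.performance
    v = values[field.exposure & np.isfinite(values)]
    idx = np.digitize(v, edges, right=False) - 1  # half-open everywhere
    counts = np.zeros(edges.size - 1, dtype=int)
    in_range = (idx >= 0) & (idx < counts.size) & (v < edges[-1])
    np.add.at(counts, idx[in_range], 1)
    return counts
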