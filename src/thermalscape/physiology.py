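"""Thermal performance curves (TPCs) and performance fields.

A TPC maps body temperature to relative physiological performance in
[0, 1]. The shape used here is the classic asymmetric curve of thermal
ecology: a slow Gaussian rise below the optimum T_opt and a fast
quadratic collapse between T_opt and the lethal limit,

    P(T) = exp(-((T - T_opt) / (2 sigma))^2)            T <= T_opt
    P(T) = 1 - ((T - T_opt) / (T_opt - T_lethal))^2     T_opt < T < T_lethal
    P(T) = 0                                            T >= T_lethal

Stress categories (suboptimal / optimal / sublethal / lethal) are assigned
by temperature interval, not by performance value, so category maps are
robust to the exact curve shape. Because P is non-linear, the spatial mean
of performance differs from performance at the mean temperature (Jensen's
inequality) — the central reason for mapping performance per cell rather
than averaging temperature first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .microclimate import TemperatureField

__all__ = [
    "ThermalPerformanceCurve",
    "PerformanceField",
    "CATEGORIES",
    "relative_performance",
    "classify_performance",
    "performance_field",
    "load_tpc",
    "save_tpc",
    "PRESETS",
]

# integer codes for category rasters
CATEGORIES = ("suboptimal", "optimal", "sublethal", "lethal")
SUBOPTIMAL, OPTIMAL, SUBLETHAL, LETHAL = range(4)


@dataclass(frozen=True)
class ThermalPerformanceCurve:
    """Parameters of one species' thermal performance curve (degC).

    ``lower`` / ``upper`` are the suboptimal/optimal and optimal/sublethal
    breakpoints; ``sigma`` controls the width of the sub-optimal ascent.
    """

    t_opt: float
    t_lethal: float
    lower: float
    upper: float
    sigma: float = 7.0
    label: str = "tpc"

    def __post_init__(self) -> None:
        if not self.lower < self.t_opt < self.upper:
            raise ValueError("breakpoints must straddle t_opt (lower < t_opt < upper)")
        if self.t_lethal < self.upper:
            raise ValueError("t_lethal must be at or above the optimal/sublethal boundary")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


# the paper-style generic intertidal curve: optimal band 21.2-30.1 degC,
# optimum 28 degC, lethal above 35 degC; "predator" is the same curve
# shifted 3 degC cooler for a dominant species with T_opt 25 degC.
PRESETS: dict[str, ThermalPerformanceCurve] = {
    "generic_intertidal": ThermalPerformanceCurve(
        t_opt=28.0, t_lethal=35.0, lower=21.2, upper=30.1, sigma=7.0,
        label="generic_intertidal",
    ),
    "predator": ThermalPerformanceCurve(
        t_opt=25.0, t_lethal=32.0, lower=18.2, upper=27.1, sigma=7.0,
        label="predator",
    ),
}


@dataclass
class PerformanceField:
    """Per-cell relative performance and stress category for one hour."""

    timestamp: object
    performance: np.ndarray
    category: np.ndarray  # integer codes, -1 where invalid
    exposure: np.ndarray
    cell_size: float = 1.0
    tpc: ThermalPerformanceCurve | None = None


def relative_performance(temperature, tpc: ThermalPerformanceCurve):
    """Relative performance in [0, 1] at the given temperature(s)."""
    t = np.asarray(temperature, dtype=float)
    rise = np.exp(-(((t - tpc.t_opt) / (2 * tpc.sigma)) ** 2))
    fall = 1.0 - ((t - tpc.t_opt) / (tpc.t_opt - tpc.t_lethal)) ** 2
    p = np.where(t <= tpc.t_opt, rise, np.clip(fall, 0.0, None))
    p = np.where(t >= tpc.t_lethal, 0.0, p)
    p = np.where(np.isfinite(t), p, np.nan)
    return float(p) if np.isscalar(temperature) else p


def classify_performance(temperature, tpc: ThermalPerformanceCurve):
    """Stress category code(s) by temperature interval.

    Intervals are left-closed/right-open except the lethal boundary, which
    is open from below: temperatures strictly above t_lethal are lethal.
    """
    t = np.asarray(temperature, dtype=float)
    cat = np.full(t.shape, SUBOPTIMAL, dtype=np.int8)
    cat[(t >= tpc.lower) & (t < tpc.upper)] = OPTIMAL
    cat[(t >= tpc.upper) & (t <= tpc.t_lethal)] = SUBLETHAL
    cat[t > tpc.t_lethal] = LETHAL
    cat = np.where(np.isfinite(t), cat, -1).astype(np.int8)
    return int(cat) if np.isscalar(temperature) else cat


def performance_field(temps: TemperatureField, tpc: ThermalPerformanceCurve) -> PerformanceField:
    """Element-wise TPC application to a temperature field.

    Submerged cells carry performance evaluated at water temperature (their
    temperature in the field) and remain flagged by the exposure mask.
    """
    return PerformanceField(
        timestamp=temps.timestamp,
        performance=relative_performance(temps.temperature, tpc),
        category=classify_performance(temps.temperature, tpc),
        exposure=temps.exposure,
        cell_size=temps.cell_size,
        tpc=tpc,
    )


def load_tpc(path: str | Path) -> ThermalPerformanceCurve:
    """Load a TPC preset from a flat key/value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ThermalPerformanceCurve(
        t_opt=float(raw["t_opt_C"]),
        t_lethal=float(raw["t_lethal_C"]),
        lower=float(raw["lower_C"]),
        upper=float(raw["upper_C"]),
        sigma=float(raw.get("sigma_C", 7.0)),
        label=str(raw.get("label", "tpc")),
    )


def save_tpc(tpc: ThermalPerformanceCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "label": tpc.label,
                "t_opt_C": tpc.t_opt,
                "t_lethal_C": tpc.t_lethal,
                "lower_C": tpc.lower,
                "upper_C": tpc.upper,
                "sigma_C": tpc.sigma,
            },
            fh,
        )
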