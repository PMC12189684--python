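"""Binary habitat maps and loss/gain/net range-change accounting.

Suitability maps are binarized at a threshold (by default the ensemble's
max-TSS threshold, applied identically to current and future maps). Range
change between two binary maps is reported relative to the *current*
suitable-cell count: loss% is signed negative, gain% is non-negative and
may exceed 100 when a range expands past its present size, and
net% = gain% + loss%. Habitat area uses exact spherical cell areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from loligosdm.grids import cell_areas_km2
from loligosdm.scenarios import SuitabilityMap


@dataclass
class BinaryMap:
    """0/1 habitat map with NaN over land; derived by thresholding."""

    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray  # float array: 0.0, 1.0 or NaN
    threshold: float | None = None
    scenario: str | None = None

    @property
    def sea_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def suitable_mask(self) -> np.ndarray:
        return np.nan_to_num(self.values, nan=0.0) >= 0.5

    @property
    def n_suitable(self) -> int:
        return int(self.suitable_mask.sum())

    def aligned_with(self, other: "BinaryMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Cell suitable iff suitability >= threshold; land stays missing."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = smap.values
    out = np.where(np.isfinite(vals), (vals >= threshold).astype(float), np.nan)
    return BinaryMap(
        lat=smap.lat.copy(),
        lon=smap.lon.copy(),
        values=out,
        threshold=threshold,
        scenario=smap.scenario,
    )


@dataclass
class RangeChangeReport:
    """Habitat change between a current and a future binary map.

    Percentages use the current suitable-cell count as denominator:
    loss_pct = -100 * lost / current_total (in [-100, 0]),
    gain_pct = 100 * gained / current_total (>= 0, can exceed 100),
    net_pct = gain_pct + loss_pct.
    """

    kept: int
    lost: int
    gained: int
    current_total: int
    loss_pct: float
    gain_pct: float
    net_pct: float
    current_area_km2: float
    future_area_km2: float
    scenario: str | None = None


def range_change(current: BinaryMap, future: BinaryMap, scenario: str | None = None) -> RangeChangeReport:
    """Count kept/lost/gained cells and derive the signed percentages."""
    if not current.aligned_with(future):
        raise ValueError("maps are not aligned")
    cur = current.suitable_mask
    fut = future.suitable_mask
    total = int(cur.sum())
    if total == 0:
        raise ValueError("current range is empty; percentages undefined")
    kept = int((cur & fut).sum())
    lost = int((cur & ~fut).sum())
    gained = int((~cur & fut).sum())
    loss_pct = -100.0 * lost / total
    gain_pct = 100.0 * gained / total
    return RangeChangeReport(
        kept=kept,
        lost=lost,
        gained=gained,
        current_total=total,
        loss_pct=loss_pct,
        gain_pct=gain_pct,
        net_pct=gain_pct + loss_pct,
        current_area_km2=habitat_area(current),
        future_area_km2=habitat_area(future),
        scenario=scenario or future.scenario,
    )


def habitat_area(bmap: BinaryMap) -> float:
    """Total suitable area in km^2 from spherical cell geometry.

    Each cell at centre latitude phi with angular size d contributes
    R^2 * d(radians) * (sin(phi + d/2) - sin(phi - d/2)), R = 6371 km.
    """
    lat = np.asarray(bmap.lat, dtype=float)
    if lat.size > 1:
        cell = float(np.median(np.diff(lat)))
    else:
        lon = np.asarray(bmap.lon, dtype=float)
        cell = float(np.median(np.diff(lon))) if lon.size > 1 else 0.5
    row_areas = cell_areas_km2(lat, cell)
    suitable = bmap.suitable_mask
    return float((suitable.sum(axis=1) * row_areas).sum())
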