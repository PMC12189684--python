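"""Climate-scenario registry, delta-method bias correction, and projection.

Climate-model output carries systematic bias relative to observations.
The delta method sidesteps it by transporting only the model's own
anomaly onto the observed baseline:

    corrected_future = observed_baseline + (gcm_future - gcm_baseline)

applied cellwise and additively to every covariate, so any bias common to
the two model epochs cancels exactly. The corrected stack is then pushed
through the fitted ensemble to yield a suitability map per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from loligosdm.grids import EnvStack

SSPS = ("SSP1-2.6", "SSP2-4.5", "SSP3-7.0", "SSP5-8.5")
HORIZONS = ("2050s", "2090s")


@dataclass(frozen=True)
class ScenarioSpec:
    """One shared-socioeconomic-pathway scenario at one horizon.

    Horizons follow the usual decade conventions: the 2050s cover
    2040-2050 and the 2090s cover 2090-2100.
    """

    ssp: str
    horizon: str

    def __post_init__(self) -> None:
        if self.ssp not in SSPS:
            raise ValueError(f"unknown SSP {self.ssp!r}; expected one of {SSPS}")
        if self.horizon not in HORIZONS:
            raise ValueError(f"unknown horizon {self.horizon!r}; expected one of {HORIZONS}")

    @property
    def label(self) -> str:
        year = "2050" if self.horizon == "2050s" else "2100"
        return f"{self.ssp.replace('-', '').replace('.', '')}-{year}"


#: the eight scenario combinations (4 SSPs x 2 horizons)
SCENARIOS: tuple[ScenarioSpec, ...] = tuple(
    ScenarioSpec(ssp, h) for ssp in SSPS for h in HORIZONS
)

#: default true warming (deg C, applied to SST/SBT) and freshening
#: (per-mille, applied to SSS/SBS) per scenario, in line with CMIP6-era
#: regional projections for the northwest Pacific shelf seas.
DEFAULT_SHIFTS: dict[tuple[str, str], dict[str, float]] = {
    ("SSP1-2.6", "2050s"): {"temp": 0.6, "sal": -0.05},
    ("SSP1-2.6", "2090s"): {"temp": 1.0, "sal": -0.10},
    ("SSP2-4.5", "2050s"): {"temp": 0.9, "sal": -0.10},
    ("SSP2-4.5", "2090s"): {"temp": 1.9, "sal": -0.20},
    ("SSP3-7.0", "2050s"): {"temp": 1.1, "sal": -0.15},
    ("SSP3-7.0", "2090s"): {"temp": 2.9, "sal": -0.35},
    ("SSP5-8.5", "2050s"): {"temp": 1.3, "sal": -0.20},
    ("SSP5-8.5", "2090s"): {"temp": 3.8, "sal": -0.45},
}

_TEMP_VARS = ("sst", "sbt")
_SAL_VARS = ("sss", "sbs")


def scenario_shift(spec: ScenarioSpec, covariates=None) -> dict[str, float]:
    """Per-covariate additive shift for one scenario's stated world."""
    s = DEFAULT_SHIFTS[(spec.ssp, spec.horizon)]
    covariates = covariates or (*_TEMP_VARS, *_SAL_VARS)
    out = {}
    for c in covariates:
        if c in _TEMP_VARS:
            out[c] = s["temp"]
        elif c in _SAL_VARS:
            out[c] = s["sal"]
        else:
            out[c] = 0.0
    return out


def delta_correct(
    obs_baseline: np.ndarray,
    gcm_baseline: np.ndarray,
    gcm_future: np.ndarray,
) -> np.ndarray:
    """Delta-corrected future grid for one covariate.

    Cellwise ``obs + (gcm_future - gcm_baseline)``; the output mask is the
    union of the inputs' NaN masks.
    """
    obs = np.asarray(obs_baseline, dtype=float)
    gb = np.asarray(gcm_baseline, dtype=float)
    gf = np.asarray(gcm_future, dtype=float)
    if not (obs.shape == gb.shape == gf.shape):
        raise ValueError("grids are not aligned")
    return obs + (gf - gb)


def delta_correct_stack(
    obs_baseline: EnvStack,
    gcm_baseline: EnvStack,
    gcm_future: EnvStack,
) -> EnvStack:
    """Apply the delta correction to every covariate layer of a stack."""
    obs_baseline.require_aligned(gcm_baseline)
    obs_baseline.require_aligned(gcm_future)
    for name in obs_baseline.layers:
        if name not in gcm_baseline.layers or name not in gcm_future.layers:
            raise ValueError(f"covariate {name!r} missing from a GCM stack")
    layers = {
        name: delta_correct(
            obs_baseline.layers[name],
            gcm_baseline.layers[name],
            gcm_future.layers[name],
        )
        for name in obs_baseline.layers
    }
    return EnvStack(
        lat=obs_baseline.lat.copy(),
        lon=obs_baseline.lon.copy(),
        layers=layers,
        season=obs_baseline.season,
    )


@dataclass
class SuitabilityMap:
    """Cellwise ensemble suitability on a stack's grid; NaN over land."""

    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray
    scenario: str | None = None
    novel_mask: np.ndarray | None = None

    @property
    def sea_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_sea(self) -> int:
        return int(self.sea_mask.sum())

    def to_dataset(self):
        import xarray as xr

        ds = xr.Dataset(
            {"suitability": (("lat", "lon"), self.values)},
            coords={"lat": self.lat, "lon": self.lon},
        )
        if self.novel_mask is not None:
            ds["novel"] = (("lat", "lon"), self.novel_mask.astype(np.int8))
        if self.scenario:
            ds.attrs["scenario"] = self.scenario
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def project(ensemble, stack: EnvStack, scenario: str | None = None) -> SuitabilityMap:
    """Project a fitted ensemble onto an environmental stack.

    Land cells stay missing; cells whose covariates fall outside the
    ensemble members' training ranges are flagged in ``novel_mask``
    (prediction still made — warming scenarios exceed baselines by
    design).
    """
    covs = ensemble.covariates
    for c in covs:
        if c not in stack.layers:
            raise ValueError(f"stack lacks covariate layer {c!r}")
    mask = stack.sea_mask
    ii, jj = np.nonzero(mask)
    rows = pd.DataFrame({c: stack.layers[c][ii, jj] for c in covs})
    preds = ensemble.predict(rows)

    values = np.full(stack.shape, np.nan)
    values[ii, jj] = preds

    lo = {c: min(m.training_range[c][0] for m in getattr(ensemble, "members", [ensemble])) for c in covs}
    hi = {c: max(m.training_range[c][1] for m in getattr(ensemble, "members", [ensemble])) for c in covs}
    novel = np.zeros(stack.shape, dtype=bool)
    for c in covs:
        layer = stack.layers[c]
        with np.errstate(invalid="ignore"):
            novel |= (layer < lo[c]) | (layer > hi[c])
    novel &= mask
    return SuitabilityMap(
        lat=stack.lat.copy(),
        lon=stack.lon.copy(),
        values=values,
        scenario=scenario,
        novel_mask=novel,
    )
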