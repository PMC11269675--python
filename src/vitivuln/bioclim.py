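"""Viticultural bioclimatic indices on monthly climatologies.

Three indices summarise the growing-season climate of a winegrowing
region:

* **Huglin heliothermal index (HI)**, °C·days — day-length-weighted sum of
  mean/maximum temperature excess above 10 °C over April–September.
* **Cool Night Index (CNI)**, °C — mean September minimum temperature, a
  proxy for night-time ripening conditions.
* **Dryness Index (DI)**, mm — the potential soil-water reserve left at the
  end of September by Riou's monthly water balance (initial reserve ``Wo``,
  vine transpiration, bare-soil evaporation).

All functions are vectorised: monthly variables carry the month on axis 0
(12 values, January..December) and broadcast over any trailing spatial
shape. Latitudes are Northern-Hemisphere degrees; the growing season is
fixed to April–September.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "DIParams",
    "huglin_index",
    "cool_night_index",
    "estimate_pet",
    "dryness_index",
    "bioclim_dataset",
    "regional_bioclim",
]

# April..September month indices (0-based) and lengths
_GS_MONTHS = np.arange(3, 9)
_GS_DAYS = np.array([30.0, 31.0, 30.0, 31.0, 31.0, 30.0])
_SEPTEMBER = 8

# mid-month day of year, used for extraterrestrial radiation
_MID_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_MONTH_DAYS = np.array([31.0, 28.0, 31.0, 30.0, 31.0, 30.0, 31.0, 31.0, 30.0, 31.0, 30.0, 31.0])


@dataclass(frozen=True)
class DIParams:
    """Parameters of the Riou potential soil-water balance.

    ``wo`` is the initial (and maximal) soil-water reserve in mm.
    ``k_by_month`` is the vegetation absorption coefficient for
    April..September; the published parameterisation ramps from 0.1 in
    April to 0.5 from June onwards. ``evap_days_divisor`` converts monthly
    precipitation into the number of effective bare-soil evaporation days
    (JPm = min(N, pr / divisor)).
    """

    wo: float = 200.0
    k_by_month: tuple[float, ...] = (0.1, 0.3, 0.5, 0.5, 0.5, 0.5)
    evap_days_divisor: float = 5.0

    def __post_init__(self) -> None:
        if self.wo <= 0:
            raise ValueError("initial soil-water reserve wo must be positive")
        if len(self.k_by_month) != 6:
            raise ValueError("k_by_month needs six values (April..September)")
        if any(not 0.0 <= k <= 1.0 for k in self.k_by_month):
            raise ValueError("absorption coefficients must lie in [0, 1]")


def _huglin_k(lat: np.ndarray, extend: bool = False) -> np.ndarray:
    """Huglin day-length coefficient K, stepwise in latitude.

    The published table stops at 50°N; between 50 and 60°N the last value
    (1.06) is carried forward. Beyond 60°N the coefficient is undefined and
    an error is raised unless ``extend`` is set.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(lat >= 60.0) and not extend:
        raise ValueError("Huglin K coefficient undefined at latitude >= 60N "
                         "(pass extend_k=True to carry the last value forward)")
    edges = np.array([40.0, 42.0, 44.0, 46.0, 48.0, 50.0])
    values = np.array([1.00, 1.02, 1.03, 1.04, 1.05, 1.06, 1.06])
    return values[np.searchsorted(edges, lat, side="left")]


def huglin_index(tas: np.ndarray, tasmax: np.ndarray, lat: np.ndarray,
                 *, clamp: bool = True, extend_k: bool = False) -> np.ndarray:
    """Huglin heliothermal index in °C·days.

    HI = sum over April–September of ((tas − 10) + (tasmax − 10)) / 2 · N · K(lat),
    with the monthly contribution floored at zero (``clamp``) so cold months
    do not offset warm ones. Daily sums are approximated by monthly means
    times month length, consistent with monthly climatology inputs.
    """
    tas = np.asarray(tas, dtype=float)
    tasmax = np.asarray(tasmax, dtype=float)
    if tas.shape[0] != 12 or tasmax.shape[0] != 12:
        raise ValueError("monthly variables must have 12 months on axis 0")
    k = _huglin_k(lat, extend=extend_k)
    contrib = ((tas[_GS_MONTHS] - 10.0) + (tasmax[_GS_MONTHS] - 10.0)) / 2.0
    if clamp:
        contrib = np.maximum(contrib, 0.0)
    days = _GS_DAYS.reshape((6,) + (1,) * (contrib.ndim - 1))
    hi = (contrib * days).sum(axis=0) * k
    return hi


def cool_night_index(tasmin: np.ndarray) -> np.ndarray:
    """Cool Night Index: the September monthly-mean minimum temperature, °C."""
    tasmin = np.asarray(tasmin, dtype=float)
    if tasmin.shape[0] != 12:
        raise ValueError("tasmin must have 12 months on axis 0")
    return tasmin[_SEPTEMBER]


def _extraterrestrial_radiation(lat: np.ndarray) -> np.ndarray:
    """Monthly-mean extraterrestrial radiation Ra, MJ m-2 day-1 (FAO-56).

    Evaluated at the mid-month day of year. Shape: (12,) + lat.shape.
    """
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    doy = _MID_DOY.reshape((12,) + (1,) * lat.ndim)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = -np.tan(lat) * np.tan(delta)
    ws = np.arccos(np.clip(x, -1.0, 1.0))  # clipped: polar day/night
    ra = (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        ws * np.sin(lat) * np.sin(delta) + np.cos(lat) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def estimate_pet(tas: np.ndarray, tasmin: np.ndarray, tasmax: np.ndarray,
                 lat: np.ndarray) -> np.ndarray:
    """Monthly potential evapotranspiration, mm/month, by Hargreaves.

    PET = 0.0023 · Ra · (tas + 17.8) · sqrt(tasmax − tasmin) · N_days with
    Ra converted from MJ m-2 day-1 to mm/day by dividing by 2.45 (latent
    heat). Temperature-only by design: the input contract carries no
    humidity or wind. Values are floored at zero.
    """
    tas = np.asarray(tas, dtype=float)
    tasmin = np.asarray(tasmin, dtype=float)
    tasmax = np.asarray(tasmax, dtype=float)
    if np.any(tasmax < tasmin):
        raise ValueError("tasmax < tasmin encountered while estimating PET")
    ra_mm = _extraterrestrial_radiation(lat) / 2.45
    days = _MONTH_DAYS.reshape((12,) + (1,) * (tas.ndim - 1))
    pet = 0.0023 * ra_mm * (tas + 17.8) * np.sqrt(tasmax - tasmin) * days
    return np.maximum(pet, 0.0)


def dryness_index(pr: np.ndarray, pet: np.ndarray,
                  params: DIParams | None = None) -> np.ndarray:
    """Dryness Index: end-of-September potential soil-water reserve, mm.

    Riou's monthly balance: the reserve W starts at Wo in April; each month
    April→September loses vine transpiration Tv = k·ETP and bare-soil
    evaporation Es = (ETP/N)·(1−k)·JPm with JPm = min(N, pr/divisor) wet
    days, and gains the month's precipitation. W is capped at Wo (runoff /
    drainage) but may go negative, expressing a potential deficit.
    """
    params = params or DIParams()
    pr = np.asarray(pr, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if pr.shape[0] != 12 or pet.shape[0] != 12:
        raise ValueError("pr and pet must have 12 months on axis 0")
    if np.any(pet < 0):
        raise ValueError("negative PET supplied to the water balance")
    w = np.full(pr.shape[1:], params.wo, dtype=float)
    for i, month in enumerate(_GS_MONTHS):
        n = _GS_DAYS[i]
        k = params.k_by_month[i]
        etp = pet[month]
        p = pr[month]
        tv = k * etp
        jpm = np.minimum(n, p / params.evap_days_divisor)
        es = (etp / n) * (1.0 - k) * jpm
        w = np.minimum(params.wo, w + p - tv - es)
    return w


def bioclim_dataset(climate: xr.Dataset, di_params: DIParams | None = None) -> xr.Dataset:
    """Compute per-cell HI, CNI and DI for one monthly climatology stack.

    ``climate`` must carry ``tas``/``tasmin``/``tasmax`` (°C) and ``pr``
    (mm/month) on dims ``(month, y, x)`` with a ``lat`` coordinate on
    ``(y, x)`` or ``(y,)``. A ``pet`` variable, when present, overrides the
    Hargreaves estimate.
    """
    lat = climate["lat"].values
    if lat.ndim == 1:  # (y,) -> broadcast over x
        lat = lat[:, None] * np.ones((1, climate.sizes["x"]))
    tas = climate["tas"].values
    tasmin = climate["tasmin"].values
    tasmax = climate["tasmax"].values
    pr = climate["pr"].values
    if "pet" in climate:
        pet = climate["pet"].values
    else:
        pet = estimate_pet(tas, tasmin, tasmax, lat)
    hi = huglin_index(tas, tasmax, lat)
    cni = cool_night_index(tasmin)
    di = dryness_index(pr, pet, di_params)
    return xr.Dataset(
        {
            "hi": (("y", "x"), hi),
            "cni": (("y", "x"), cni),
            "di": (("y", "x"), di),
        },
        coords={k: climate.coords[k] for k in ("y", "x") if k in climate.coords},
    )


def regional_bioclim(cell_bioclim: xr.Dataset, membership: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell indices to regions by (fractional) weighted mean.

    ``membership`` has columns ``region_id, y, x, weight``; weights are
    normalised within each region. Besides the per-index means the result
    carries ``hi_sd``, the within-region weighted standard deviation of the
    Huglin index — the spatial variability of thermal conditions that feeds
    the climatic-niche diagnostic.
    """
    if membership.empty:
        raise ValueError("empty region membership")
    hi = cell_bioclim["hi"].values
    cni = cell_bioclim["cni"].values
    di = cell_bioclim["di"].values
    rows = []
    for region_id, grp in membership.groupby("region_id", sort=True):
        yy = grp["y"].to_numpy(dtype=int)
        xx = grp["x"].to_numpy(dtype=int)
        w = grp["weight"].to_numpy(dtype=float)
        if len(w) == 0 or w.sum() <= 0:
            raise ValueError(f"region {region_id!r} has no member cells")
        w = w / w.sum()
        h = hi[yy, xx]
        mean_hi = float(np.sum(w * h))
        rows.append({
            "region_id": region_id,
            "hi": mean_hi,
            "cni": float(np.sum(w * cni[yy, xx])),
            "di": float(np.sum(w * di[yy, xx])),
            "hi_sd": float(np.sqrt(np.sum(w * (h - mean_hi) ** 2))),
        })
    return pd.DataFrame(rows)
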