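"""Seeded synthetic fixtures emulating every input of the vulnerability pipeline.

The generator produces, from a single integer seed, the full set of inputs
the assessment consumes: monthly climate climatologies for a present and
one or more future scenarios (optionally with pseudo-GCM ensemble members),
contiguous winegrowing regions on the grid, variety catalogues with known
"true" climatic optima, cultivation-area tables with macro-region
indirection and synonym aliasing, correlated adaptive-capacity indicator
tables, and an expert pairwise-comparison matrix built from a known weight
vector. The ground truth (variety optima, noise-free exposure ranking,
true indicator weights) is persisted alongside the fixture so that
parameter-recovery tests can score the pipeline without re-deriving it.

Fixtures are statistical stand-ins only: fields are smooth latitudinal
gradients plus seeded texture and noise, not real European geography.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
import shapely.ops
import xarray as xr

from . import bioclim

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "ClimateStack",
    "RegionSet",
    "generate_climate",
    "generate_regions",
    "generate_varieties",
    "generate_indicators",
    "generate_ahp_matrix",
    "make_fixture",
    "load_fixture",
    "scenario_ladder",
    "INDICATOR_COLUMNS",
    "DEFAULT_DIRECTIONS",
    "INDICATOR_DIMENSIONS",
]

# ---------------------------------------------------------------------------
# adaptive-capacity indicator inventory (five dimensions, 15 indicators)

INDICATOR_DIMENSIONS: dict[str, str] = {
    "aging_index": "social",
    "dependency_ratio": "social",
    "population_density": "social",
    "road_length": "physical",
    "mechanization_index": "physical",
    "naturalness": "physical",
    "shift_in_space": "natural",
    "water_availability": "natural",
    "climatic_niches": "natural",
    "labor_force": "human",
    "education_level": "human",
    "research_accessibility": "human",
    "debt_ratio": "financial",
    "return_on_assets": "financial",
    "subsidy_dependence": "financial",
}
INDICATOR_COLUMNS: tuple[str, ...] = tuple(INDICATOR_DIMENSIONS)

# Direction conventions: whether a larger raw value means more capacity to
# adapt. Reconstructed from the meaning of each indicator (e.g. an older
# population, a heavier debt load or a longer distance to the nearest
# research centre all reduce capacity); editable by the caller.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "aging_index": "lower_is_better",
    "dependency_ratio": "lower_is_better",
    "population_density": "lower_is_better",
    "road_length": "higher_is_better",
    "mechanization_index": "higher_is_better",
    "naturalness": "higher_is_better",
    "shift_in_space": "higher_is_better",
    "water_availability": "higher_is_better",
    "climatic_niches": "higher_is_better",
    "labor_force": "higher_is_better",
    "education_level": "higher_is_better",
    "research_accessibility": "lower_is_better",
    "debt_ratio": "lower_is_better",
    "return_on_assets": "higher_is_better",
    "subsidy_dependence": "lower_is_better",
}

# per-indicator (location, scale) used to map correlated z-draws onto
# plausible raw units
_INDICATOR_MOMENTS: dict[str, tuple[float, float]] = {
    "aging_index": (1.4, 0.35),
    "dependency_ratio": (0.55, 0.10),
    "population_density": (1.8, 0.8),
    "road_length": (120.0, 45.0),
    "mechanization_index": (3200.0, 900.0),
    "naturalness": (35.0, 12.0),
    "shift_in_space": (60.0, 30.0),
    "water_availability": (180.0, 70.0),
    "climatic_niches": (1.6, 0.6),
    "labor_force": (65.0, 15.0),
    "education_level": (2.1, 0.5),
    "research_accessibility": (85.0, 40.0),
    "debt_ratio": (28.0, 10.0),
    "return_on_assets": (6.5, 2.5),
    "subsidy_dependence": (22.0, 9.0),
}

_COUNTRIES = ("AT", "BT", "CT", "DT")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic study.

    Defaults describe a desk-scale stand-in for a continental assessment:
    a 60x60 grid spanning the 36-51°N vine belt, 60 regions, 20 varieties,
    a +2.5 °C / -15 % precipitation end-of-century scenario and a 5-member
    pseudo-GCM ensemble.
    """

    grid_shape: tuple[int, int] = (60, 60)
    cell_size_deg: float = 0.25
    lat_range: tuple[float, float] = (36.0, 51.0)
    n_regions: int = 60
    n_varieties: int = 20
    n_macro_regions: int = 8
    warming_delta_C: float = 2.5
    precip_factor: float = 0.85
    noise_sd: float = 0.3
    synonym_rate: float = 0.2
    indicator_corr: float = 0.3
    seed: int = 0
    n_members: int = 5
    macro_share: float = 0.4
    # scenario label -> (warming delta °C, precipitation factor); None means
    # the single default scenario built from warming_delta_C/precip_factor
    scenarios: tuple[tuple[str, float, float], ...] | None = None
    optimum_bandwidth: float = 0.6
    ahp_noise: float = 0.05

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape dimensions must be positive")
        if not 0.0 <= self.synonym_rate <= 1.0:
            raise ValueError("synonym_rate must lie in [0, 1]")
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions (tertile classes)")
        if abs(self.indicator_corr) >= 1.0:
            raise ValueError("indicator_corr must satisfy |rho| < 1")
        if self.indicator_corr < -1.0 / (len(INDICATOR_COLUMNS) - 1):
            raise ValueError("indicator_corr too negative for a valid "
                             "equicorrelation matrix of 15 indicators")
        if not 0.0 <= self.macro_share <= 1.0:
            raise ValueError("macro_share must lie in [0, 1]")

    def resolved_scenarios(self) -> tuple[tuple[str, float, float], ...]:
        if self.scenarios is not None:
            return self.scenarios
        return (("ssp370", self.warming_delta_C, self.precip_factor),)


def scenario_ladder(config: SynthConfig) -> SynthConfig:
    """Return a config with an increasing-severity three-scenario ladder.

    The ladder stands in for ssp126 / ssp370 / ssp585 over the same future
    period: warming scaled by 0.5 / 1.0 / 1.6 of the configured delta, with
    proportionally deepened drying.
    """
    d, pf = config.warming_delta_C, config.precip_factor
    ladder = tuple(
        (name, f * d, 1.0 - f * (1.0 - pf))
        for name, f in (("ssp126", 0.5), ("ssp370", 1.0), ("ssp585", 1.6))
    )
    return dataclasses.replace(config, scenarios=ladder)


@dataclass
class GroundTruth:
    """Persisted generator truth used by parameter-recovery tests."""

    variety_optima: pd.DataFrame  # variety, hi, cni, di
    region_true_e_rank: pd.DataFrame  # region_id, true_e_rank (1 = largest change)
    ac_true_weights: np.ndarray  # the weight vector behind the AHP matrix

    def to_json(self) -> str:
        return json.dumps(
            {
                "variety_optima": self.variety_optima.to_dict(orient="list"),
                "region_true_e_rank": self.region_true_e_rank.to_dict(orient="list"),
                "ac_true_weights": [float(w) for w in self.ac_true_weights],
            },
            sort_keys=True,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            variety_optima=pd.DataFrame(d["variety_optima"]),
            region_true_e_rank=pd.DataFrame(d["region_true_e_rank"]),
            ac_true_weights=np.asarray(d["ac_true_weights"], dtype=float),
        )


@dataclass
class ClimateStack:
    """Monthly climatology stacks for the present period and future scenarios."""

    present: xr.Dataset
    scenarios: dict[str, xr.Dataset]
    members: dict[str, list[xr.Dataset]] = field(default_factory=dict)


@dataclass
class RegionSet:
    """Winegrowing regions as contiguous cell blobs on the climate grid."""

    table: pd.DataFrame  # region_id, country, centroid_lat, centroid_lon, vineyard_area_ha
    membership: pd.DataFrame  # region_id, y, x, weight

    @property
    def region_ids(self) -> list[str]:
        return list(self.table["region_id"])

    def to_geojson(self, grid: xr.Dataset) -> dict:
        """Dissolve each region's cells into a polygon feature."""
        lat = grid["lat"].values
        lon = grid["lon"].values
        half_lat = float(abs(lat[1] - lat[0])) / 2.0 if len(lat) > 1 else 0.5
        half_lon = float(abs(lon[1] - lon[0])) / 2.0 if len(lon) > 1 else 0.5
        features = []
        for _, row in self.table.iterrows():
            cells = self.membership[self.membership["region_id"] == row["region_id"]]
            boxes = [
                sgeom.box(lon[int(c.x)] - half_lon, lat[int(c.y)] - half_lat,
                          lon[int(c.x)] + half_lon, lat[int(c.y)] + half_lat)
                for c in cells.itertuples()
            ]
            geom = shapely.unary_union(boxes)
            features.append({
                "type": "Feature",
                "geometry": sgeom.mapping(geom),
                "properties": {
                    "region_id": row["region_id"],
                    "country": row["country"],
                    "vineyard_area_ha": float(row["vineyard_area_ha"]),
                },
            })
        return {"type": "FeatureCollection", "features": features}

    @classmethod
    def from_geojson(cls, collection: dict, grid: xr.Dataset) -> "RegionSet":
        """Rebuild cell membership by point-in-polygon tests on cell centres."""
        lat = grid["lat"].values
        lon = grid["lon"].values
        lon2d, lat2d = np.meshgrid(lon, lat)
        rows, members = [], []
        for feat in collection["features"]:
            geom = sgeom.shape(feat["geometry"])
            props = feat["properties"]
            inside = shapely.contains_xy(geom, lon2d.ravel(), lat2d.ravel())
            yy, xx = np.unravel_index(np.flatnonzero(inside), lat2d.shape)
            if len(yy) == 0:
                raise ValueError(f"region {props['region_id']!r} covers no grid cell")
            for y, x in zip(yy, xx):
                members.append({"region_id": props["region_id"], "y": int(y),
                                "x": int(x), "weight": 1.0})
            rows.append({
                "region_id": props["region_id"],
                "country": props["country"],
                "centroid_lat": float(lat[yy].mean()),
                "centroid_lon": float(lon[xx].mean()),
                "vineyard_area_ha": float(props["vineyard_area_ha"]),
            })
        return cls(table=pd.DataFrame(rows), membership=pd.DataFrame(members))


# ---------------------------------------------------------------------------
# climate


def _grid_coords(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = config.grid_shape
    lat_lo, lat_hi = config.lat_range
    lat = lat_hi - np.arange(rows) * config.cell_size_deg
    if rows > 1:  # honour the requested latitude span
        lat = lat_hi - np.arange(rows) * (lat_hi - lat_lo) / (rows - 1)
    lon = np.arange(cols) * config.cell_size_deg
    return lat, lon


def _texture(rng: np.random.Generator, shape: tuple[int, int], n_modes: int = 6) -> np.ndarray:
    """Smooth zero-mean random field from a few low-frequency Fourier modes."""
    rows, cols = shape
    yy, xx = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij")
    fld = np.zeros(shape)
    for _ in range(n_modes):
        fy, fx = rng.uniform(0.5, 3.0, size=2)
        phase_y, phase_x = rng.uniform(0, 2 * np.pi, size=2)
        fld += rng.normal() * np.sin(2 * np.pi * fy * yy + phase_y) * np.sin(2 * np.pi * fx * xx + phase_x)
    fld -= fld.mean()
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def _base_fields(config: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Noise-free monthly climatology of the present period."""
    rows, cols = config.grid_shape
    lat, _ = _grid_coords(config)
    lat2d = lat[:, None] * np.ones((1, cols))
    months = np.arange(12)
    seasonal = np.cos(2 * np.pi * (months - 6) / 12.0)  # +1 in July
    elev = _texture(rng, (rows, cols))  # pseudo-orography
    t_annual = 16.0 - 0.6 * (lat2d - lat2d.min()) - 2.0 * elev
    amp = 9.0 + 0.5 * _texture(rng, (rows, cols))
    tas = t_annual[None, :, :] + amp[None, :, :] * seasonal[:, None, None]
    dtr = np.clip(9.0 + 1.5 * _texture(rng, (rows, cols)), 4.0, None)
    tasmin = tas - dtr[None, :, :] / 2.0
    tasmax = tas + dtr[None, :, :] / 2.0
    pr_base = 45.0 + 1.8 * (lat2d - lat2d.min()) + 8.0 * _texture(rng, (rows, cols))
    pr_seasonal = 1.0 - 0.35 * seasonal  # summer dip, winter peak
    pr = np.clip(pr_base[None, :, :] * pr_seasonal[:, None, None], 0.0, None)
    return {"tas": tas, "tasmin": tasmin, "tasmax": tasmax, "pr": pr}


def _to_dataset(fields: dict[str, np.ndarray], config: SynthConfig) -> xr.Dataset:
    lat, lon = _grid_coords(config)
    return xr.Dataset(
        {name: (("month", "y", "x"), arr) for name, arr in fields.items()},
        coords={
            "month": np.arange(1, 13),
            "y": np.arange(config.grid_shape[0]),
            "x": np.arange(config.grid_shape[1]),
            "lat": ("y", lat),
            "lon": ("x", lon),
        },
    )


def _add_noise(fields: dict[str, np.ndarray], sd: float,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    if sd == 0:
        return {k: v.copy() for k, v in fields.items()}
    t_noise = rng.normal(0.0, sd, size=fields["tas"].shape)
    p_noise = rng.normal(0.0, sd, size=fields["pr"].shape)
    return {
        "tas": fields["tas"] + t_noise,
        "tasmin": fields["tasmin"] + t_noise,  # shared shift keeps ordering
        "tasmax": fields["tasmax"] + t_noise,
        "pr": np.clip(fields["pr"] + p_noise, 0.0, None),
    }


def _shift(fields: dict[str, np.ndarray], warm: float, pfac: float) -> dict[str, np.ndarray]:
    return {
        "tas": fields["tas"] + warm,
        "tasmin": fields["tasmin"] + warm,
        "tasmax": fields["tasmax"] + warm,
        "pr": fields["pr"] * pfac,
    }


def generate_climate(config: SynthConfig) -> ClimateStack:
    """Generate present and future monthly climatologies.

    The future scenario is the present base field plus a uniform warming
    delta, with precipitation scaled multiplicatively; each period carries
    its own seeded noise realisation. Pseudo-GCM members are the scenario
    field plus zero-mean perturbations, so their ensemble mean reproduces
    the scenario exactly.
    """
    root = np.random.default_rng(config.seed)
    base_rng = np.random.default_rng(root.integers(2**31))
    base = _base_fields(config, base_rng)
    present = _add_noise(base, config.noise_sd, np.random.default_rng(root.integers(2**31)))
    scenarios: dict[str, xr.Dataset] = {}
    members: dict[str, list[xr.Dataset]] = {}
    for name, warm, pfac in config.resolved_scenarios():
        fut = _add_noise(_shift(base, warm, pfac), config.noise_sd,
                         np.random.default_rng(root.integers(2**31)))
        scenarios[name] = _to_dataset(fut, config)
        if config.n_members >= 2:
            pert_rng = np.random.default_rng(root.integers(2**31))
            t_perts = np.stack([_texture(pert_rng, config.grid_shape)
                                for _ in range(config.n_members)])
            p_perts = np.stack([_texture(pert_rng, config.grid_shape)
                                for _ in range(config.n_members)])
            t_perts -= t_perts.mean(axis=0, keepdims=True)
            p_perts -= p_perts.mean(axis=0, keepdims=True)
            mem = []
            for k in range(config.n_members):
                mk = {
                    "tas": fut["tas"] + 0.5 * t_perts[k],
                    "tasmin": fut["tasmin"] + 0.5 * t_perts[k],
                    "tasmax": fut["tasmax"] + 0.5 * t_perts[k],
                    "pr": fut["pr"] + 4.0 * p_perts[k],
                }
                mem.append(_to_dataset(mk, config))
            members[name] = mem
    return ClimateStack(present=_to_dataset(present, config),
                        scenarios=scenarios, members=members)


# ---------------------------------------------------------------------------
# regions


def _repair_contiguity(owner: np.ndarray, sy: np.ndarray, sx: np.ndarray) -> np.ndarray:
    """Reassign cells disconnected from their region's seed to a neighbour.

    Discrete Voronoi partitions are almost always contiguous under
    4-connectivity, but thin slivers can detach; flood-fill from each seed
    and hand orphan cells to an adjacent region, keeping every blob a
    single connected component.
    """
    from collections import deque

    rows, cols = owner.shape
    keep = np.full(owner.shape, -1, dtype=int)
    for r, (y0, x0) in enumerate(zip(sy, sx)):
        q = deque([(int(y0), int(x0))])
        keep[y0, x0] = r
        while q:
            y, x = q.popleft()
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < rows and 0 <= nx < cols \
                        and keep[ny, nx] == -1 and owner[ny, nx] == r:
                    keep[ny, nx] = r
                    q.append((ny, nx))
    orphans = deque(zip(*np.nonzero(keep == -1)))
    while orphans:
        y, x = orphans.popleft()
        neigh = [keep[y + dy, x + dx] for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
                 if 0 <= y + dy < rows and 0 <= x + dx < cols and keep[y + dy, x + dx] >= 0]
        if neigh:
            keep[y, x] = min(neigh)
        else:
            orphans.append((int(y), int(x)))
    return keep


def generate_regions(config: SynthConfig) -> RegionSet:
    """Partition the grid into contiguous regions around jittered seed cells.

    Each cell joins its nearest seed (a discrete Voronoi partition, which
    is contiguous on a regular grid); countries are longitude bands of the
    region centroids and vineyard areas are lognormal.
    """
    rows, cols = config.grid_shape
    if config.n_regions > rows * cols:
        raise ValueError("grid too small for the requested number of regions")
    rng = np.random.default_rng(np.random.default_rng(config.seed + 1).integers(2**31))
    idx = rng.choice(rows * cols, size=config.n_regions, replace=False)
    sy, sx = np.unravel_index(idx, (rows, cols))
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (yy[None] - sy[:, None, None]) ** 2 + (xx[None] - sx[:, None, None]) ** 2
    owner = d2.argmin(axis=0)  # ties -> lowest region index
    owner = _repair_contiguity(owner, sy, sx)
    lat, lon = _grid_coords(config)
    width = max(config.n_regions // len(_COUNTRIES), 1)
    areas = rng.lognormal(mean=np.log(2000.0), sigma=0.6, size=config.n_regions)
    rows_out, members = [], []
    # order region ids by seed longitude so country bands are contiguous
    order = np.argsort(sx, kind="stable")
    for rank, r in enumerate(order):
        rid = f"R{rank + 1:03d}"
        ys, xs = np.nonzero(owner == r)
        country = _COUNTRIES[min(rank // width, len(_COUNTRIES) - 1)]
        rows_out.append({
            "region_id": rid,
            "country": country,
            "centroid_lat": float(lat[ys].mean()),
            "centroid_lon": float(lon[xs].mean()),
            "vineyard_area_ha": float(areas[rank]),
        })
        for y, x in zip(ys, xs):
            members.append({"region_id": rid, "y": int(y), "x": int(x), "weight": 1.0})
    return RegionSet(table=pd.DataFrame(rows_out), membership=pd.DataFrame(members))


# ---------------------------------------------------------------------------
# varieties, cultivation, synonyms


def _regional_present_bioclim(climate: ClimateStack, regions: RegionSet) -> pd.DataFrame:
    cells = bioclim.bioclim_dataset(climate.present)
    return bioclim.regional_bioclim(cells, regions.membership)


def generate_varieties(
    config: SynthConfig, regions: RegionSet, climate: ClimateStack
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Place varieties in climate space and distribute cultivation areas.

    Each variety receives a true optimum per bioclimatic index (a region's
    present climate plus jitter); its cultivation area decays as a Gaussian
    in standardised climate distance from that optimum, which makes the
    area-weighted mean of regional climates a consistent estimator of the
    optimum. A share of cultivation rows is re-addressed at macro-region
    level, and a fraction of variety mentions is replaced by country-scoped
    synonyms recorded in the synonym table.

    Returns (catalog, cultivation, synonyms, macro_map, ground_truth).
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed + 2).integers(2**31))
    regional = _regional_present_bioclim(climate, regions).merge(
        regions.table, on="region_id")
    vals = regional[["hi", "cni", "di"]].to_numpy()
    mu, sd = vals.mean(axis=0), vals.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (vals - mu) / sd

    n_v = config.n_varieties
    anchor = rng.integers(0, len(regional), size=n_v)
    opt_z = z[anchor] + rng.normal(0.0, 0.2, size=(n_v, 3))
    optima = opt_z * sd + mu
    var_names = [f"Variety_{i + 1:03d}" for i in range(n_v)]

    totals = rng.lognormal(mean=np.log(5000.0), sigma=0.8, size=n_v)
    d2 = ((z[None, :, :] - opt_z[:, None, :]) ** 2).mean(axis=2)  # (v, r)
    w = np.exp(-0.5 * d2 / config.optimum_bandwidth**2)

    catalog_rows, cult_rows = [], []
    region_ids = regional["region_id"].to_list()
    region_country = dict(zip(regions.table["region_id"], regions.table["country"]))
    authorized = np.zeros_like(w, dtype=bool)
    for v in range(n_v):
        rel = w[v] / w[v].max()
        authorized[v] = rel > 0.05
    # every region must authorise at least one variety
    for r in range(len(region_ids)):
        if not authorized[:, r].any():
            authorized[w[:, r].argmax(), r] = True
    for v, vname in enumerate(var_names):
        wv = np.where(authorized[v], w[v], 0.0)
        shares = wv / wv.sum()
        cutoff = np.quantile(shares[authorized[v]], 0.3) if authorized[v].sum() > 1 else 0.0
        for r, rid in enumerate(region_ids):
            if not authorized[v, r]:
                continue
            role = "primary" if shares[r] >= cutoff else "additional"
            catalog_rows.append({"region_id": rid, "variety_name": vname, "role": role})
            area = totals[v] * shares[r]
            if area > 0:
                cult_rows.append({"region_id": rid, "variety_name": vname,
                                  "area_ha": float(area)})
    catalog = pd.DataFrame(catalog_rows)
    # ensure every region keeps at least one primary variety
    for rid, grp in catalog.groupby("region_id"):
        if not (grp["role"] == "primary").any():
            catalog.loc[grp.index[0], "role"] = "primary"

    # macro-regions: country-pure chunks of regions
    macro_rows = []
    macro_of_region: dict[str, str] = {}
    if config.n_macro_regions > 0:
        countries = regions.table.groupby("country")["region_id"].apply(list)
        n_groups = max(config.n_macro_regions, len(countries))
        per_country = np.maximum(
            np.round(np.array([len(v) for v in countries]) / len(regions.table)
                     * n_groups).astype(int), 1)
        m = 0
        for (country, rids), k in zip(countries.items(), per_country):
            chunks = np.array_split(np.array(rids), k)
            for chunk in chunks:
                if len(chunk) == 0:
                    continue
                m += 1
                mid = f"M{m:03d}"
                for rid in chunk:
                    macro_rows.append({"macro_id": mid, "region_id": rid})
                    macro_of_region[rid] = mid
    macro_map = pd.DataFrame(macro_rows, columns=["macro_id", "region_id"])

    # cultivation table with macro indirection
    cult = pd.DataFrame(cult_rows)
    unit_rows = []
    macro_accum: dict[tuple[str, str], float] = {}
    to_macro = rng.random(len(cult)) < (config.macro_share if macro_rows else 0.0)
    for (row, macro_flag) in zip(cult.itertuples(), to_macro):
        if macro_flag and row.region_id in macro_of_region:
            key = (macro_of_region[row.region_id], row.variety_name)
            macro_accum[key] = macro_accum.get(key, 0.0) + row.area_ha
        else:
            unit_rows.append({"unit_id": row.region_id, "unit_level": "pdo",
                              "variety_name": row.variety_name, "area_ha": row.area_ha})
    for (mid, vname), area in sorted(macro_accum.items()):
        unit_rows.append({"unit_id": mid, "unit_level": "macro",
                          "variety_name": vname, "area_ha": area})
    cultivation = pd.DataFrame(unit_rows)

    # country-scoped synonyms; aliases replace a fraction of mentions
    macro_country = {mid: region_country[rids[0]] for mid, rids in
                     macro_map.groupby("macro_id")["region_id"].apply(list).items()} \
        if len(macro_map) else {}
    syn_rows = []
    alias_of: dict[tuple[str, str], str] = {}
    for i in range(len(cultivation)):
        if rng.random() >= config.synonym_rate:
            continue
        row = cultivation.iloc[i]
        country = (region_country[row["unit_id"]] if row["unit_level"] == "pdo"
                   else macro_country[row["unit_id"]])
        key = (country, row["variety_name"])
        if key not in alias_of:
            alias = f"Syn_{row['variety_name']}_{country}"
            alias_of[key] = alias
            syn_rows.append({"canonical_name": row["variety_name"], "synonym": alias,
                             "country": country, "tier": int(rng.integers(1, 3))})
        cultivation.iat[i, cultivation.columns.get_loc("variety_name")] = alias_of[key]
    synonyms = pd.DataFrame(syn_rows,
                            columns=["canonical_name", "synonym", "country", "tier"])

    truth = GroundTruth(
        variety_optima=pd.DataFrame({
            "variety": var_names,
            "hi": optima[:, 0], "cni": optima[:, 1], "di": optima[:, 2],
        }),
        region_true_e_rank=_true_exposure_rank(config, regions),
        ac_true_weights=np.array([]),
    )
    return catalog, cultivation, synonyms, macro_map, truth


def _true_exposure_rank(config: SynthConfig, regions: RegionSet) -> pd.DataFrame:
    """Exposure ranking from the noise-free fields (1 = greatest change)."""
    from . import exposure as expo

    quiet = dataclasses.replace(config, noise_sd=0.0, n_members=0)
    clim = generate_climate(quiet)
    pres = bioclim.regional_bioclim(bioclim.bioclim_dataset(clim.present),
                                    regions.membership)
    name = quiet.resolved_scenarios()[-1][0]
    fut = bioclim.regional_bioclim(bioclim.bioclim_dataset(clim.scenarios[name]),
                                   regions.membership)
    deltas = expo.adverse_delta(pres, fut)
    scores = expo.exposure_index(deltas)
    ranks = scores["exposure"].rank(ascending=False, method="first").astype(int)
    return pd.DataFrame({"region_id": scores["region_id"], "true_e_rank": ranks})


# ---------------------------------------------------------------------------
# indicators & AHP


def generate_indicators(config: SynthConfig, regions: RegionSet) -> pd.DataFrame:
    """Correlated multivariate draw of the 15 adaptive-capacity indicators."""
    rho = config.indicator_corr
    p = len(INDICATOR_COLUMNS)
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    rng = np.random.default_rng(np.random.default_rng(config.seed + 3).integers(2**31))
    chol = np.linalg.cholesky(cov)
    zs = rng.normal(size=(len(regions.table), p)) @ chol.T
    data = {"region_id": regions.table["region_id"].to_list()}
    for j, col in enumerate(INDICATOR_COLUMNS):
        loc, scale = _INDICATOR_MOMENTS[col]
        data[col] = loc + scale * zs[:, j]
    return pd.DataFrame(data)


def generate_ahp_matrix(config: SynthConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise-comparison matrix built from a known weight vector.

    Entries are w_i/w_j with multiplicative lognormal perturbation of the
    upper triangle (reciprocity enforced exactly), so the principal
    eigenvector recovers the weights up to the perturbation.
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed + 4).integers(2**31))
    p = len(INDICATOR_COLUMNS)
    w = rng.dirichlet(np.full(p, 3.0))
    a = np.outer(w, 1.0 / w)
    noise = np.exp(rng.normal(0.0, config.ahp_noise, size=(p, p)))
    for i in range(p):
        for j in range(i + 1, p):
            a[i, j] *= noise[i, j]
            a[j, i] = 1.0 / a[i, j]
    mat = pd.DataFrame(a, index=list(INDICATOR_COLUMNS), columns=list(INDICATOR_COLUMNS))
    return mat, w


# ---------------------------------------------------------------------------
# fixture I/O


def _write_netcdf(ds: xr.Dataset, path: Path) -> None:
    ds.to_netcdf(path, engine="scipy")


def _directions_toml(directions: dict[str, str]) -> str:
    lines = ["[directions]"]
    for k in INDICATOR_COLUMNS:
        lines.append(f'{k} = "{directions[k]}"')
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture(config: SynthConfig, out_dir: str | Path) -> dict:
    """Write the complete fixture to ``out_dir`` and return its manifest.

    Files: ``climate_present.nc``, one ``climate_<scenario>.nc`` per
    scenario (plus ``_m<k>`` member files), ``regions.geojson``,
    ``varieties.csv``, ``cultivation.csv``, ``synonyms.csv``,
    ``macro_map.csv``, ``indicators.csv``, ``directions.toml``,
    ``ahp_matrix.csv``, ``ground_truth.json`` and ``manifest.json`` with
    SHA-256 hashes of everything else.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    climate = generate_climate(config)
    regions = generate_regions(config)
    catalog, cultivation, synonyms, macro_map, truth = generate_varieties(
        config, regions, climate)
    indicators = generate_indicators(config, regions)
    ahp, true_w = generate_ahp_matrix(config)
    truth.ac_true_weights = true_w

    _write_netcdf(climate.present, out / "climate_present.nc")
    for name, ds in climate.scenarios.items():
        _write_netcdf(ds, out / f"climate_{name}.nc")
        for k, mds in enumerate(climate.members.get(name, [])):
            _write_netcdf(mds, out / f"climate_{name}_m{k + 1}.nc")
    (out / "regions.geojson").write_text(
        json.dumps(regions.to_geojson(climate.present), sort_keys=True))
    catalog.to_csv(out / "varieties.csv", index=False)
    cultivation.to_csv(out / "cultivation.csv", index=False)
    synonyms.to_csv(out / "synonyms.csv", index=False)
    macro_map.to_csv(out / "macro_map.csv", index=False)
    indicators.to_csv(out / "indicators.csv", index=False)
    (out / "directions.toml").write_text(_directions_toml(DEFAULT_DIRECTIONS))
    ahp.to_csv(out / "ahp_matrix.csv")
    (out / "ground_truth.json").write_text(truth.to_json())

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def load_fixture(fixture_dir: str | Path) -> dict:
    """Read a fixture directory back into in-memory objects."""
    d = Path(fixture_dir)
    present = xr.load_dataset(d / "climate_present.nc", engine="scipy")
    scenarios, members = {}, {}
    for p in sorted(d.glob("climate_*.nc")):
        stem = p.stem.removeprefix("climate_")
        if stem == "present":
            continue
        if "_m" in stem and stem.rsplit("_m", 1)[1].isdigit():
            base = stem.rsplit("_m", 1)[0]
            members.setdefault(base, []).append(xr.load_dataset(p, engine="scipy"))
        else:
            scenarios[stem] = xr.load_dataset(p, engine="scipy")
    regions = RegionSet.from_geojson(
        json.loads((d / "regions.geojson").read_text()), present)
    out = {
        "climate": ClimateStack(present=present, scenarios=scenarios, members=members),
        "regions": regions,
        "catalog": pd.read_csv(d / "varieties.csv"),
        "cultivation": pd.read_csv(d / "cultivation.csv"),
        "synonyms": pd.read_csv(d / "synonyms.csv"),
        "macro_map": pd.read_csv(d / "macro_map.csv"),
        "indicators": pd.read_csv(d / "indicators.csv"),
        "ahp_matrix": pd.read_csv(d / "ahp_matrix.csv", index_col=0),
    }
    gt = d / "ground_truth.json"
    if gt.exists():
        out["ground_truth"] = GroundTruth.from_json(gt.read_text())
    import tomllib

    with open(d / "directions.toml", "rb") as fh:
        out["directions"] = tomllib.load(fh)["directions"]
    return out
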