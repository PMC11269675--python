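"""End-to-end orchestration of the vulnerability assessment.

``run_all`` drives the stages in order — (optional) synthetic fixture
generation, bioclimatic indices, exposure, variety canonicalisation and
allocation, bioregional ranges, sensitivity and positive-effect shares,
adaptive capacity, vulnerability classification — reading a fixture
directory and writing stage CSVs plus a manifest with the config hash,
per-stage row counts and warning counts. Every stage is also callable on
its own for partial reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bioclim, capacity, exposure, synthetic, varieties, vulnerability

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``input_dir`` holds the fixture (see :func:`vitivuln.synthetic.make_fixture`
    for the file inventory); ``scenario`` selects the future stack used for
    exposure and sensitivity-side diagnostics. Strategy switches default to
    the study's stated choices (signed adverse deltas, equal indicator
    weights) or, where the choice was open, to the package defaults
    documented in each stage module.
    """

    input_dir: str = "fixture"
    out_dir: str = "out"
    scenario: str = "ssp370"
    delta_mode: str = "signed"
    sensitivity_standardization: str = "zscore"
    benefit_rule: str = "mean_deviation"
    positive_weighting: str = "area"
    weighting_mode: str = "equal"  # equal | ahp
    range_sd_multiplier: float = 1.0
    seed: int = 0
    simulate: bool = False
    synth: dict = field(default_factory=dict)  # SynthConfig overrides

    def config_hash(self) -> str:
        # path fields are machine-specific and do not affect the results,
        # so they stay out of the hash: identical settings => identical hash
        payload = dataclasses.asdict(self)
        payload.pop("input_dir")
        payload.pop("out_dir")
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML file."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    synth = raw.pop("synth", {})
    cfg = RunConfig(**raw)
    cfg.synth = synth
    return cfg


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def write_stage_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Stage CSV writer; %.17g keeps float64 round-trips bit-exact so
    partial reruns reproduce the pipeline identically."""
    df.to_csv(path, index=False, float_format="%.17g")


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_stage_csv(path: str | Path) -> pd.DataFrame:
    # exactly-rounded float parsing so stagewise reruns reproduce run_all
    # bit for bit
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def fixture_allocation(fx: dict, regional_present: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Canonicalise, resolve primaries, allocate areas and group regions.

    The shared front half of the sensitivity chain: attaches countries to
    cultivation units, maps aliased variety names through the synonym
    tables, applies the primary-variety fallback, distributes macro-level
    areas onto authorising regions and assigns present-period climate
    groups. Returns (allocation, catalog, groups, match_report).
    """
    regions = fx["regions"]
    cult = fx["cultivation"].copy()
    region_country = dict(zip(regions.table["region_id"],
                              regions.table["country"]))
    macro_country = {}
    if len(fx["macro_map"]):
        macro_country = (fx["macro_map"].merge(
            regions.table[["region_id", "country"]], on="region_id")
            .drop_duplicates("macro_id").set_index("macro_id")["country"]
            .to_dict())
    cult["country"] = [
        region_country[u] if lvl == "pdo" else macro_country[u]
        for u, lvl in zip(cult["unit_id"], cult["unit_level"])]
    known = set(fx["catalog"]["variety_name"])
    cult, report = varieties.canonicalize_varieties(cult, fx["synonyms"],
                                                    known_names=known)
    catalog = varieties.resolve_primary(fx["catalog"])
    allocation = varieties.allocate_cultivation(cult, fx["macro_map"],
                                                regions.table, catalog)
    groups = varieties.classify_climate_group(regional_present)
    return allocation, catalog, groups, report


def _apply_sd_multiplier(ranges: pd.DataFrame, mult: float) -> pd.DataFrame:
    out = ranges.copy()
    out["upper_limit"] = out["weighted_mean"] + mult * out["weighted_sd"]
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Validates that every required input exists before any computation,
    then runs the stages in order. Output CSVs carry the config hash in a
    comment header; the manifest records row counts, logged-warning counts
    and output file hashes.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    counter = _WarningCounter()
    pkg_logger = logging.getLogger("vitivuln")
    pkg_logger.addHandler(counter)
    try:
        if config.simulate:
            synth_cfg = synthetic.SynthConfig(
                **{"seed": config.seed, **config.synth})
            synthetic.make_fixture(synth_cfg, in_dir)

        # validation-first: every consumed file must exist before compute
        for name in ("climate_present.nc", f"climate_{config.scenario}.nc",
                     "regions.geojson", "varieties.csv", "cultivation.csv",
                     "synonyms.csv", "macro_map.csv", "indicators.csv",
                     "directions.toml"):
            _require(in_dir / name)

        fx = synthetic.load_fixture(in_dir)
        clim: synthetic.ClimateStack = fx["climate"]
        regions: synthetic.RegionSet = fx["regions"]
        if config.scenario not in clim.scenarios:
            raise KeyError(f"scenario {config.scenario!r} not in fixture "
                           f"(have {sorted(clim.scenarios)})")

        # --- bioclim stage -------------------------------------------------
        cells_present = bioclim.bioclim_dataset(clim.present)
        regional = {"present": bioclim.regional_bioclim(cells_present,
                                                        regions.membership)}
        for name, ds in clim.scenarios.items():
            regional[name] = bioclim.regional_bioclim(
                bioclim.bioclim_dataset(ds), regions.membership)
        bio_rows = []
        for period, df in regional.items():
            d = df.copy()
            d.insert(1, "period", period)
            bio_rows.append(d)
        bio_table = pd.concat(bio_rows, ignore_index=True)
        _write(bio_table, out_dir / "bioclim_regions.csv", cfg_hash)
        logger.info("bioclim: %d region-period rows", len(bio_table))

        # --- exposure stage ------------------------------------------------
        deltas = exposure.adverse_delta(regional["present"],
                                        regional[config.scenario],
                                        mode=config.delta_mode)
        expo = exposure.exposure_index(deltas)
        _write(expo, out_dir / "exposure.csv", cfg_hash)

        # --- varieties / ranges stage -------------------------------------
        allocation, catalog, groups, match_report = fixture_allocation(
            fx, regional["present"])
        (out_dir / "match_report.json").write_text(
            json.dumps(match_report, indent=1, sort_keys=True))
        ranges = varieties.estimate_ranges(regional["present"], allocation, groups)
        ranges = _apply_sd_multiplier(ranges, config.range_sd_multiplier)
        _write(ranges, out_dir / "ranges.csv", cfg_hash)

        # --- sensitivity & positive effects -------------------------------
        sens = varieties.gi_sensitivity(
            regional["present"], ranges, allocation, catalog, groups,
            standardization=config.sensitivity_standardization)
        for name in clim.scenarios:
            share = varieties.positive_effect_share(
                ranges, regional["present"], regional[name], allocation,
                catalog, groups, benefit_rule=config.benefit_rule,
                weighting=config.positive_weighting)
            col = f"positive_share_{name}"
            sens = sens.merge(share.rename(columns={"positive_share": col}),
                              on="region_id")
        sens["positive_share"] = sens[f"positive_share_{config.scenario}"]
        _write(sens, out_dir / "sensitivity.csv", cfg_hash)

        # --- adaptive capacity ---------------------------------------------
        weights = None
        ahp_report = None
        if (in_dir / "ahp_matrix.csv").exists():
            w, lam, cr = capacity.ahp_weights(fx["ahp_matrix"])
            ok, msg = capacity.check_consistency(cr)
            ahp_report = {"weights": [float(x) for x in w],
                          "lambda_max": lam, "cr": cr,
                          "accepted": ok, "message": msg}
            (out_dir / "ahp_report.json").write_text(
                json.dumps(ahp_report, indent=1, sort_keys=True))
            if config.weighting_mode == "ahp":
                if not ok:
                    raise ValueError(f"AHP weighting requested but {msg}")
                weights = w
        elif config.weighting_mode == "ahp":
            raise FileNotFoundError("weighting_mode='ahp' but no ahp_matrix.csv "
                                    "in the input directory")
        cap = capacity.capacity_scores(fx["indicators"],
                                       directions=fx["directions"],
                                       weights=weights)
        _write(cap, out_dir / "capacity.csv", cfg_hash)

        # --- vulnerability --------------------------------------------------
        prof, summary = vulnerability.assemble_profiles(
            expo, sens, cap, regions=regions.table)
        _write(prof, out_dir / "vulnerability.csv", cfg_hash)
        if summary is not None:
            _write(summary, out_dir / "country_summary.csv", cfg_hash)

        outputs = sorted(p.name for p in out_dir.iterdir()
                         if p.name != "manifest.json")
        manifest = {
            "config_hash": cfg_hash,
            "config": dataclasses.asdict(config),
            "n_regions": int(len(prof)),
            "n_varieties": int(fx["catalog"]["variety_name"].nunique()),
            "match_report": match_report,
            "n_warnings": counter.count,
            "outputs": {name: hashlib.sha256((out_dir / name).read_bytes())
                        .hexdigest() for name in outputs},
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    finally:
        pkg_logger.removeHandler(counter)
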