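"""Variety canonicalisation, cultivation-area allocation, bioregional
climate ranges and regional sensitivity.

Sensitivity asks how close each region's present climate sits to the upper
limit of the historic growing conditions — the *bioregional climate range*
— of its primary grape varieties. Ranges are estimated per variety and
bioclimatic climate group as the cultivation-area-weighted mean ± SD of
each index across the regions growing the variety; the upper limit is
mean + SD. A region whose climate is near (or beyond) those limits is
likely to see its traditional wine style change first, so small margins map
to high sensitivity. The same ranges also say which varieties would move
*closer* to their historic reference under a future scenario — the
"positive effects" share.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GroupBoundaries",
    "canonicalize_varieties",
    "resolve_primary",
    "allocate_cultivation",
    "classify_climate_group",
    "estimate_ranges",
    "overall_range_means",
    "gi_sensitivity",
    "positive_effect_share",
]

_INDICES = ("hi", "cni", "di")


class GroupBoundaries:
    """Class edges for the multicriteria climate grouping.

    Defaults follow the Géoviticulture multicriteria classification:
    Huglin classes at 1500/1800/2100/2400/3000 °C·days, cool-night classes
    at 12/14/18 °C and dryness classes at −100/50/150 mm. Bins are
    right-closed (a value exactly on an edge falls in the lower class);
    values beyond the outermost edges take the terminal class.
    """

    def __init__(self,
                 hi_edges=(1500.0, 1800.0, 2100.0, 2400.0, 3000.0),
                 cni_edges=(12.0, 14.0, 18.0),
                 di_edges=(-100.0, 50.0, 150.0)):
        for name, edges in (("hi", hi_edges), ("cni", cni_edges), ("di", di_edges)):
            e = np.asarray(edges, dtype=float)
            if e.ndim != 1 or len(e) == 0 or np.any(np.diff(e) <= 0):
                raise ValueError(f"{name} class edges must be strictly increasing")
        self.hi_edges = np.asarray(hi_edges, dtype=float)
        self.cni_edges = np.asarray(cni_edges, dtype=float)
        self.di_edges = np.asarray(di_edges, dtype=float)


def canonicalize_varieties(
    table: pd.DataFrame,
    synonyms: pd.DataFrame,
    known_names: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Map variety names to canonical form through country-scoped synonyms.

    ``table`` needs columns ``variety_name`` and ``country``. The synonym
    table (columns ``canonical_name, synonym, country`` and optional
    ``tier``) is consulted tier by tier: names are first looked up in the
    primary list (tier 1), then in the secondary list. Unmatched names are
    retained verbatim and flagged; a name already present in
    ``known_names`` (e.g. the catalogue's canonical inventory) counts as
    matched without lookup.

    Returns the table with ``variety_name`` canonicalised plus a ``matched``
    column, and a report dict with the matched fraction and counts.
    """
    syn = synonyms.copy()
    if "tier" not in syn.columns:
        syn["tier"] = 1
    lookups: list[dict[tuple[str, str], str]] = []
    for tier in sorted(syn["tier"].unique()):
        sub = syn[syn["tier"] == tier]
        conflicts = sub.groupby(["country", "synonym"])["canonical_name"].nunique()
        bad = conflicts[conflicts > 1]
        if len(bad):
            raise ValueError(
                "conflicting synonym targets within a country: "
                + ", ".join(f"{c}/{s}" for c, s in bad.index))
        lookups.append({(r.country, r.synonym): r.canonical_name
                        for r in sub.itertuples()})
    out = table.copy()
    names, matched = [], []
    for row in table.itertuples():
        name = row.variety_name
        if known_names is not None and name in known_names:
            names.append(name)
            matched.append(True)
            continue
        hit = None
        for lut in lookups:  # primary list first, then secondary
            hit = lut.get((row.country, name))
            if hit is not None:
                break
        if hit is None:
            names.append(name)
            matched.append(False)
        else:
            names.append(hit)
            matched.append(True)
    out["variety_name"] = names
    out["matched"] = matched
    n_unmatched = int(len(matched) - sum(matched))
    if n_unmatched:
        logger.warning("%d variety mentions could not be matched", n_unmatched)
    report = {
        "n_rows": len(table),
        "n_matched": int(sum(matched)),
        "n_unmatched": n_unmatched,
        "matched_fraction": float(sum(matched) / len(matched)) if len(matched) else 1.0,
    }
    return out, report


def resolve_primary(catalog: pd.DataFrame) -> pd.DataFrame:
    """Apply the primary-variety fallback rule per region.

    Regions with at least one explicitly primary variety keep their split;
    regions whose specification names no primary variety have all their
    authorised varieties promoted to primary.
    """
    if catalog.empty:
        raise ValueError("empty variety catalogue")
    out = catalog.copy()
    role = out.get("role")
    if role is None:
        out["role"] = "primary"
        return out
    out["role"] = out["role"].fillna("")
    for rid, grp in out.groupby("region_id"):
        if len(grp) == 0:
            raise ValueError(f"region {rid!r} has an empty variety list")
        if not (grp["role"] == "primary").any():
            out.loc[grp.index, "role"] = "primary"
    return out


def allocate_cultivation(
    cultivation: pd.DataFrame,
    macro_map: pd.DataFrame,
    regions: pd.DataFrame,
    catalog: pd.DataFrame,
) -> pd.DataFrame:
    """Distribute cultivation areas onto regions.

    Rows addressed at PDO level pass through. Rows addressed at
    macro-region level are split among the macro's member regions that
    authorise the variety, proportionally to each member's vineyard area;
    the split conserves the macro total. A macro-level variety authorised
    by no member is dropped with a warning.
    """
    members = macro_map.groupby("macro_id")["region_id"].apply(list).to_dict() \
        if len(macro_map) else {}
    vineyard = dict(zip(regions["region_id"], regions["vineyard_area_ha"]))
    authorized = set(zip(catalog["region_id"], catalog["variety_name"]))
    rows = []
    n_dropped = 0
    for row in cultivation.itertuples():
        if row.unit_level == "pdo":
            rows.append({"region_id": row.unit_id, "variety_name": row.variety_name,
                         "area_ha": float(row.area_ha)})
            continue
        if row.unit_id not in members:
            raise KeyError(f"macro-region {row.unit_id!r} missing from macro map")
        auth = [r for r in members[row.unit_id]
                if (r, row.variety_name) in authorized]
        if not auth:
            n_dropped += 1
            logger.warning("variety %s authorised nowhere in macro %s; "
                           "dropping %.1f ha", row.variety_name, row.unit_id,
                           row.area_ha)
            continue
        w = np.array([vineyard[r] for r in auth], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"macro {row.unit_id!r}: zero total vineyard area "
                             "among authorising members")
        for r, share in zip(auth, w / w.sum()):
            rows.append({"region_id": r, "variety_name": row.variety_name,
                         "area_ha": float(row.area_ha * share)})
    if n_dropped:
        logger.warning("%d macro-level rows dropped (no authorising member)", n_dropped)
    out = pd.DataFrame(rows, columns=["region_id", "variety_name", "area_ha"])
    return (out.groupby(["region_id", "variety_name"], as_index=False)["area_ha"]
            .sum())


def classify_climate_group(records: pd.DataFrame,
                           boundaries: GroupBoundaries | None = None) -> pd.DataFrame:
    """Assign each region a climate-group label from its (HI, CNI, DI) triple.

    Each index is binned by its class edges (right-closed); the group is
    the concatenated class triple. The distinct observed triples form the
    climate-group inventory.
    """
    b = boundaries or GroupBoundaries()
    out = records.copy()
    hi_c = np.searchsorted(b.hi_edges, out["hi"].to_numpy(), side="left")
    cni_c = np.searchsorted(b.cni_edges, out["cni"].to_numpy(), side="left")
    di_c = np.searchsorted(b.di_edges, out["di"].to_numpy(), side="left")
    out["hi_class"] = hi_c
    out["cni_class"] = cni_c
    out["di_class"] = di_c
    out["group_id"] = [f"HI{a}-CN{b_}-DI{c}" for a, b_, c in zip(hi_c, cni_c, di_c)]
    return out


def estimate_ranges(
    regional: pd.DataFrame,
    allocation: pd.DataFrame,
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Cultivation-area-weighted climate ranges per variety and climate group.

    For every (variety, group, index): the area-weighted mean over
    cultivating regions, the area-weighted (population-style) standard
    deviation, and the upper limit mean + SD. A variety cultivated in a
    single region of a group has SD 0 and upper limit equal to the mean.
    """
    merged = (allocation
              .merge(regional[["region_id", *(_INDICES)]], on="region_id")
              .merge(groups[["region_id", "group_id"]], on="region_id"))
    rows = []
    for (variety, group_id), grp in merged.groupby(["variety_name", "group_id"]):
        w = grp["area_ha"].to_numpy(dtype=float)
        if w.sum() <= 0:
            logger.warning("variety %s has zero area in group %s; excluded",
                           variety, group_id)
            continue
        wn = w / w.sum()
        for index in _INDICES:
            x = grp[index].to_numpy(dtype=float)
            mean = float(np.sum(wn * x))
            sd = float(np.sqrt(np.sum(wn * (x - mean) ** 2)))
            rows.append({
                "variety": variety, "group_id": group_id, "index": index,
                "weighted_mean": mean, "weighted_sd": sd,
                "upper_limit": mean + sd, "total_area": float(w.sum()),
            })
    return pd.DataFrame(rows)


def overall_range_means(ranges: pd.DataFrame) -> pd.DataFrame:
    """Collapse group-wise range means to one per (variety, index).

    Group means are combined weighted by each group's total cultivation
    area — the across-group area-weighted centre of a variety's historic
    climate, used by the parameter-recovery diagnostics.
    """
    def _combine(grp: pd.DataFrame) -> float:
        w = grp["total_area"].to_numpy(dtype=float)
        return float(np.sum(w * grp["weighted_mean"].to_numpy()) / w.sum())

    rows = [
        {"variety": v, "index": idx, "mean": _combine(grp)}
        for (v, idx), grp in ranges.groupby(["variety", "index"])
    ]
    return pd.DataFrame(rows)


def _standardize(values: np.ndarray, strategy: str) -> np.ndarray:
    if strategy == "zscore":
        sd = values.std()
        return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    if strategy == "minmax":
        lo, hi = values.min(), values.max()
        return (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    if strategy == "raw":
        return values
    raise ValueError(f"unknown standardization strategy {strategy!r}")


def _margin_table(regional: pd.DataFrame, ranges: pd.DataFrame,
                  allocation: pd.DataFrame, catalog: pd.DataFrame,
                  groups: pd.DataFrame) -> pd.DataFrame:
    """Per (region, primary variety): cultivation area and per-index margin
    upper_limit − current value, for varieties with a range in the region's
    group."""
    primary = resolve_primary(catalog)
    primary = primary[primary["role"] == "primary"]
    alloc = allocation.merge(
        primary[["region_id", "variety_name"]], on=["region_id", "variety_name"])
    alloc = alloc[alloc["area_ha"] > 0]
    wide = ranges.pivot_table(index=["variety", "group_id"], columns="index",
                              values="upper_limit")
    refs = ranges.pivot_table(index=["variety", "group_id"], columns="index",
                              values="weighted_mean")
    merged = (alloc
              .merge(regional[["region_id", *(_INDICES)]], on="region_id")
              .merge(groups[["region_id", "group_id"]], on="region_id"))
    rows = []
    for row in merged.itertuples():
        key = (row.variety_name, row.group_id)
        if key not in wide.index:
            continue
        lim = wide.loc[key]
        ref = refs.loc[key]
        rec = {"region_id": row.region_id, "variety_name": row.variety_name,
               "area_ha": row.area_ha}
        for index in _INDICES:
            rec[f"margin_{index}"] = float(lim[index] - getattr(row, index))
            rec[f"ref_{index}"] = float(ref[index])
        rows.append(rec)
    return pd.DataFrame(rows)


def gi_sensitivity(
    regional: pd.DataFrame,
    ranges: pd.DataFrame,
    allocation: pd.DataFrame,
    catalog: pd.DataFrame,
    groups: pd.DataFrame,
    standardization: str = "zscore",
) -> pd.DataFrame:
    """Score each region's sensitivity in [0, 1].

    Per primary variety the margin to the upper range limit is computed for
    each index, standardised per index across all (region, variety) pairs
    so that °C·days, °C and mm are commensurable, averaged over the three
    indices and negated (a small or negative margin means high
    sensitivity). Regional scores are the cultivation-area-weighted mean
    over primary varieties, min-max scaled across regions.
    """
    margins = _margin_table(regional, ranges, allocation, catalog, groups)
    if margins.empty:
        raise ValueError("no (region, primary variety) pair has a climate range")
    std = np.column_stack([
        _standardize(margins[f"margin_{index}"].to_numpy(dtype=float), standardization)
        for index in _INDICES
    ])
    margins["score"] = -std.mean(axis=1)
    rows = []
    for rid, grp in margins.groupby("region_id"):
        w = grp["area_ha"].to_numpy(dtype=float)
        rows.append({"region_id": rid,
                     "raw_sensitivity": float(np.sum(w * grp["score"]) / w.sum())})
    out = pd.DataFrame(rows)
    missing = set(regional["region_id"]) - set(out["region_id"])
    if missing:
        raise ValueError("regions without any primary variety range: "
                         f"{sorted(missing)}")
    from .exposure import minmax_scale

    out["sensitivity"] = minmax_scale(out["raw_sensitivity"].to_numpy())
    return out


def positive_effect_share(
    ranges: pd.DataFrame,
    present: pd.DataFrame,
    future: pd.DataFrame,
    allocation: pd.DataFrame,
    catalog: pd.DataFrame,
    groups: pd.DataFrame,
    benefit_rule: str = "mean_deviation",
    weighting: str = "area",
) -> pd.DataFrame:
    """Area-weighted share of primary varieties that move closer to their
    historic reference under the future scenario.

    The reference is the present-day group-wise weighted mean per variety
    and index. Deviations are standardised by the across-region SD of each
    present index so the three indices contribute comparably. Under
    ``mean_deviation`` a variety benefits iff its mean absolute
    standardised deviation shrinks strictly; ``majority`` requires at least
    two of the three indices to move closer. Ties count as not benefiting.
    """
    if benefit_rule not in ("mean_deviation", "majority"):
        raise ValueError(f"unknown benefit rule {benefit_rule!r}")
    if weighting not in ("area", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    margins = _margin_table(present, ranges, allocation, catalog, groups)
    if margins.empty:
        raise ValueError("no (region, primary variety) pair has a climate range")
    fut = future.set_index("region_id")
    missing = set(margins["region_id"]) - set(fut.index)
    if missing:
        raise ValueError(f"missing future records for regions: {sorted(missing)}")
    pres = present.set_index("region_id")
    scale = {index: (pres[index].std() or 1.0) for index in _INDICES}
    rows = []
    for row in margins.itertuples():
        closer = []
        devs_p, devs_f = [], []
        for index in _INDICES:
            ref = getattr(row, f"ref_{index}")
            dp = abs(pres.loc[row.region_id, index] - ref) / scale[index]
            df_ = abs(fut.loc[row.region_id, index] - ref) / scale[index]
            devs_p.append(dp)
            devs_f.append(df_)
            closer.append(df_ < dp)
        if benefit_rule == "mean_deviation":
            benefits = float(np.mean(devs_f)) < float(np.mean(devs_p))
        else:
            benefits = sum(closer) >= 2
        rows.append({"region_id": row.region_id, "area_ha": row.area_ha,
                     "benefits": benefits})
    df = pd.DataFrame(rows)
    out = []
    for rid, grp in df.groupby("region_id"):
        w = (grp["area_ha"].to_numpy(dtype=float) if weighting == "area"
             else np.ones(len(grp)))
        out.append({"region_id": rid,
                    "positive_share": float(np.sum(w * grp["benefits"]) / w.sum())})
    return pd.DataFrame(out)
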