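"""Canonicalisation, allocation, climate ranges, sensitivity and benefits."""

import logging

import numpy as np
import pandas as pd
import pytest

from vitivuln import varieties as vmod
from vitivuln.varieties import (GroupBoundaries, allocate_cultivation,
                                canonicalize_varieties, classify_climate_group,
                                estimate_ranges, gi_sensitivity,
                                positive_effect_share, resolve_primary)


class TestCanonicalize:
    def test_country_scoped_synonym_mapped(self):
        table = pd.DataFrame({"variety_name": ["Spätburgunder"], "country": ["DE"]})
        syn = pd.DataFrame({"canonical_name": ["Pinot Noir"],
                            "synonym": ["Spätburgunder"], "country": ["DE"]})
        out, report = canonicalize_varieties(table, syn)
        assert out.loc[0, "variety_name"] == "Pinot Noir"
        assert report["matched_fraction"] == 1.0

    def test_synonym_from_other_country_not_applied(self):
        table = pd.DataFrame({"variety_name": ["Spätburgunder"], "country": ["FR"]})
        syn = pd.DataFrame({"canonical_name": ["Pinot Noir"],
                            "synonym": ["Spätburgunder"], "country": ["DE"]})
        out, report = canonicalize_varieties(table, syn)
        assert out.loc[0, "variety_name"] == "Spätburgunder"
        assert report["n_unmatched"] == 1

    def test_primary_list_consulted_before_secondary(self):
        table = pd.DataFrame({"variety_name": ["Alias"], "country": ["IT"]})
        syn = pd.DataFrame({
            "canonical_name": ["FromPrimary", "FromSecondary"],
            "synonym": ["Alias", "Alias"], "country": ["IT", "IT"],
            "tier": [1, 2]})
        out, _ = canonicalize_varieties(table, syn)
        assert out.loc[0, "variety_name"] == "FromPrimary"

    def test_unmatched_retained_and_flagged(self):
        table = pd.DataFrame({"variety_name": ["Mystery", "Known"],
                              "country": ["IT", "IT"]})
        syn = pd.DataFrame({"canonical_name": [], "synonym": [], "country": []})
        out, report = canonicalize_varieties(table, syn, known_names={"Known"})
        assert out.loc[0, "variety_name"] == "Mystery"
        assert not out.loc[0, "matched"]
        assert out.loc[1, "matched"]
        assert report["matched_fraction"] == 0.5

    def test_conflicting_targets_rejected(self):
        table = pd.DataFrame({"variety_name": ["X"], "country": ["IT"]})
        syn = pd.DataFrame({"canonical_name": ["A", "B"],
                            "synonym": ["X", "X"], "country": ["IT", "IT"],
                            "tier": [1, 1]})
        with pytest.raises(ValueError, match="conflicting"):
            canonicalize_varieties(table, syn)

    def test_clean_fixture_fully_matched(self, small_bundle):
        cult = small_bundle["cultivation"].copy()
        regions = small_bundle["regions"].table
        country = dict(zip(regions["region_id"], regions["country"]))
        macro_country = (small_bundle["macro_map"]
                         .merge(regions[["region_id", "country"]], on="region_id")
                         .drop_duplicates("macro_id")
                         .set_index("macro_id")["country"].to_dict())
        cult["country"] = [country[u] if lvl == "pdo" else macro_country[u]
                           for u, lvl in zip(cult["unit_id"], cult["unit_level"])]
        known = set(small_bundle["catalog"]["variety_name"])
        _, report = canonicalize_varieties(cult, small_bundle["synonyms"],
                                           known_names=known)
        assert report["matched_fraction"] == 1.0


class TestResolvePrimary:
    def test_explicit_split_kept(self):
        cat = pd.DataFrame({"region_id": ["A", "A"], "variety_name": ["v1", "v2"],
                            "role": ["primary", "additional"]})
        out = resolve_primary(cat)
        assert list(out["role"]) == ["primary", "additional"]

    def test_unspecified_promotes_all(self):
        cat = pd.DataFrame({"region_id": ["A", "A"], "variety_name": ["v1", "v2"],
                            "role": [None, None]})
        out = resolve_primary(cat)
        assert (out["role"] == "primary").all()

    def test_singleton_region(self):
        cat = pd.DataFrame({"region_id": ["A"], "variety_name": ["v1"],
                            "role": ["additional"]})
        assert resolve_primary(cat).loc[0, "role"] == "primary"

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            resolve_primary(pd.DataFrame(columns=["region_id", "variety_name",
                                                  "role"]))


class TestAllocation:
    regions = pd.DataFrame({"region_id": ["A", "B", "C"],
                            "vineyard_area_ha": [100.0, 300.0, 50.0]})
    catalog = pd.DataFrame({"region_id": ["A", "B"],
                            "variety_name": ["v", "v"]})
    macro_map = pd.DataFrame({"macro_id": ["M", "M", "M"],
                              "region_id": ["A", "B", "C"]})

    def test_proportional_macro_split(self):
        cult = pd.DataFrame({"unit_id": ["M"], "unit_level": ["macro"],
                             "variety_name": ["v"], "area_ha": [400.0]})
        out = allocate_cultivation(cult, self.macro_map, self.regions,
                                   self.catalog).set_index("region_id")
        # C does not authorise v; A and B split 400 as 100:300
        assert out.loc["A", "area_ha"] == pytest.approx(100.0)
        assert out.loc["B", "area_ha"] == pytest.approx(300.0)
        assert "C" not in out.index

    def test_single_authorising_member_gets_all(self):
        catalog = pd.DataFrame({"region_id": ["B"], "variety_name": ["v"]})
        cult = pd.DataFrame({"unit_id": ["M"], "unit_level": ["macro"],
                             "variety_name": ["v"], "area_ha": [400.0]})
        out = allocate_cultivation(cult, self.macro_map, self.regions, catalog)
        assert out.loc[0, "area_ha"] == pytest.approx(400.0)

    def test_pdo_rows_pass_through(self):
        cult = pd.DataFrame({"unit_id": ["A"], "unit_level": ["pdo"],
                             "variety_name": ["v"], "area_ha": [42.0]})
        out = allocate_cultivation(cult, self.macro_map, self.regions,
                                   self.catalog)
        assert out.loc[0, "area_ha"] == 42.0

    def test_unauthorised_macro_variety_dropped_with_warning(self, caplog):
        cult = pd.DataFrame({"unit_id": ["M"], "unit_level": ["macro"],
                             "variety_name": ["ghost"], "area_ha": [10.0]})
        with caplog.at_level(logging.WARNING, logger="vitivuln.varieties"):
            out = allocate_cultivation(cult, self.macro_map, self.regions,
                                       self.catalog)
        assert out.empty
        assert any("authorised nowhere" in r.message for r in caplog.records)

    def test_zero_vineyard_area_rejected(self):
        regions = self.regions.assign(vineyard_area_ha=[0.0, 0.0, 50.0])
        cult = pd.DataFrame({"unit_id": ["M"], "unit_level": ["macro"],
                             "variety_name": ["v"], "area_ha": [400.0]})
        with pytest.raises(ValueError, match="zero total vineyard area"):
            allocate_cultivation(cult, self.macro_map, regions, self.catalog)

    def test_unknown_macro_rejected(self):
        cult = pd.DataFrame({"unit_id": ["ZZ"], "unit_level": ["macro"],
                             "variety_name": ["v"], "area_ha": [1.0]})
        with pytest.raises(KeyError):
            allocate_cultivation(cult, self.macro_map, self.regions,
                                 self.catalog)

    def test_area_conservation_on_fixture(self, small_bundle):
        """Macro-level totals are exactly conserved through the split."""
        cult = small_bundle["cultivation"].copy()
        regions = small_bundle["regions"].table
        country = dict(zip(regions["region_id"], regions["country"]))
        macro_country = (small_bundle["macro_map"]
                         .merge(regions[["region_id", "country"]], on="region_id")
                         .drop_duplicates("macro_id")
                         .set_index("macro_id")["country"].to_dict())
        cult["country"] = [country[u] if lvl == "pdo" else macro_country[u]
                           for u, lvl in zip(cult["unit_id"], cult["unit_level"])]
        cult, _ = canonicalize_varieties(
            cult, small_bundle["synonyms"],
            known_names=set(small_bundle["catalog"]["variety_name"]))
        catalog = resolve_primary(small_bundle["catalog"])
        out = allocate_cultivation(cult, small_bundle["macro_map"], regions,
                                   catalog)
        assert out["area_ha"].sum() == pytest.approx(cult["area_ha"].sum(),
                                                     rel=1e-9)


class TestClimateGroups:
    def test_cool_region_lands_in_lowest_hi_class(self):
        rec = pd.DataFrame({"region_id": ["A"], "hi": [1200.0], "cni": [10.0],
                            "di": [160.0]})
        out = classify_climate_group(rec)
        assert out.loc[0, "hi_class"] == 0

    def test_edge_value_falls_in_lower_bin(self):
        rec = pd.DataFrame({"region_id": ["A", "B"], "hi": [1500.0, 1500.0001],
                            "cni": [12.0, 12.0], "di": [50.0, 50.0]})
        out = classify_climate_group(rec)
        assert out.loc[0, "hi_class"] == 0
        assert out.loc[1, "hi_class"] == 1

    def test_same_bins_same_group(self):
        rec = pd.DataFrame({"region_id": ["A", "B"], "hi": [1900.0, 2050.0],
                            "cni": [13.0, 13.5], "di": [60.0, 100.0]})
        out = classify_climate_group(rec)
        assert out.loc[0, "group_id"] == out.loc[1, "group_id"]

    def test_beyond_terminal_edges_takes_terminal_class(self):
        rec = pd.DataFrame({"region_id": ["A"], "hi": [4000.0], "cni": [25.0],
                            "di": [-500.0]})
        out = classify_climate_group(rec)
        assert out.loc[0, "hi_class"] == 5
        assert out.loc[0, "cni_class"] == 3
        assert out.loc[0, "di_class"] == 0

    def test_nonincreasing_edges_rejected(self):
        with pytest.raises(ValueError):
            GroupBoundaries(hi_edges=(1500.0, 1500.0))


class TestRanges:
    def test_weighted_moments_hand_oracle(self):
        regional = pd.DataFrame({"region_id": ["A", "B"],
                                 "hi": [1800.0, 2000.0],
                                 "cni": [13.0, 13.0], "di": [60.0, 60.0]})
        groups = classify_climate_group(regional).assign(group_id="G")
        alloc = pd.DataFrame({"region_id": ["A", "B"],
                              "variety_name": ["v", "v"],
                              "area_ha": [100.0, 300.0]})
        out = estimate_ranges(regional, alloc, groups)
        hi = out[out["index"] == "hi"].iloc[0]
        assert hi["weighted_mean"] == pytest.approx(1950.0)
        assert hi["weighted_sd"] == pytest.approx(86.60, abs=0.01)
        assert hi["upper_limit"] == pytest.approx(2036.60, abs=0.01)

    def test_equal_areas_match_unweighted_oracle(self):
        rng = np.random.default_rng(0)
        his = rng.uniform(1850.0, 2050.0, size=6)
        regional = pd.DataFrame({"region_id": [f"R{i}" for i in range(6)],
                                 "hi": his, "cni": np.full(6, 13.0),
                                 "di": np.full(6, 60.0)})
        groups = classify_climate_group(regional)
        alloc = pd.DataFrame({"region_id": regional["region_id"],
                              "variety_name": "v", "area_ha": 10.0})
        out = estimate_ranges(regional, alloc, groups)
        hi = out[out["index"] == "hi"].set_index("group_id")
        # all six regions share the group (same bins by construction)
        assert len(hi) == 1
        assert hi["weighted_mean"].iloc[0] == pytest.approx(his.mean())
        assert hi["weighted_sd"].iloc[0] == pytest.approx(his.std())  # population SD


def _three_region_setup(margins_hi=(50.0, 200.0, 125.0)):
    """Regions differing only in HI, one variety per region, one group."""
    n = len(margins_hi)
    upper = 2000.0
    regional = pd.DataFrame({
        "region_id": [f"R{i}" for i in range(n)],
        "hi": [upper - m for m in margins_hi],
        "cni": np.full(n, 13.0), "di": np.full(n, 60.0)})
    groups = classify_climate_group(regional).assign(group_id="G", hi_class=0)
    catalog = pd.DataFrame({"region_id": regional["region_id"],
                            "variety_name": [f"v{i}" for i in range(n)],
                            "role": "primary"})
    alloc = pd.DataFrame({"region_id": regional["region_id"],
                          "variety_name": catalog["variety_name"],
                          "area_ha": 100.0})
    rows = []
    for i in range(n):
        for index, val in (("hi", upper), ("cni", 13.0), ("di", 60.0)):
            rows.append({"variety": f"v{i}", "group_id": "G", "index": index,
                         "weighted_mean": val, "weighted_sd": 0.0,
                         "upper_limit": val, "total_area": 100.0})
    ranges = pd.DataFrame(rows)
    return regional, ranges, alloc, catalog, groups


class TestSensitivity:
    def test_two_point_minmax_of_negated_margins(self):
        regional, ranges, alloc, catalog, groups = _three_region_setup((50.0, 200.0))
        out = gi_sensitivity(regional, ranges, alloc, catalog, groups) \
            .set_index("region_id")
        assert out.loc["R0", "sensitivity"] == pytest.approx(1.0)
        assert out.loc["R1", "sensitivity"] == pytest.approx(0.0)

    def test_smaller_margin_means_higher_sensitivity(self):
        regional, ranges, alloc, catalog, groups = _three_region_setup(
            (10.0, 300.0, 150.0))
        out = gi_sensitivity(regional, ranges, alloc, catalog, groups) \
            .set_index("region_id")
        assert out.loc["R0", "sensitivity"] > out.loc["R2", "sensitivity"] \
            > out.loc["R1", "sensitivity"]

    def test_enlarging_upper_limits_never_raises_sensitivity(self):
        regional, ranges, alloc, catalog, groups = _three_region_setup(
            (25.0, 250.0, 90.0))
        base = gi_sensitivity(regional, ranges, alloc, catalog, groups) \
            .set_index("region_id")["raw_sensitivity"]
        wider = ranges.assign(upper_limit=ranges["upper_limit"] + 100.0)
        relaxed = gi_sensitivity(regional, wider, alloc, catalog, groups) \
            .set_index("region_id")["raw_sensitivity"]
        assert (relaxed <= base + 1e-9).all()

    def test_area_weight_shifts_region_score(self):
        # two varieties in one region with different margins: weighting the
        # tighter-margin variety more raises the pre-scaling score
        regional = pd.DataFrame({"region_id": ["A", "B"], "hi": [1950.0, 1800.0],
                                 "cni": [13.0, 13.0], "di": [60.0, 60.0]})
        groups = classify_climate_group(regional).assign(group_id="G")
        catalog = pd.DataFrame({"region_id": ["A", "A", "B"],
                                "variety_name": ["tight", "loose", "loose"],
                                "role": "primary"})
        rows = []
        for v, lim in (("tight", 1960.0), ("loose", 2200.0)):
            for index, val in (("hi", lim), ("cni", 14.0), ("di", 80.0)):
                rows.append({"variety": v, "group_id": "G", "index": index,
                             "weighted_mean": val, "weighted_sd": 0.0,
                             "upper_limit": val, "total_area": 1.0})
        ranges = pd.DataFrame(rows)

        def region_a_raw(tight_area):
            alloc = pd.DataFrame({
                "region_id": ["A", "A", "B"],
                "variety_name": ["tight", "loose", "loose"],
                "area_ha": [tight_area, 100.0, 100.0]})
            return gi_sensitivity(regional, ranges, alloc, catalog, groups) \
                .set_index("region_id").loc["A", "raw_sensitivity"]

        assert region_a_raw(300.0) > region_a_raw(30.0)

    def test_region_without_ranged_primary_rejected(self):
        regional, ranges, alloc, catalog, groups = _three_region_setup()
        with pytest.raises(ValueError):
            gi_sensitivity(regional, ranges.iloc[0:0], alloc, catalog, groups)


class TestPositiveEffects:
    def test_identical_future_ties_to_not_benefiting(self):
        regional, ranges, alloc, catalog, groups = _three_region_setup()
        out = positive_effect_share(ranges, regional, regional.copy(), alloc,
                                    catalog, groups)
        assert (out["positive_share"] == 0.0).all()

    def test_closer_to_reference_benefits(self):
        # present HI 200 below the reference, future only 50 below
        regional = pd.DataFrame({"region_id": ["A", "B"],
                                 "hi": [1800.0, 1700.0],
                                 "cni": [13.0, 13.0], "di": [60.0, 60.0]})
        future = regional.assign(hi=[1950.0, 1700.0])
        groups = classify_climate_group(regional).assign(group_id="G")
        catalog = pd.DataFrame({"region_id": ["A", "B"],
                                "variety_name": ["v", "v"], "role": "primary"})
        alloc = pd.DataFrame({"region_id": ["A", "B"], "variety_name": "v",
                              "area_ha": 100.0})
        rows = [{"variety": "v", "group_id": "G", "index": idx,
                 "weighted_mean": ref, "weighted_sd": 0.0, "upper_limit": ref,
                 "total_area": 200.0}
                for idx, ref in (("hi", 2000.0), ("cni", 13.0), ("di", 60.0))]
        out = positive_effect_share(pd.DataFrame(rows), regional, future,
                                    alloc, catalog, groups) \
            .set_index("region_id")
        assert out.loc["A", "positive_share"] == 1.0
        assert out.loc["B", "positive_share"] == 0.0

    def test_share_bounds(self, small_bundle, small_regional):
        from vitivuln import bioclim as bio

        clim = small_bundle["climate"]
        regions = small_bundle["regions"]
        name = next(iter(clim.scenarios))
        fut = bio.regional_bioclim(bio.bioclim_dataset(clim.scenarios[name]),
                                   regions.membership)
        regional = small_regional
        cult = small_bundle["cultivation"].copy()
        country = dict(zip(regions.table["region_id"], regions.table["country"]))
        macro_country = (small_bundle["macro_map"]
                         .merge(regions.table[["region_id", "country"]],
                                on="region_id")
                         .drop_duplicates("macro_id")
                         .set_index("macro_id")["country"].to_dict())
        cult["country"] = [country[u] if lvl == "pdo" else macro_country[u]
                           for u, lvl in zip(cult["unit_id"], cult["unit_level"])]
        cult, _ = canonicalize_varieties(
            cult, small_bundle["synonyms"],
            known_names=set(small_bundle["catalog"]["variety_name"]))
        catalog = resolve_primary(small_bundle["catalog"])
        alloc = allocate_cultivation(cult, small_bundle["macro_map"],
                                     regions.table, catalog)
        groups = classify_climate_group(regional)
        ranges = estimate_ranges(regional, alloc, groups)
        out = positive_effect_share(ranges, regional, fut, alloc, catalog, groups)
        assert out["positive_share"].between(0.0, 1.0).all()

    def test_unknown_strategy_rejected(self):
        regional, ranges, alloc, catalog, groups = _three_region_setup()
        with pytest.raises(ValueError):
            positive_effect_share(ranges, regional, regional, alloc, catalog,
                                  groups, benefit_rule="bogus")
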