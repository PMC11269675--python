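# vitivuln

Climate-change vulnerability assessment for winegrowing regions
(geographical indications, GIs) under the IPCC
exposure–sensitivity–adaptive-capacity framework, with a seeded
synthetic-data generator for testing and method development.

Wine GIs — in the EU, most strictly the Protected Designations of Origin
(PDO) — bind a wine's identity to a place, its climate and a fixed roster
of authorized grape varieties. Climate change strains that bond from three
directions at once: the regional climate itself shifts (**exposure**), the
shift pushes conditions toward the upper edge of the historic growing
conditions of the region's traditional varieties (**sensitivity**), and
regions differ widely in the socioeconomic and biophysical resources they
can mobilise to adapt (**adaptive capacity**). `vitivuln` implements the
full index-based pipeline that turns gridded monthly climate, region
boundaries, variety registers, cultivation areas and an indicator table
into a per-region vulnerability classification.

## The model

**Bioclimatic indices** (per grid cell, monthly climatologies, Northern
Hemisphere, growing season April–September):

- Huglin heliothermal index
  `HI = Σ_Apr..Sep max(0, ((T_mean − 10) + (T_max − 10))/2) · N · K(lat)`
  (°C·days), with `K` the day-length coefficient;
- Cool Night Index `CNI` = mean September minimum temperature (°C);
- Dryness Index `DI` = end-of-September soil-water reserve of Riou's
  potential water balance, starting from `Wo = 200 mm` and losing vine
  transpiration `Tv = k·ETP` and bare-soil evaporation
  `Es = (ETP/N)(1−k)·JPm`, capped at `Wo` (mm). PET defaults to a
  Hargreaves temperature-only estimate.

**Exposure** `E`: per-region change of each index between the present and
a future scenario period, oriented so warming (ΔHI, ΔCNI > 0) and drying
(−ΔDI > 0) count as adverse, min–max scaled across regions and averaged.

**Sensitivity** `S`: per variety and climate group (regions binned by
multicriteria HI/CNI/DI classes), the *bioregional climate range* is the
cultivation-area-weighted mean ± SD of each index over the regions growing
the variety; the margin between a region's present climate and the upper
limits of its primary varieties' ranges — standardised, negated,
area-weighted, min–max scaled — gives `S`. The same ranges yield the share
of varieties a future scenario moves *closer* to their historic reference
(positive effects).

**Adaptive capacity** `AC` (15 indicators over social / physical / natural
/ human / financial dimensions):

```
AC_i = clamp((X − Q5) / (Q95 − Q5), 0, 1)       AC = (1/n) Σ_i AC_i
```

with lower-is-better indicators inverted, equal weights by default, and
optional weights from an AHP pairwise-comparison matrix (accepted only if
the consistency ratio CR < 0.10).

**Integrated vulnerability**: `E`, `S`, `AC` are cut into tertiles
(low/moderate/high); adverse conditions are high `E`, high `S`, low `AC`.
All three adverse ⇒ *very high* (group 6); exactly two ⇒ *high* (groups
3/4/5 by the adverse pair {E,S}/{E,AC}/{S,AC}); at least two favourable ⇒
*low* (group 1); else *moderate* (group 2).

## Worked example

The pipeline runs end-to-end on a self-generated synthetic study:

```sh
cat > run.toml <<'EOF'
input_dir = "fixture"
out_dir = "out"
scenario = "ssp370"
seed = 42
simulate = true
EOF
vitivuln run-all --config run.toml
```

```
run complete: 60 regions, 0 warnings, config hash a465a9f02d3d0cbc
```

`out/vulnerability.csv` then holds one row per region with its three
scores, tertile classes, level and group:

```
region_id  exposure  sensitivity    ac    level  group
     R001     0.470        0.820 0.577 moderate      2
     R002     0.731        0.526 0.523 moderate      2
     R003     0.453        0.895 0.606      low      1
     R004     0.453        0.451 0.222      low      1
     R005     0.708        0.838 0.694     high      3
```

R005, for instance, combines high exposure and high sensitivity — it faces
the strongest climatic pressure — but its adaptive capacity is in the top
tertile, so it lands in group 3 (high vulnerability, resources to adapt)
rather than group 6. Across this study the levels split 17 low / 33
moderate / 8 high / 2 very high, and `out/country_summary.csv` gives the
per-country percentages. Intermediate stages (`bioclim_regions.csv`,
`exposure.csv`, `ranges.csv`, `sensitivity.csv`, `capacity.csv`,
`ahp_report.json`) are written alongside and can be recomputed
independently via the `vitivuln bioclim | exposure | ranges | sensitivity |
capacity | ahp | vulnerability` subcommands.

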