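"""Integrated vulnerability classification.

Each region's exposure (E), sensitivity (S) and adaptive capacity (AC)
scores are cut into tertile classes (low / moderate / high at the 33rd and
66th percentiles across regions). A rule set maps the class triple to four
vulnerability levels — adverse conditions are high E, high S and *low* AC:

* **very high** — all three adverse,
* **high** — exactly two adverse,
* **low** — at least two favourable (low E, low S, high AC),
* **moderate** — everything else,

and to six groups: group 6 is the very-high level; groups 3/4/5 partition
the high level by which pair of indicators is adverse ({E,S}, {E,AC},
{S,AC}); groups 1 and 2 are the low and moderate levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "tertile_classes",
    "vulnerability_level",
    "vulnerability_group",
    "assemble_profiles",
    "LEVELS",
]

LEVELS = ("low", "moderate", "high", "very_high")
_CLASSES = ("low", "moderate", "high")


def tertile_classes(values) -> list[str]:
    """Cut a score vector into low/moderate/high at the 33rd/66th percentiles.

    Linear-interpolation percentiles; ties on a cut resolve downward
    (v <= q33 -> low, v <= q66 -> moderate, else high). All-equal input
    puts every region in the low class.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("tertile classes need at least 3 regions")
    q33, q66 = np.percentile(x, [100.0 / 3.0, 200.0 / 3.0])
    return ["low" if v <= q33 else ("moderate" if v <= q66 else "high")
            for v in x]


def _adverse(e_class: str, s_class: str, ac_class: str) -> tuple[bool, bool, bool]:
    return e_class == "high", s_class == "high", ac_class == "low"


def _favorable(e_class: str, s_class: str, ac_class: str) -> tuple[bool, bool, bool]:
    return e_class == "low", s_class == "low", ac_class == "high"


def vulnerability_level(e_class: str, s_class: str, ac_class: str) -> str:
    """Map a tertile class triple to one of the four vulnerability levels.

    Precedence: very_high before high, then low, then moderate — which
    makes the rule set a partition of all 27 class triples.
    """
    for c in (e_class, s_class, ac_class):
        if c not in _CLASSES:
            raise ValueError(f"invalid tertile class {c!r}")
    n_adverse = sum(_adverse(e_class, s_class, ac_class))
    if n_adverse == 3:
        return "very_high"
    if n_adverse == 2:
        return "high"
    if sum(_favorable(e_class, s_class, ac_class)) >= 2:
        return "low"
    return "moderate"


def vulnerability_group(e_class: str, s_class: str, ac_class: str) -> int:
    """Map a tertile class triple to one of the six region groups.

    6 = very-high level; within the high level, 3 / 4 / 5 by the adverse
    pair {E,S} / {E,AC} / {S,AC}; 2 = moderate level; 1 = low level.
    """
    level = vulnerability_level(e_class, s_class, ac_class)
    if level == "very_high":
        return 6
    if level == "high":
        adv_e, adv_s, adv_ac = _adverse(e_class, s_class, ac_class)
        if adv_e and adv_s:
            return 3
        if adv_e and adv_ac:
            return 4
        return 5  # adv_s and adv_ac
    return 2 if level == "moderate" else 1


def assemble_profiles(
    exposure: pd.DataFrame,
    sensitivity: pd.DataFrame,
    capacity: pd.DataFrame,
    regions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Join the three score tables and classify every region.

    Inputs must cover identical region-id sets (columns ``region_id`` plus
    ``exposure`` / ``sensitivity`` / ``ac``). Returns the profile table
    (scores, tertile classes, level, group) and — when a region table with
    countries is supplied — a per-country summary with the percentage of
    regions at each level.
    """
    ids = [set(t["region_id"]) for t in (exposure, sensitivity, capacity)]
    if not (ids[0] == ids[1] == ids[2]):
        missing = (ids[0] | ids[1] | ids[2]) - (ids[0] & ids[1] & ids[2])
        raise ValueError(f"region sets differ across inputs: {sorted(missing)}")
    prof = (exposure[["region_id", "exposure"]]
            .merge(sensitivity[["region_id", "sensitivity"]], on="region_id")
            .merge(capacity[["region_id", "ac"]], on="region_id"))
    prof["e_class"] = tertile_classes(prof["exposure"])
    prof["s_class"] = tertile_classes(prof["sensitivity"])
    prof["ac_class"] = tertile_classes(prof["ac"])
    prof["level"] = [vulnerability_level(e, s, a) for e, s, a in
                     zip(prof["e_class"], prof["s_class"], prof["ac_class"])]
    prof["group"] = [vulnerability_group(e, s, a) for e, s, a in
                     zip(prof["e_class"], prof["s_class"], prof["ac_class"])]
    summary = None
    if regions is not None:
        merged = prof.merge(regions[["region_id", "country"]], on="region_id")
        rows = []
        for country, grp in merged.groupby("country"):
            rec = {"country": country}
            for level in LEVELS:
                rec[f"pct_{level}"] = 100.0 * float((grp["level"] == level).mean())
            rows.append(rec)
        summary = pd.DataFrame(rows)
    return prof, summary
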