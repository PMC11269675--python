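"""Regional climate-change exposure from bioclimatic index deltas.

Exposure ranks regions by the magnitude of projected adverse change in the
three bioclimatic indices between a present and a future period: per-region
deltas (warming raises HI and CNI; drying lowers DI, whose delta is
sign-flipped so drying scores positive) are min-max scaled across regions
and averaged. The ensemble-spread diagnostic measures disagreement among
climate-model members.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["minmax_scale", "adverse_delta", "exposure_index", "ensemble_spread"]


def minmax_scale(values, invert: bool = False) -> np.ndarray:
    """Linear min-max normalisation to [0, 1].

    All-equal input maps to all zeros: with no differential change across
    regions the column contributes no exposure.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot min-max scale an empty sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in min-max scaling input")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    scaled = (x - lo) / (hi - lo)
    return 1.0 - scaled if invert else scaled


def adverse_delta(present: pd.DataFrame, future: pd.DataFrame,
                  mode: str = "signed") -> pd.DataFrame:
    """Per-region index changes oriented so adverse change is positive.

    d_hi = HI_fut − HI_pres, d_cni = CNI_fut − CNI_pres, and
    d_di = DI_pres − DI_fut (a drop in soil-water reserve counts as
    adverse). ``mode='absolute'`` takes magnitudes instead of signed
    adverse-direction changes.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown delta mode {mode!r}")
    p = present.set_index("region_id")
    f = future.set_index("region_id")
    if set(p.index) != set(f.index):
        missing = set(p.index) ^ set(f.index)
        raise ValueError(f"present/future region sets differ: {sorted(missing)}")
    f = f.reindex(p.index)
    out = pd.DataFrame({
        "region_id": p.index,
        "d_hi": (f["hi"] - p["hi"]).to_numpy(),
        "d_cni": (f["cni"] - p["cni"]).to_numpy(),
        "d_di": (p["di"] - f["di"]).to_numpy(),
    })
    if mode == "absolute":
        for c in ("d_hi", "d_cni", "d_di"):
            out[c] = out[c].abs()
    return out.reset_index(drop=True)


def exposure_index(deltas: pd.DataFrame) -> pd.DataFrame:
    """Scale each delta column across regions and average into exposure.

    Returns region_id, the raw deltas, the scaled components e_hi/e_cni/e_di
    and their mean ``exposure``, all in [0, 1].
    """
    if len(deltas) < 2:
        warnings.warn("exposure computed over fewer than 2 regions; "
                      "min-max scale is degenerate (all zeros)")
    out = deltas.copy()
    out["e_hi"] = minmax_scale(deltas["d_hi"])
    out["e_cni"] = minmax_scale(deltas["d_cni"])
    out["e_di"] = minmax_scale(deltas["d_di"])
    out["exposure"] = out[["e_hi", "e_cni", "e_di"]].mean(axis=1)
    return out


def ensemble_spread(member_grids: list[xr.Dataset],
                    variables: tuple[str, ...] = ("tas", "pr")) -> xr.Dataset:
    """Per-cell inter-member range and standard deviation.

    A diagnostic of model disagreement: larger spread among ensemble
    members flags cells whose future climate is more uncertain.
    """
    if len(member_grids) < 2:
        raise ValueError("ensemble spread needs at least 2 members")
    out = {}
    for var in variables:
        stack = xr.concat([m[var] for m in member_grids], dim="member")
        out[f"{var}_range"] = stack.max("member") - stack.min("member")
        out[f"{var}_sd"] = stack.std("member")
    return xr.Dataset(out)
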