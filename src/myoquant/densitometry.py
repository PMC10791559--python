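"""Immunoblot densitometry ratio schemes.

Three per-experiment ratio schemes compare a kinase-activated condition (PKA)
with its paired control (CON):

a. ``ratio_pka_con`` — PKA/CON band-intensity ratio of like lanes, optionally
   corrected by Coomassie-blue (CB) loading stain;
b. ``coip_degree`` — [+]IP/WCL ratio (degree of coimmunoprecipitation) per
   condition, and its PKA:CON ratio;
c. ``surface_degree`` — biotinylated/WCL ratio (degree of surface
   biotinylation) per condition, and its PKA:CON ratio.

Band intensities are inputs (gel densitometry itself is upstream).  Within an
experiment the WCL:pulldown loading ratio is a recorded constant (1:20 by
convention); ratios are reported raw since like lanes are compared, with an
optional absolute-recovery correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WCL_TO_PULLDOWN_LOADING = 20.0

REQUIRED_COLUMNS = ("experiment_id", "condition", "lane_kind", "target",
                    "band_intensity")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"band table missing columns: {missing}")
    if (table["band_intensity"] < 0).any():
        raise ValueError("band intensities must be >= 0")


@dataclass
class RatioSummary:
    per_experiment: pd.DataFrame
    mean: float
    se: float
    n: int
    excluded: list[str]


def _summarize(values: pd.Series, excluded: list[str]) -> RatioSummary:
    vals = values.dropna()
    n = len(vals)
    mean = float(vals.mean()) if n else np.nan
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return RatioSummary(values.reset_index(), mean, se, n, excluded)


def _lane_intensity(grp: pd.DataFrame, condition: str, lane_kind: str,
                    use_cb: bool = False) -> float | None:
    sel = grp[(grp["condition"] == condition) & (grp["lane_kind"] == lane_kind)]
    if sel.empty:
        return None
    row = sel.iloc[0]
    val = float(row["band_intensity"])
    if use_cb:
        cb = float(row.get("cb_intensity", np.nan))
        if not np.isfinite(cb) or cb <= 0:
            return None
        val /= cb
    return val


def ratio_pka_con(table: pd.DataFrame, target: str, use_cb: bool = False,
                  lane_kind: str = "WCL") -> RatioSummary:
    """Per-experiment PKA/CON band-intensity ratio, mean ± SE across
    experiments.  With ``use_cb`` each band is first divided by its CB lane."""
    _check_table(table)
    sub = table[table["target"] == target]
    ratios, excluded = {}, []
    for eid, grp in sub.groupby("experiment_id"):
        i_con = _lane_intensity(grp, "CON", lane_kind, use_cb)
        i_pka = _lane_intensity(grp, "PKA", lane_kind, use_cb)
        if i_con is None or i_pka is None:
            excluded.append(f"{eid}: missing lane")
            continue
        if i_con == 0:
            excluded.append(f"{eid}: zero CON denominator")
            ratios[eid] = np.nan
            continue
        ratios[eid] = i_pka / i_con
    for msg in excluded:
        warnings.warn(f"ratio_pka_con[{target}] excluded {msg}")
    return _summarize(pd.Series(ratios, name="ratio", dtype=float), excluded)


def _degree_scheme(table: pd.DataFrame, target: str, pull_kind: str,
                   absolute: bool) -> tuple[pd.DataFrame, RatioSummary]:
    _check_table(table)
    sub = table[table["target"] == target]
    rows, effects, excluded = [], {}, []
    factor = 1.0 / WCL_TO_PULLDOWN_LOADING if absolute else 1.0
    for eid, grp in sub.groupby("experiment_id"):
        degree = {}
        for cond in ("CON", "PKA"):
            wcl = _lane_intensity(grp, cond, "WCL")
            pull = _lane_intensity(grp, cond, pull_kind)
            if wcl is None or pull is None or wcl == 0:
                excluded.append(f"{eid}/{cond}: missing or zero WCL lane")
                degree[cond] = np.nan
            else:
                degree[cond] = pull / wcl * factor
            rows.append({"experiment_id": eid, "condition": cond,
                         "degree": degree[cond]})
        if np.isfinite(degree.get("CON", np.nan)) and degree["CON"] > 0 \
                and np.isfinite(degree.get("PKA", np.nan)):
            effects[eid] = degree["PKA"] / degree["CON"]
        else:
            effects[eid] = np.nan
    for msg in excluded:
        warnings.warn(f"degree[{target}] excluded {msg}")
    summary = _summarize(pd.Series(effects, name="ratio", dtype=float), excluded)
    return pd.DataFrame(rows), summary


def coip_degree(table: pd.DataFrame, target: str,
                absolute: bool = False) -> tuple[pd.DataFrame, RatioSummary]:
    """Degree of coimmunoprecipitation ([+]IP/WCL) per experiment and
    condition, plus the PKA:CON ratio of degrees."""
    return _degree_scheme(table, target, "IP_pos", absolute)


def surface_degree(table: pd.DataFrame, target: str,
                   absolute: bool = False) -> tuple[pd.DataFrame, RatioSummary]:
    """Degree of surface biotinylation (biotinylated/WCL) per experiment and
    condition, plus the PKA:CON ratio of degrees."""
    return _degree_scheme(table, target, "biotinylated", absolute)
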