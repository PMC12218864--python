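"""Schema, range and referential-integrity checks for the pipeline's CSVs.

``validate_tables`` reports violations instead of raising, so a pipeline run
can surface every problem in one pass. Each violation row names the table,
the rule broken and (where applicable) the offending row index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["validate_tables"]

_SITE_COLS = {
    "site_id", "square_id", "season", "easting_m", "northing_m", "camera_model",
    "opuntia_cover_pct", "square_opuntia_vol_m3_per_m", "grass_pct", "shrub_pct",
    "forb_pct", "succulent_pct", "tree_count", "dist_river_m", "dist_road_m",
    "livestock_prop",
}
_OBS_COLS = {"site_id", "date", "detected", "count", "night_count", "temp_c", "lunar_frac"}
_TRAN_COLS = {"square_id", "size_class", "bin_lo_m", "bin_hi_m", "count", "transect_length_m"}
_VOTE_COLS = {"image_id", "site_id", "timestamp", "volunteer_id", "label", "expert_label"}


def _viol(table: str, rule: str, rows=None) -> dict:
    return {
        "table": table,
        "rule": rule,
        "rows": "" if rows is None else ";".join(str(r) for r in rows[:20]),
        "n_rows": 0 if rows is None else len(rows),
    }


def validate_tables(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Validate the study CSVs; returns a violations table (possibly empty).

    ``paths`` maps any subset of {sites, observations, transects, votes} to
    file paths. Missing files are themselves reported as violations.
    """
    v: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, p in paths.items():
        p = Path(p)
        if not p.exists():
            v.append(_viol(name, f"file not found: {p}"))
            continue
        tables[name] = pd.read_csv(p)

    sites = tables.get("sites")
    if sites is not None:
        missing = _SITE_COLS - set(sites.columns)
        if missing:
            v.append(_viol("sites", f"missing columns {sorted(missing)}"))
        else:
            bad = sites.index[~sites["season"].isin([1, 2])]
            if len(bad):
                v.append(_viol("sites", "season not in {1,2}", bad))
            for col in ["opuntia_cover_pct", "grass_pct", "shrub_pct", "forb_pct", "succulent_pct"]:
                bad = sites.index[(sites[col] < 0) | (sites[col] > 100)]
                if len(bad):
                    v.append(_viol("sites", f"{col} outside [0,100]", bad))
            bad = sites.index[(sites["livestock_prop"] < 0) | (sites["livestock_prop"] > 1)]
            if len(bad):
                v.append(_viol("sites", "livestock_prop outside [0,1]", bad))
            for col in ["tree_count", "dist_river_m", "dist_road_m"]:
                bad = sites.index[sites[col] < 0]
                if len(bad):
                    v.append(_viol("sites", f"{col} negative", bad))
            dup = sites.index[sites["site_id"].duplicated()]
            if len(dup):
                v.append(_viol("sites", "duplicate site_id", dup))

    obs = tables.get("observations")
    if obs is not None:
        missing = _OBS_COLS - set(obs.columns)
        if missing:
            v.append(_viol("observations", f"missing columns {sorted(missing)}"))
        else:
            if sites is not None and "site_id" in sites.columns:
                bad = obs.index[~obs["site_id"].isin(sites["site_id"])]
                if len(bad):
                    v.append(_viol("observations", "unknown site_id", bad))
            bad = obs.index[~(obs["detected"].isin([0, 1]) | obs["detected"].isna())]
            if len(bad):
                v.append(_viol("observations", "detected not in {0,1,NA}", bad))
            bad = obs.index[obs["night_count"] > obs["count"]]
            if len(bad):
                v.append(_viol("observations", "night_count > count", bad))
            bad = obs.index[(obs["count"] < 0) | (obs["night_count"] < 0)]
            if len(bad):
                v.append(_viol("observations", "negative count", bad))
            bad = obs.index[(obs["lunar_frac"] < 0) | (obs["lunar_frac"] > 1)]
            if len(bad):
                v.append(_viol("observations", "lunar_frac outside [0,1]", bad))

    tr = tables.get("transects")
    if tr is not None:
        missing = _TRAN_COLS - set(tr.columns)
        if missing:
            v.append(_viol("transects", f"missing columns {sorted(missing)}"))
        else:
            bad = tr.index[~tr["size_class"].isin(["S", "M", "L"])]
            if len(bad):
                v.append(_viol("transects", "size_class not in {S,M,L}", bad))
            bad = tr.index[tr["count"] < 0]
            if len(bad):
                v.append(_viol("transects", "negative count", bad))
            bad = tr.index[tr["bin_hi_m"] <= tr["bin_lo_m"]]
            if len(bad):
                v.append(_viol("transects", "bin_hi <= bin_lo", bad))
            bad = tr.index[tr["transect_length_m"] <= 0]
            if len(bad):
                v.append(_viol("transects", "non-positive transect length", bad))

    votes = tables.get("votes")
    if votes is not None and len(votes):
        missing = _VOTE_COLS - set(votes.columns)
        if missing:
            v.append(_viol("votes", f"missing columns {sorted(missing)}"))
        else:
            if sites is not None and "site_id" in sites.columns:
                bad = votes.index[~votes["site_id"].isin(sites["site_id"])]
                if len(bad):
                    v.append(_viol("votes", "unknown site_id", bad))
            per_img = votes.groupby("image_id")["volunteer_id"].nunique()
            empty = per_img.index[per_img < 1]
            if len(empty):
                v.append(_viol("votes", "image with no volunteers", list(empty)))

    return pd.DataFrame(v, columns=["table", "rule", "rows", "n_rows"])
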