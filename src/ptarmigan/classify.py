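"""Seasonal activity centers and migrant/resident classification.

A bird-season is winter (January–March) or summer (May–July). Each bird's
fixes in a season collapse to an activity center; for nesting hens the
summer center is pulled halfway toward the nest. Consecutive season pairs
(winter→summer of the same year, summer→winter of the next) become
transitions whose Euclidean displacement is compared against the
classification threshold — the sum of the baseline winter and summer range
radii: centers further apart than that cannot have overlapping circular
ranges, so the bird is called a migrant.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geo import RangeBaseline, filter_gps_outliers

__all__ = [
    "SeasonKey",
    "assign_season",
    "activity_center",
    "build_transitions",
    "summarize_transitions",
    "classify_population",
]

_WINTER_MONTHS = (1, 2, 3)
_SUMMER_MONTHS = (5, 6, 7)


class SeasonKey(NamedTuple):
    year: int
    season: str  # "winter" | "summer"

    @property
    def order(self) -> int:
        """Total order over seasons: winter(y) < summer(y) < winter(y+1)."""
        return 2 * self.year + (0 if self.season == "winter" else 1)


def assign_season(timestamp) -> SeasonKey | None:
    """Map an instant to its analysis season, or None outside both windows."""
    ts = pd.Timestamp(timestamp)
    if ts.month in _WINTER_MONTHS:
        return SeasonKey(ts.year, "winter")
    if ts.month in _SUMMER_MONTHS:
        return SeasonKey(ts.year, "summer")
    return None


def activity_center(fixes, nest=None) -> np.ndarray:
    """Seasonal activity center of a fix set, optionally nest-weighted.

    Without a nest the center is the arithmetic mean of the fixes. With a
    nest, the nest location and the mean of all other positions get equal
    weight, i.e. the center is their midpoint. A nest with no other fixes is
    the center itself.
    """
    pts = None if fixes is None else np.asarray(fixes, dtype=float).reshape(-1, 2)
    has_fixes = pts is not None and len(pts) > 0
    if not has_fixes and nest is None:
        raise ValidationError("activity center needs at least one fix or a nest")
    if nest is None:
        return pts.mean(axis=0)
    nest = np.asarray(nest, dtype=float).reshape(2)
    if not has_fixes:
        return nest
    return 0.5 * (nest + pts.mean(axis=0))


def build_transitions(centers: pd.DataFrame, baseline: RangeBaseline | None = None) -> pd.DataFrame:
    """Pair consecutive season centers and classify each displacement.

    Parameters
    ----------
    centers : DataFrame with columns bird_id, year, season, x, y
        One row per bird-season; duplicates are rejected.
    baseline : RangeBaseline
        Supplies the classification threshold (default 1276 m).

    Returns
    -------
    DataFrame with one row per consecutive pair present for a bird:
    bird_id, from_year, from_season, to_year, to_season, distance_m,
    strategy, is_first_spring. A displacement strictly greater than the
    threshold is a migrant; exactly at or below it, a resident.
    """
    baseline = baseline or RangeBaseline()
    required = {"bird_id", "year", "season", "x", "y"}
    if missing := required - set(centers.columns):
        raise ValidationError(f"centers table is missing columns: {sorted(missing)}")
    if centers.duplicated(["bird_id", "year", "season"]).any():
        raise ValidationError("duplicate (bird, season) centers")

    rows = []
    for bird_id, sub in centers.groupby("bird_id", sort=True):
        sub = sub.assign(order=[SeasonKey(y, s).order for y, s in zip(sub["year"], sub["season"])])
        sub = sub.sort_values("order")
        arr = sub[["year", "x", "y", "order"]].to_numpy()
        seasons = sub["season"].to_numpy()
        for i in range(len(sub) - 1):
            if arr[i + 1, 3] - arr[i, 3] != 1:
                continue  # a season is missing; no transition
            dist = float(np.hypot(arr[i + 1, 1] - arr[i, 1], arr[i + 1, 2] - arr[i, 2]))
            rows.append(
                {
                    "bird_id": bird_id,
                    "from_year": int(arr[i, 0]),
                    "from_season": seasons[i],
                    "to_year": int(arr[i + 1, 0]),
                    "to_season": seasons[i + 1],
                    "distance_m": dist,
                    "strategy": "migrant" if dist > baseline.threshold else "resident",
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "bird_id", "from_year", "from_season", "to_year", "to_season",
            "distance_m", "strategy",
        ],
    )
    spring = (out["from_season"] == "winter") & (out["to_season"] == "summer")
    first = out[spring].groupby("bird_id")["from_year"].idxmin()
    out["is_first_spring"] = False
    out.loc[first, "is_first_spring"] = True
    return out


def summarize_transitions(transitions: pd.DataFrame, first_spring_only: bool = True) -> pd.DataFrame:
    """Per-year counts of residents and migrants with an overall row.

    The percentage of migrants is rounded to the nearest integer.
    """
    if len(transitions) == 0:
        raise ValidationError("no transitions to summarize")
    tr = transitions
    if first_spring_only:
        tr = tr[tr["is_first_spring"]]
    if len(tr) == 0:
        raise ValidationError("no first-spring transitions to summarize")
    rows = []
    for year, sub in tr.groupby("to_year"):
        n_mig = int((sub["strategy"] == "migrant").sum())
        n_res = len(sub) - n_mig
        rows.append((year, n_res, n_mig))
    n_mig = int((tr["strategy"] == "migrant").sum())
    rows.append(("total", len(tr) - n_mig, n_mig))
    out = pd.DataFrame(rows, columns=["year", "residents", "migrants"])
    out["total"] = out["residents"] + out["migrants"]
    out["pct_migrants"] = (100.0 * out["migrants"] / out["total"]).round().astype(int)
    return out


def _season_centers(fixes: pd.DataFrame, nests: pd.DataFrame | None) -> pd.DataFrame:
    nest_lookup = {}
    if nests is not None and len(nests):
        for row in nests.itertuples():
            nest_lookup[(row.bird_id, int(row.year))] = (float(row.x_m), float(row.y_m))

    rows = []
    for (bird_id, year, season), sub in fixes.groupby(["bird_id", "year", "season"]):
        non_nest = sub[sub["source"] != "nest"]
        pts = non_nest[["x_m", "y_m"]].to_numpy(dtype=float)
        nest = nest_lookup.get((bird_id, int(year))) if season == "summer" else None
        if nest is None and season == "summer":
            nest_rows = sub[sub["source"] == "nest"]
            if len(nest_rows):
                nest = nest_rows[["x_m", "y_m"]].to_numpy(dtype=float)[0]
        if len(pts) == 0 and nest is None:
            continue
        cx, cy = activity_center(pts if len(pts) else None, nest)
        rows.append({"bird_id": bird_id, "year": int(year), "season": season, "x": cx, "y": cy})
    return pd.DataFrame(rows, columns=["bird_id", "year", "season", "x", "y"])


def classify_population(
    fixes: pd.DataFrame,
    nests: pd.DataFrame | None = None,
    baseline: RangeBaseline | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full classification pipeline from a fixes table to transitions.

    Steps: parse timestamps; screen each bird's GPS track with the
    consecutive-distance outlier rule; assign fixes to seasons (capture
    positions taken January–March count as winter fixes); build per-season
    activity centers (nest-weighted in summer when a nest is known); pair
    consecutive seasons and classify against the threshold.

    Returns ``(transitions, centers)``.
    """
    baseline = baseline or RangeBaseline()
    required = {"bird_id", "datetime", "x_m", "y_m", "source"}
    if missing := required - set(fixes.columns):
        raise ValidationError(f"fixes table is missing columns: {sorted(missing)}")
    fixes = fixes.copy()
    fixes["datetime"] = pd.to_datetime(fixes["datetime"])

    # Screen GPS tracks bird by bird; other sources pass through.
    keep_parts = [fixes[fixes["source"] != "gps"]]
    for _, track in fixes[fixes["source"] == "gps"].groupby("bird_id"):
        track = track.sort_values("datetime")
        if len(track) < 3:
            keep_parts.append(track)
            continue
        _, flagged = filter_gps_outliers(
            track[["x_m", "y_m"]].to_numpy(dtype=float),
            track["datetime"].to_numpy(),
        )
        mask = np.ones(len(track), dtype=bool)
        mask[flagged] = False
        keep_parts.append(track[mask])
    clean = pd.concat(keep_parts, ignore_index=True)

    season = clean["datetime"].map(assign_season)
    clean = clean[season.notna()].copy()
    keys = season.dropna()
    clean["year"] = [k.year for k in keys]
    clean["season"] = [k.season for k in keys]

    centers = _season_centers(clean, nests)
    transitions = build_transitions(centers, baseline)
    return transitions, centers
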