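"""Synthetic telemetry generator with known ground truth.

Emulates the sampling design of a breeding-partial-migration study of
radio-tagged female willow ptarmigan: birds captured in winter at two sites,
VHF fixes scattered around per-bird seasonal activity centers, a few
GPS-collared birds producing dense winter tracks with injected position
spikes, and nesting outcomes (clutch size from an underdispersed
Conway–Maxwell–Poisson distribution, binary nest fate).

Each bird's first seasonal decision comes from a logistic rule on
standardized body weight and age class; later decisions repeat the previous
one with probability ``strategy_fidelity`` and are redrawn from the rule
otherwise. Migrant displacements are log-normal and sit far above the
classification threshold; resident displacements stay well below it, so the
generated truth labels are unambiguous.

All randomness flows from one root ``numpy`` generator, so a config plus a
seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cmp import cmp_rvs
from .errors import ValidationError
from .geo import RangeBaseline

__all__ = ["SimConfig", "SyntheticTruth", "simulate_population", "simulate_gps_track", "write_tables"]

# Expected 95% MCP area of n = 100 isotropic-Gaussian fixes, in units of the
# per-axis variance (Monte Carlo, 20k replicates, SE ~ 0.01). Stored once:
# fix scatter is solved from the configured baseline area via this constant.
MCP95_AREA_PER_VARIANCE_N100 = 12.442

# Mean 95% MCP area of a 540-fix confined correlated-walk track, in units of
# the squared mean step length, at the walk parameters below (Monte Carlo,
# 600 replicates, SE ~ 0.7).
CRW_AREA_PER_STEP2_N540 = 174.9
CRW_TURN_SD = 0.5          # rad, sd of the wrapped-normal turning angle
CRW_HOMING = 0.3           # strength of the heading bias toward the center
CRW_RANGE_OVER_STEP = 10.0  # confinement radius in units of mean step length
CRW_STEP_SHAPE = 8.0       # gamma shape of step lengths (CV ~ 0.35)


@dataclass
class SimConfig:
    """Study conditions of the synthetic population.

    Defaults reproduce the design scale of the field study: two capture
    sites 20 km apart, juvenile/adult winter weights around 590/600 g,
    a 4.08 km² winter and 0.058 km² summer circular range baseline
    (threshold 1276 m), ~73% migrants, high between-season strategy
    fidelity, clutches of ~10 eggs with underdispersion (nu = 2).
    """

    n_birds: int = 100
    n_years: int = 5
    start_year: int = 2015
    sites: tuple = ((0.0, 0.0), (20_000.0, 0.0))
    site_scatter_m: float = 1_500.0
    p_juvenile: float = 0.5
    weight_mean_juv: float = 590.0
    weight_mean_ad: float = 600.0
    weight_sd: float = 30.0
    beta0: float = 1.0
    beta_w: float = -1.5
    beta_ad: float = 0.0
    beta_w_ad: float = 1.5
    strategy_fidelity: float = 0.9
    migrant_dist_meanlog: float = 8.9   # log-meters; median ~ 7.3 km
    migrant_dist_sdlog: float = 0.65
    winter_mcp_km2: float = 4.08
    summer_range_km2: float = 0.058
    fixes_per_season: tuple = (6, 10)
    gps_interval_h: float = 4.0
    outlier_rate: float = 0.02
    outlier_multiplier: float = 20.0
    clutch_mu: float = 10.0
    clutch_nu: float = 2.0
    p_hatch: float = 0.7
    strategy_effect_eggs: float = 0.0
    strategy_effect_hatch: float = 0.0
    nesting_prob: float = 0.9
    n_gps_birds: int = 3
    seed: int = 20220310

    def __post_init__(self):
        probs = {
            "p_juvenile": self.p_juvenile,
            "strategy_fidelity": self.strategy_fidelity,
            "p_hatch": self.p_hatch,
            "nesting_prob": self.nesting_prob,
        }
        for name, v in probs.items():
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be a probability in [0, 1], got {v!r}")
        if not (math.isfinite(self.outlier_rate) and 0.0 <= self.outlier_rate < 1.0):
            raise ValidationError(f"outlier_rate must be in [0, 1), got {self.outlier_rate!r}")
        for name in ("weight_sd", "clutch_nu", "clutch_mu", "winter_mcp_km2",
                     "summer_range_km2", "migrant_dist_sdlog", "gps_interval_h",
                     "outlier_multiplier", "site_scatter_m"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive and finite, got {v!r}")
        for name in ("beta0", "beta_w", "beta_ad", "beta_w_ad", "migrant_dist_meanlog",
                     "strategy_effect_eggs", "strategy_effect_hatch"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.n_birds < 1 or self.n_years < 1:
            raise ValidationError("n_birds and n_years must be >= 1")
        lo, hi = self.fixes_per_season
        if not (1 <= lo <= hi):
            raise ValidationError(f"fixes_per_season must be an increasing range >= 1, got {self.fixes_per_season!r}")
        # Migrant displacements must clear the classification threshold.
        thr = self.baseline.threshold
        p_below = stats.lognorm.cdf(thr, s=self.migrant_dist_sdlog,
                                    scale=math.exp(self.migrant_dist_meanlog))
        if p_below > 0.01:
            raise ValidationError(
                "migrant distance distribution places "
                f"{100 * p_below:.1f}% of its mass at or below the {thr} m threshold "
                "(must be < 1%); raise migrant_dist_meanlog or shrink sdlog"
            )

    @property
    def baseline(self) -> RangeBaseline:
        return RangeBaseline(self.winter_mcp_km2, self.summer_range_km2)

    @property
    def winter_scatter_m(self) -> float:
        """Per-axis fix scatter solved from the winter baseline area."""
        return math.sqrt(self.winter_mcp_km2 * 1e6 / MCP95_AREA_PER_VARIANCE_N100)

    @property
    def summer_scatter_m(self) -> float:
        return math.sqrt(self.summer_range_km2 * 1e6 / MCP95_AREA_PER_VARIANCE_N100)


@dataclass
class SyntheticTruth:
    """Generating truth for recovery tests.

    ``transitions`` has one row per simulated consecutive-season pair
    (bird_id, from_year, from_season, to_year, to_season, strategy,
    displacement_m, is_first_spring); ``birds`` carries the true state
    variables; ``gps_outliers`` maps GPS bird ids to injected spike indices
    within that bird's time-ordered track; ``params`` records the generating
    coefficients.
    """

    transitions: pd.DataFrame
    birds: pd.DataFrame
    gps_outliers: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def simulate_gps_track(
    center,
    config: SimConfig,
    n_fixes: int = 540,
    start=None,
    rng: np.random.Generator | None = None,
):
    """Confined correlated-random-walk GPS track with injected spikes.

    The bird takes gamma-distributed steps with persistent headings and a
    gentle homing bias toward ``center``; the walk parameters are calibrated
    so a 540-fix track has an expected 95% MCP near the configured winter
    area. Each injected outlier displaces a single fix by
    ``outlier_multiplier`` × the mean step length in a random direction
    (spikes are kept ≥3 fixes apart and off the track ends so each one is a
    lone spike, as GPS error produces).

    Returns ``(DataFrame with datetime/x_m/y_m, outlier_indices)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if n_fixes < 3:
        raise ValidationError(f"a GPS track needs at least 3 fixes, got {n_fixes}")
    center = np.asarray(center, dtype=float).reshape(2)
    L = math.sqrt(config.winter_mcp_km2 * 1e6 / CRW_AREA_PER_STEP2_N540)
    R = CRW_RANGE_OVER_STEP * L

    pts = np.empty((n_fixes, 2))
    pos = center.copy()
    heading = rng.uniform(0.0, 2.0 * math.pi)
    for i in range(n_fixes):
        pts[i] = pos
        off = pos - center
        r = math.hypot(*off)
        bias = 0.0
        if r > 0:
            to_center = math.atan2(-off[1], -off[0])
            dh = (to_center - heading + math.pi) % (2.0 * math.pi) - math.pi
            bias = CRW_HOMING * dh * min(1.0, r / R)
        heading += bias + rng.normal(0.0, CRW_TURN_SD)
        step = rng.gamma(CRW_STEP_SHAPE, L / CRW_STEP_SHAPE)
        pos = pos + step * np.array([math.cos(heading), math.sin(heading)])

    outliers: list[int] = []
    if config.outlier_rate > 0:
        hits = np.flatnonzero(rng.random(n_fixes) < config.outlier_rate)
        for t in hits:
            if 1 <= t <= n_fixes - 2 and all(abs(t - u) >= 3 for u in outliers):
                outliers.append(int(t))
        for t in outliers:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            pts[t] += config.outlier_multiplier * L * np.array([math.cos(ang), math.sin(ang)])

    start = pd.Timestamp(start) if start is not None else pd.Timestamp(f"{config.start_year}-01-01")
    times = start + pd.to_timedelta(np.arange(n_fixes) * config.gps_interval_h, unit="h")
    track = pd.DataFrame({"datetime": times, "x_m": pts[:, 0], "y_m": pts[:, 1]})
    return track, np.array(sorted(outliers), dtype=int)


def _season_times(year: int, season: str, n: int, rng) -> pd.DatetimeIndex:
    start = pd.Timestamp(f"{year}-01-05") if season == "winter" else pd.Timestamp(f"{year}-05-01")
    end = pd.Timestamp(f"{year}-03-28") if season == "winter" else pd.Timestamp(f"{year}-07-28")
    span = (end - start).total_seconds()
    offsets = np.sort(rng.uniform(0.0, span, n))
    return start + pd.to_timedelta(offsets, unit="s")


def simulate_population(config: SimConfig):
    """Generate (fixes, birds, nests, truth) for one synthetic population.

    Returns
    -------
    fixes : DataFrame — bird_id, datetime, x_m, y_m, source.
    birds : DataFrame — bird_id, capture_date, site, age_class, weight_g.
    nests : DataFrame — bird_id, year, clutch_size, fate, x_m, y_m.
    truth : SyntheticTruth
    """
    rng = np.random.default_rng(config.seed)
    thr = config.baseline.threshold
    sites = np.asarray(config.sites, dtype=float)
    lo_fix, hi_fix = config.fixes_per_season

    n = config.n_birds
    site_idx = rng.integers(0, len(sites), n)
    juvenile = rng.random(n) < config.p_juvenile
    weight = np.where(
        juvenile,
        rng.normal(config.weight_mean_juv, config.weight_sd, n),
        rng.normal(config.weight_mean_ad, config.weight_sd, n),
    )
    weight = np.round(weight / 5.0) * 5.0  # field scales read to the nearest 5 g
    wz = (weight - weight.mean()) / weight.std(ddof=1)
    adult = (~juvenile).astype(float)
    logit_p = (
        config.beta0
        + config.beta_w * wz
        + config.beta_ad * adult
        + config.beta_w_ad * wz * adult
    )
    p_migrate = 1.0 / (1.0 + np.exp(-logit_p))
    capture_year = rng.integers(config.start_year, config.start_year + config.n_years, n)

    bird_rows, fix_rows, nest_rows, truth_rows = [], [], [], []
    last_year = config.start_year + config.n_years - 1

    for b in range(n):
        bird_id = f"F{b + 1:03d}"
        cy = int(capture_year[b])
        capture_date = pd.Timestamp(f"{cy}-02-01") + pd.Timedelta(
            seconds=float(rng.uniform(0, 55 * 86400))
        )
        bird_rows.append(
            {
                "bird_id": bird_id,
                "capture_date": capture_date,
                "site": "Guslia" if site_idx[b] == 0 else "Lifjellet",
                "age_class": "juvenile" if juvenile[b] else "adult",
                "weight_g": weight[b],
            }
        )
        center = sites[site_idx[b]] + rng.normal(0.0, config.site_scatter_m, 2)
        fix_rows.append(
            {
                "bird_id": bird_id,
                "datetime": capture_date,
                "x_m": center[0] + rng.normal(0.0, config.winter_scatter_m),
                "y_m": center[1] + rng.normal(0.0, config.winter_scatter_m),
                "source": "capture",
            }
        )

        # Season sequence: winter(cy), summer(cy), winter(cy+1), ... summer(last).
        seasons = []
        for year in range(cy, last_year + 1):
            seasons.append((year, "winter"))
            seasons.append((year, "summer"))

        decision = None
        first_spring_done = False
        for i, (year, season) in enumerate(seasons):
            if i > 0:
                # Transition into this season.
                if decision is None:
                    decision = bool(rng.random() < p_migrate[b])
                else:
                    if rng.random() >= config.strategy_fidelity:
                        decision = bool(rng.random() < p_migrate[b])
                if decision:
                    disp = float(rng.lognormal(config.migrant_dist_meanlog, config.migrant_dist_sdlog))
                else:
                    disp = float(rng.uniform(0.0, 0.8 * thr))
                bearing = rng.uniform(0.0, 2.0 * math.pi)
                prev = seasons[i - 1]
                new_center = center + disp * np.array([math.cos(bearing), math.sin(bearing)])
                is_first_spring = season == "summer" and not first_spring_done
                if is_first_spring:
                    first_spring_done = True
                truth_rows.append(
                    {
                        "bird_id": bird_id,
                        "from_year": prev[0],
                        "from_season": prev[1],
                        "to_year": year,
                        "to_season": season,
                        "strategy": "migrant" if decision else "resident",
                        "displacement_m": disp,
                        "is_first_spring": is_first_spring,
                    }
                )
                center = new_center

            scatter = config.winter_scatter_m if season == "winter" else config.summer_scatter_m
            n_fix = int(rng.integers(lo_fix, hi_fix + 1))
            times = _season_times(year, season, n_fix, rng)
            pts = center + rng.normal(0.0, scatter, (n_fix, 2))
            for t, (x, y) in zip(times, pts):
                fix_rows.append(
                    {"bird_id": bird_id, "datetime": t, "x_m": x, "y_m": y, "source": "triangulation"}
                )

            if season == "summer" and rng.random() < config.nesting_prob:
                spring = truth_rows[-1]  # transition into this summer
                is_migrant = spring["strategy"] == "migrant"
                nest_xy = center + rng.normal(0.0, config.summer_scatter_m, 2)
                mu = config.clutch_mu * math.exp(config.strategy_effect_eggs * is_migrant)
                clutch = int(cmp_rvs(mu, config.clutch_nu, 1, rng)[0])
                logit_h = math.log(config.p_hatch / (1.0 - config.p_hatch)) if 0 < config.p_hatch < 1 else (
                    math.inf if config.p_hatch == 1.0 else -math.inf
                )
                ph = 1.0 / (1.0 + math.exp(-(logit_h + config.strategy_effect_hatch * is_migrant)))
                nest_rows.append(
                    {
                        "bird_id": bird_id,
                        "year": year,
                        "clutch_size": clutch,
                        "fate": "hatched" if rng.random() < ph else "failed",
                        "x_m": nest_xy[0],
                        "y_m": nest_xy[1],
                    }
                )
                nest_date = pd.Timestamp(f"{year}-06-01") + pd.Timedelta(
                    seconds=float(rng.uniform(0, 20 * 86400))
                )
                fix_rows.append(
                    {
                        "bird_id": bird_id,
                        "datetime": nest_date,
                        "x_m": nest_xy[0],
                        "y_m": nest_xy[1],
                        "source": "nest",
                    }
                )

    # GPS-collared birds: one dense winter track each, used for the winter
    # range baseline; single-season birds, so they yield no transitions.
    gps_outliers = {}
    fixes_per_winter = max(3, int(round(83 * 24 / config.gps_interval_h)))
    for gb in range(config.n_gps_birds):
        bird_id = f"G{gb + 1:02d}"
        site = sites[gb % len(sites)]
        center = site + rng.normal(0.0, config.site_scatter_m, 2)
        track, spikes = simulate_gps_track(
            center, config, n_fixes=fixes_per_winter,
            start=pd.Timestamp(f"{config.start_year + config.n_years - 1}-01-05"), rng=rng,
        )
        gps_outliers[bird_id] = spikes
        bird_rows.append(
            {
                "bird_id": bird_id,
                "capture_date": track["datetime"].iloc[0],
                "site": "Guslia" if gb % len(sites) == 0 else "Lifjellet",
                "age_class": "adult",
                "weight_g": float(np.round(rng.normal(config.weight_mean_ad, config.weight_sd) / 5) * 5),
                }
        )
        for row in track.itertuples():
            fix_rows.append(
                {"bird_id": bird_id, "datetime": row.datetime, "x_m": row.x_m, "y_m": row.y_m,
                 "source": "gps"}
            )

    fixes = pd.DataFrame(fix_rows).sort_values(["bird_id", "datetime"], kind="stable").reset_index(drop=True)
    birds = pd.DataFrame(bird_rows)
    nests = pd.DataFrame(nest_rows, columns=["bird_id", "year", "clutch_size", "fate", "x_m", "y_m"])
    truth = SyntheticTruth(
        transitions=pd.DataFrame(
            truth_rows,
            columns=["bird_id", "from_year", "from_season", "to_year", "to_season",
                     "strategy", "displacement_m", "is_first_spring"],
        ),
        birds=birds.assign(p_migrate=np.append(p_migrate, np.full(config.n_gps_birds, np.nan))
                           if config.n_gps_birds else p_migrate),
        gps_outliers=gps_outliers,
        params={k: v for k, v in asdict(config).items()},
    )
    return fixes, birds, nests, truth


def write_tables(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write fixes/birds/nests/truth CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixes, birds, nests, truth = simulate_population(config)
    paths = {}
    for name, df in [("fixes", fixes), ("birds", birds), ("nests", nests),
                     ("truth", truth.transitions)]:
        path = outdir / f"{name}.csv"
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)
        paths[name] = path
    return paths
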