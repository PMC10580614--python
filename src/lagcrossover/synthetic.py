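"""Synthetic geography, exposure surfaces and mortality records.

The generator emulates the statistical structure the case-crossover
analysis assumes, with known ground truth so every downstream stage can
be verified: a unit-cell grid carrying urban polygon localities
(rectangular unions of cells with positive population weights) and
rural point localities; daily PM2.5 and temperature surfaces built from
a seasonal sinusoid, a Gaussian-kernel-smoothed spatial field and AR(1)
temporal noise (PM2.5 floored at 0 to respect its physical support);
and locality-day death counts drawn from a Poisson log-linear model
whose linear predictor contains weekday effects, a slow seasonal trend,
the true distributed-lag PM2.5 effects, and a nonlinear temperature
term.  The weekday and seasonal terms are injected deliberately: the
time-stratified design must remove them, so the conditional-logistic
estimand equals ``true_lag_betas_pm``.

Default exposure moments target a realistic polluted-megacity regime
(PM2.5 mean 24.6, SD ~10.8 ug/m3; temperature mean 16.6, SD ~2.6 C).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, box

from .exposure import ExposureFields, Grid, Locality, LocalitySeries, build_locality_series

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "StudyData",
    "simulate_geography",
    "simulate_exposure_fields",
    "simulate_mortality",
    "simulate_study",
    "betas_for_lag06_percent",
]

# stage tags mixed into the seed stream so stages are independently reproducible
_STAGE_GEO, _STAGE_FIELDS, _STAGE_DEATHS = 11, 23, 37

#: Log-rate day-of-week effects (Mon..Sun) injected into the truth model.
WEEKDAY_EFFECTS = np.array([0.05, 0.02, 0.0, -0.01, 0.01, -0.04, -0.03])

_DEFAULT_CAUSE_MIX = {
    "I21": 0.14, "I10": 0.04, "I25": 0.015, "I50": 0.02, "I61": 0.02,
    "I63": 0.007, "J18": 0.036, "J44": 0.045, "K70": 0.063, "N18": 0.021,
    "G20": 0.002, "F03": 0.006, "X70": 0.007, "C50": 0.3, "E11": 0.278,
}

_DEMOGRAPHICS = {
    "sex": (["male", "female"], [0.508, 0.492]),
    "education": (
        ["primary", "mid-high", "none", "college", "unspecified"],
        [0.494, 0.231, 0.129, 0.103, 0.043],
    ),
    "insurance": (["social-security", "none", "unspecified"], [0.628, 0.335, 0.037]),
    "job_category": (["not-employed", "employed", "unspecified"], [0.50, 0.45, 0.05]),
}
_P_ELDERLY = 0.627  # share of deaths at age >= 65


def betas_for_lag06_percent(percent: float, weights=None) -> np.ndarray:
    """Distribute a one-week cumulative effect over lags 0..6.

    ``percent`` is the percent increase per 10 ug/m3 for the lag06
    window; the implied cumulative log-odds per ug/m3 is split across
    the 7 lags with a declining-weight profile by default.
    """
    cum = np.log1p(percent / 100.0) / 10.0
    if weights is None:
        weights = np.array([0.30, 0.25, 0.15, 0.10, 0.08, 0.07, 0.05])
    weights = np.asarray(weights, dtype=float)
    return cum * weights / weights.sum()


@dataclass
class SyntheticScenario:
    """Ground-truth configuration of one simulated study."""

    n_urban_localities: int = 6
    n_rural_localities: int = 6
    grid_shape: tuple[int, int] = (8, 8)  # (rows, cols) of 1-km-analog cells
    date_range: tuple[str, str] = ("2004-01-01", "2006-12-31")
    true_lag_betas_pm: np.ndarray = field(
        default_factory=lambda: np.zeros(7)
    )  # log-odds per ug/m3, lags 0..6
    temp_effect: dict = field(
        default_factory=lambda: {"type": "quadratic", "center": 17.0, "coef": 0.002}
    )
    baseline_rate: float = 0.05  # deaths per locality-day
    pm_quad_coef: float = 0.0  # curvature of a nonlinear lag-0 PM term (0 = linear truth)

    mean_pm: float = 24.6
    seasonal_amplitude_pm: float = 6.0
    ar1_coef_pm: float = 0.65
    spatial_range_pm: float = 2.0  # Gaussian-kernel sigma, cells
    spatial_sd_pm: float = 4.0
    noise_sd_pm: float = 9.1  # marginal SD of the AR(1) component

    mean_temp: float = 16.6
    seasonal_amplitude_temp: float = 3.0
    ar1_coef_temp: float = 0.7
    spatial_range_temp: float = 2.0
    spatial_sd_temp: float = 0.5
    noise_sd_temp: float = 1.2

    cross_corr: float = 0.3  # shared-innovation fraction between PM and temp
    cause_mix: dict = field(default_factory=lambda: dict(_DEFAULT_CAUSE_MIX))
    distinct_cause: tuple[str, np.ndarray] | None = None  # (icd root, its own betas)
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_lag_betas_pm = np.asarray(self.true_lag_betas_pm, dtype=float)
        if self.true_lag_betas_pm.shape != (7,) or not np.isfinite(
            self.true_lag_betas_pm
        ).all():
            raise ValueError("true_lag_betas_pm must be 7 finite values")
        for rho in (self.ar1_coef_pm, self.ar1_coef_temp):
            if not -1.0 < rho < 1.0:
                raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-12:
            raise ValueError("cause_mix must sum to 1 within 1e-12")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.date_range[0], self.date_range[1], freq="D")

    def ground_truth(self) -> "GroundTruth":
        return GroundTruth.from_betas(self.true_lag_betas_pm)

    @classmethod
    def from_yaml(cls, source) -> "SyntheticScenario":
        raw = yaml.safe_load(source.read() if hasattr(source, "read") else open(source))
        if "true_lag_betas_pm" in raw:
            raw["true_lag_betas_pm"] = np.asarray(raw["true_lag_betas_pm"], float)
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "date_range" in raw:
            raw["date_range"] = tuple(raw["date_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_lag_betas_pm"] = [float(b) for b in self.true_lag_betas_pm]
        if self.distinct_cause is not None:
            d["distinct_cause"] = [
                self.distinct_cause[0],
                [float(b) for b in self.distinct_cause[1]],
            ]
        return d


@dataclass(frozen=True)
class GroundTruth:
    """The estimands implied by the generator's lag coefficients."""

    cumulative_beta_lag01: float
    cumulative_beta_lag06: float
    percent_per_10: dict

    @classmethod
    def from_betas(cls, betas) -> "GroundTruth":
        betas = np.asarray(betas, dtype=float)
        b01 = float(betas[:2].sum())
        b06 = float(betas.sum())
        to_pct = lambda b: float((np.exp(10.0 * b) - 1.0) * 100.0)
        return cls(
            cumulative_beta_lag01=b01,
            cumulative_beta_lag06=b06,
            percent_per_10={"lag01": to_pct(b01), "lag06": to_pct(b06)},
        )


def _rng(scenario: SyntheticScenario, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(scenario.seed), stage]))


def simulate_geography(
    scenario: SyntheticScenario,
) -> tuple[Grid, list[Locality], dict[int, float]]:
    """Grid, localities and per-cell population weights.

    Urban localities are 2x2-cell rectangles tiled row-major; rural
    localities are single points, each inside its own free cell.  Every
    cell carries a positive population weight (urban cells heavier).
    """
    rows, cols = scenario.grid_shape
    grid = Grid(nrows=rows, ncols=cols)
    rng = _rng(scenario, _STAGE_GEO)

    blocks = [(2 * r, 2 * c) for r in range(rows // 2) for c in range(cols // 2)]
    if scenario.n_urban_localities > len(blocks):
        raise ValueError(
            f"grid {scenario.grid_shape} fits at most {len(blocks)} urban localities"
        )
    localities: list[Locality] = []
    urban_cells: set[int] = set()
    for i in range(scenario.n_urban_localities):
        r0, c0 = blocks[i]
        localities.append(
            Locality(f"U{i:04d}", True, box(c0, r0, c0 + 2, r0 + 2))
        )
        urban_cells.update(
            grid.cell_id(r, c) for r in (r0, r0 + 1) for c in (c0, c0 + 1)
        )

    free = [c for c in range(grid.n_cells) if c not in urban_cells]
    if scenario.n_rural_localities > len(free):
        raise ValueError(
            f"only {len(free)} free cells for {scenario.n_rural_localities} rural localities"
        )
    for i in range(scenario.n_rural_localities):
        cell = free[i]
        r, c = divmod(cell, cols)
        dx, dy = rng.uniform(0.2, 0.8, size=2)
        localities.append(Locality(f"R{i:04d}", False, Point(c + dx, r + dy)))

    population = {
        c: float(rng.lognormal(8.0 if c in urban_cells else 5.0, 0.8))
        for c in range(grid.n_cells)
    }
    return grid, localities, population


def _smooth_spatial(rng, grid: Grid, sigma: float, sd: float) -> np.ndarray:
    if sd <= 0:
        return np.zeros(grid.n_cells)
    f = rng.standard_normal((grid.nrows, grid.ncols))
    if sigma > 0:
        f = gaussian_filter(f, sigma=sigma, mode="reflect")
    f = f - f.mean()  # centring before rescaling: smoothing leaves few
    s = f.std()       # effective dof, so a raw sample mean would be amplified
    if s > 0:
        f = f / s * sd
    return f.ravel()


def simulate_exposure_fields(scenario: SyntheticScenario, grid: Grid) -> ExposureFields:
    """Daily cell-level PM2.5 and temperature surfaces.

    Each variable = mean + seasonal sinusoid + smoothed spatial field +
    AR(1) temporal noise; PM2.5 and temperature share a configurable
    fraction of their innovations (``cross_corr``) and PM2.5 is floored
    at 0.
    """
    dates = scenario.dates
    T, C = len(dates), grid.n_cells
    rng = _rng(scenario, _STAGE_FIELDS)
    doy = dates.dayofyear.to_numpy()

    def spatial_innovations(sigma: float) -> np.ndarray:
        """(T, C) unit-variance innovations, spatially correlated across
        cells at the given Gaussian-kernel range (daily surfaces co-move)."""
        z = rng.standard_normal((T, grid.nrows, grid.ncols))
        if sigma > 0:
            z = gaussian_filter(z, sigma=(0, sigma, sigma), mode="reflect")
            s = z.std()
            if s > 0:
                z = z / s
        return z.reshape(T, C)

    a = np.sqrt(np.clip(scenario.cross_corr, 0.0, 1.0))
    z0 = spatial_innovations(scenario.spatial_range_pm)
    z_pm = a * z0 + np.sqrt(1 - a**2) * spatial_innovations(scenario.spatial_range_pm)
    z_tp = a * z0 + np.sqrt(1 - a**2) * spatial_innovations(scenario.spatial_range_temp)

    def ar1(z, rho, sd):
        if sd <= 0:
            return np.zeros_like(z)
        innov_sd = sd * np.sqrt(1 - rho**2)
        e = np.empty_like(z)
        e[0] = z[0] * sd
        for t in range(1, len(z)):
            e[t] = rho * e[t - 1] + innov_sd * z[t]
        return e

    season_pm = scenario.seasonal_amplitude_pm * np.sin(2 * np.pi * (doy - 15) / 365.25)
    season_tp = scenario.seasonal_amplitude_temp * np.sin(
        2 * np.pi * (doy - 100) / 365.25
    )
    spat_pm = _smooth_spatial(rng, grid, scenario.spatial_range_pm, scenario.spatial_sd_pm)
    spat_tp = _smooth_spatial(
        rng, grid, scenario.spatial_range_temp, scenario.spatial_sd_temp
    )

    pm = (
        scenario.mean_pm
        + season_pm[:, None]
        + spat_pm[None, :]
        + ar1(z_pm, scenario.ar1_coef_pm, scenario.noise_sd_pm)
    )
    temp = (
        scenario.mean_temp
        + season_tp[:, None]
        + spat_tp[None, :]
        + ar1(z_tp, scenario.ar1_coef_temp, scenario.noise_sd_temp)
    )
    return ExposureFields(grid=grid, dates=dates, pm=np.maximum(pm, 0.0), temp=temp)


def _temp_effect_values(spec: dict, t: np.ndarray) -> np.ndarray:
    kind = (spec or {}).get("type", "none")
    if kind == "none":
        return np.zeros_like(t)
    if kind == "quadratic":
        v = spec["coef"] * (t - spec["center"]) ** 2
        return v - np.nanmean(v)
    raise ValueError(f"unknown temp_effect type {kind!r}")


def simulate_mortality(
    scenario: SyntheticScenario, series: LocalitySeries
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual mortality records from a Poisson truth model.

    Per locality-day the death count is Poisson with log-rate =
    log(baseline) + weekday effect + slow seasonal trend +
    sum_l beta_l PM(t-l) + f(mean temperature over lags 0..6), PM and
    temperature terms centred so the realised rate stays near
    ``baseline_rate``.  Locality-days with any missing lag exposure are
    skipped and logged.  Each death gets an ICD-10 code from
    ``cause_mix`` and demographics from fixed categorical mixes.
    """
    rng = _rng(scenario, _STAGE_DEATHS)
    dates = series.dates
    T, L = series.pm.shape
    betas = scenario.true_lag_betas_pm

    def lagsum(b):
        out = np.zeros((T, L))
        for l, bl in enumerate(b):
            if bl != 0.0:
                out[6:] += bl * series.pm[6 - l : T - l]
        return out

    tmean = np.full((T, L), np.nan)
    w = np.lib.stride_tricks.sliding_window_view(series.temp, 7, axis=0)
    tmean[6:] = w.mean(axis=2)
    usable = np.zeros((T, L), dtype=bool)
    cw = np.lib.stride_tricks.sliding_window_view(series.complete, 7, axis=0)
    usable[6:] = cw.all(axis=2)

    # weekday + month-level seasonality and trend: exactly the structure the
    # time-stratified referent matching absorbs (constant within each stratum),
    # so the conditional-logistic estimand equals the injected lag betas
    dow = dates.dayofweek.to_numpy()
    month = dates.month.to_numpy()
    months_since = (dates.year.to_numpy() - dates.year[0]) * 12 + (
        month - dates.month[0]
    )
    time_terms = (
        WEEKDAY_EFFECTS[dow]
        + 0.15 * np.cos(2 * np.pi * (month - 1) / 12.0)
        - 0.02 * months_since / 12.0
    )
    pm_center = float(np.nanmean(series.pm))
    temp_term = np.where(usable, _temp_effect_values(scenario.temp_effect, tmean), 0.0)
    pm_quad = 0.0
    if scenario.pm_quad_coef:
        q = scenario.pm_quad_coef * (series.pm - pm_center) ** 2
        pm_quad = q - float(np.nanmean(q))

    mix = dict(scenario.cause_mix)
    groups: list[tuple[dict, np.ndarray]] = []
    if scenario.distinct_cause is not None:
        code, own = scenario.distinct_cause
        p = mix.pop(code)
        tot = sum(mix.values())
        groups.append(({k: v / tot for k, v in mix.items()}, betas, 1.0 - p))
        groups.append(({code: 1.0}, np.asarray(own, float), p))
    else:
        groups.append((mix, betas, 1.0))

    recs: list[pd.DataFrame] = []
    for g_mix, g_betas, g_frac in groups:
        log_rate = (
            np.log(scenario.baseline_rate * g_frac)
            + time_terms[:, None]
            + lagsum(g_betas)
            - float(np.sum(g_betas)) * pm_center
            + temp_term
            + pm_quad
        )
        counts = np.where(usable, rng.poisson(np.exp(log_rate)), 0)
        t_idx, l_idx = np.nonzero(counts)
        n_deaths = counts[t_idx, l_idx]
        n_tot = int(n_deaths.sum())
        codes = np.array(list(g_mix), dtype=object)
        probs = np.array([g_mix[c] for c in codes], dtype=float)
        probs = probs / probs.sum()
        t_rep = np.repeat(t_idx, n_deaths)
        l_rep = np.repeat(l_idx, n_deaths)
        elderly = rng.random(n_tot) < _P_ELDERLY
        age = np.where(
            elderly, rng.integers(65, 96, n_tot), rng.integers(18, 65, n_tot)
        )
        part = {
            "death_date": dates[t_rep],
            "locality_id": np.asarray(series.locality_ids, dtype=object)[l_rep],
            "icd10": codes[rng.choice(len(codes), size=n_tot, p=probs)],
            "age_years": age,
        }
        for col, (levels, pr) in _DEMOGRAPHICS.items():
            part[col] = np.asarray(levels, dtype=object)[
                rng.choice(len(levels), size=n_tot, p=np.asarray(pr))
            ]
        recs.append(pd.DataFrame(part))

    cols = [
        "death_date", "locality_id", "icd10", "age_years",
        "sex", "education", "insurance", "job_category",
    ]
    records = (
        pd.concat(recs, ignore_index=True)[cols]
        if recs and sum(len(r) for r in recs)
        else pd.DataFrame(columns=cols)
    )
    t_skip, l_skip = np.nonzero(~usable[6:])
    skipped = pd.DataFrame(
        {
            "date": dates[t_skip + 6],
            "locality_id": np.asarray(series.locality_ids, dtype=object)[l_skip],
            "reason": "missing-lag-exposure",
        }
    )
    return records, skipped


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    scenario: SyntheticScenario
    grid: Grid
    localities: list[Locality]
    population: dict[int, float]
    fields: ExposureFields
    series: LocalitySeries
    records: pd.DataFrame
    skipped: pd.DataFrame
    ground_truth: GroundTruth


def simulate_study(scenario: SyntheticScenario) -> StudyData:
    """Run geography -> fields -> assignment -> mortality end to end."""
    grid, localities, population = simulate_geography(scenario)
    fields = simulate_exposure_fields(scenario, grid)
    series = build_locality_series(fields, localities, population)
    records, skipped = simulate_mortality(scenario, series)
    return StudyData(
        scenario=scenario,
        grid=grid,
        localities=localities,
        population=population,
        fields=fields,
        series=series,
        records=records,
        skipped=skipped,
        ground_truth=scenario.ground_truth(),
    )
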