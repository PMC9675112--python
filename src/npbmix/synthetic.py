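"""Seeded synthetic cohorts emulating a Denver-area pre-birth study.

The real cohort this package's analysis was designed around is not publicly
available, so everything downstream is exercised on synthetic mother-child
dyads whose marginal summary statistics, correlation structure, covariate
frequencies, and outcome model mirror the published cohort description:
roughly 900 dyads, 21 census-tract-level exposures (12 environmental,
9 social), correlated within and across domains, with birth weight in grams
as the primary outcome and adiposity (% fat mass) as the secondary one.

Exposures are drawn from a Gaussian copula with Normal marginals; the
outcome is a sparse linear model in *population*-standardized predictors
(so planted per-SD effect sizes are exact truths), plus Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExposureSpec",
    "CorrelationSpec",
    "CovariateSpec",
    "SpatialFieldSpec",
    "SimulationConfig",
    "default_exposures",
    "nearest_correlation",
    "simulate_cohort",
    "simulate_monitors",
    "write_cohort",
    "read_cohort",
]

ENVIRONMENTAL = "environmental"
SOCIAL = "social"


@dataclass(frozen=True)
class ExposureSpec:
    """One census-tract exposure: name, units, Normal marginal, domain group."""

    name: str
    units: str
    mean: float
    sd: float
    group: str  # "environmental" | "social"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"exposure {self.name!r}: sd must be > 0, got {self.sd}")
        if self.group not in (ENVIRONMENTAL, SOCIAL):
            raise ValueError(f"exposure {self.name!r}: unknown group {self.group!r}")


def default_exposures() -> list[ExposureSpec]:
    """The 21 default exposures with published cohort means and SDs."""
    env = [
        ("pm25", "ug/m3", 7.5, 0.6),
        ("o3", "ppb", 48.0, 3.1),
        ("temperature", "degF", 52.2, 4.8),
        ("tree_cover", "%", 6.3, 3.1),
        ("impervious", "%", 40.5, 13.3),
        ("aadt", "vehicles/d-km2", 10344.0, 8203.0),
        ("dist_tri", "km", 3.9, 2.6),
        ("dist_npl", "km", 5.5, 3.3),
        ("dist_waste", "km", 5.2, 2.3),
        ("dist_emitters", "km", 8.3, 3.2),
        ("dist_cafos", "km", 36.8, 6.8),
        ("dist_mines_wells", "km", 3.4, 2.1),
    ]
    soc = [
        ("cvd_hosp", "n/10000", 244.0, 45.2),
        ("resp_hosp", "n/10000", 165.2, 33.0),
        ("violent_crimes", "n/1000", 12.8, 6.3),
        ("property_crimes", "n/1000", 55.4, 36.0),
        ("pct_less_hs", "%", 16.5, 12.7),
        ("pct_unemployed", "%", 9.7, 5.0),
        ("pct_poverty", "%", 15.3, 10.9),
        ("pct_limited_english", "%", 8.3, 8.3),
        ("pct_poc", "%", 54.3, 22.9),
    ]
    return [ExposureSpec(n, u, m, s, ENVIRONMENTAL) for n, u, m, s in env] + [
        ExposureSpec(n, u, m, s, SOCIAL) for n, u, m, s in soc
    ]


@dataclass(frozen=True)
class CorrelationSpec:
    """Block correlation ranges; pairwise entries drawn uniformly per block.

    Defaults reflect the published ranges: environmental-environmental
    Pearson correlations roughly -0.5..0.7, social-social -0.1..0.9, and
    moderate cross-domain correlation. The raw draw is projected to the
    nearest correlation matrix (Higham alternating projections).
    """

    env_range: tuple[float, float] = (-0.5, 0.7)
    social_range: tuple[float, float] = (-0.1, 0.9)
    cross_range: tuple[float, float] = (-0.3, 0.5)
    # Separate stream so the target matrix is stable across cohort seeds
    # unless the caller wants it otherwise.
    corr_seed: int = 20221119

    def build(self, exposures: list[ExposureSpec]) -> np.ndarray:
        rng = np.random.default_rng(self.corr_seed)
        p = len(exposures)
        groups = [e.group for e in exposures]
        raw = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                if groups[i] == ENVIRONMENTAL and groups[j] == ENVIRONMENTAL:
                    lo, hi = self.env_range
                    block = "environmental-environmental"
                elif groups[i] == SOCIAL and groups[j] == SOCIAL:
                    lo, hi = self.social_range
                    block = "social-social"
                else:
                    lo, hi = self.cross_range
                    block = "cross-block"
                if lo > hi:
                    raise ValueError(f"empty correlation range for {block} block")
                raw[i, j] = raw[j, i] = rng.uniform(lo, hi)
        return nearest_correlation(raw, groups=groups)


def nearest_correlation(
    a: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
    groups: list[str] | None = None,
) -> np.ndarray:
    """Higham (2002) alternating projections onto PSD and unit-diagonal sets.

    Raises ValueError naming the offending block if the result is not
    positive definite after repair (only possible for pathological input,
    e.g. non-finite entries).
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("correlation input contains non-finite entries")
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2.0)
        x = (v * np.maximum(w, 0.0)) @ v.T
        ds = x - r
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        if np.max(np.abs(y_new - y)) < tol:
            y = y_new
            break
        y = y_new
    y = (y + y.T) / 2.0
    # small jitter to move PSD boundary solutions strictly inside
    w = np.linalg.eigvalsh(y)
    if w.min() < 1e-8:
        y = y + (1e-8 - min(w.min(), 0.0)) * np.eye(len(y))
        d = np.sqrt(np.diag(y))
        y = y / np.outer(d, d)
    if np.linalg.eigvalsh(y).min() <= 0:
        block = "correlation matrix"
        if groups is not None:
            off = np.abs(y - np.eye(len(y)))
            i, j = np.unravel_index(np.argmax(off), off.shape)
            block = f"{groups[i]}-{groups[j]} block (entry {i},{j})"
        raise ValueError(f"correlation not positive definite after repair: {block}")
    return y


@dataclass(frozen=True)
class CovariateSpec:
    """Individual-level covariate distributions (published cohort frequencies)."""

    race_levels: tuple[str, ...] = (
        "White non-Hispanic",
        "Hispanic/Latina",
        "African American",
        "Other",
    )
    race_freqs: tuple[float, ...] = (445 / 897, 238 / 897, 154 / 897, 60 / 897)
    education_levels: tuple[str, ...] = (
        "Less than high school",
        "High school or GED",
        "Some college/Associate's",
        "Bachelor's degree",
        "Graduate degree",
    )
    education_freqs: tuple[float, ...] = (
        137 / 897,
        166 / 897,
        208 / 897,
        196 / 897,
        190 / 897,
    )
    smoking_freq: float = 78 / 897
    shs_freq: float = 231 / 897
    male_freq: float = 459 / 897
    maternal_age: tuple[float, float] = (27.6, 6.2)  # mean, sd years
    cpss: tuple[float, float] = (18.6, 3.1)
    epds: tuple[float, float] = (4.3, 3.3)
    bmi: tuple[float, float] = (25.7, 5.6)  # continuous kg/m2, truncated [15, 55]
    days_to_peapod: tuple[float, float] = (1.6, 2.5)  # |Normal|, rounded, days
    lon: tuple[float, float] = (-104.9, 0.10)  # degrees; Denver metro
    lat: tuple[float, float] = (39.72, 0.08)


@dataclass(frozen=True)
class SpatialFieldSpec:
    """Stationary isotropic Gaussian random field for monitor simulation."""

    family: str = "exponential"  # exponential | spherical
    sill: float = 1.0  # partial sill (variance of the spatially structured part)
    range_km: float = 10.0
    nugget: float = 0.0
    mean: float = 0.0

    def covariance(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.family == "exponential":
            c = self.sill * np.exp(-d / self.range_km)
        elif self.family == "spherical":
            h = np.minimum(d / self.range_km, 1.0)
            c = self.sill * (1.0 - 1.5 * h + 0.5 * h**3)
        else:
            raise ValueError(f"unknown covariance family {self.family!r}")
        return c + self.nugget * (d == 0.0)


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``true_effects`` maps term names to effect sizes in outcome units per
    1 SD of the (product of) population-standardized predictor(s):
    ``"o3"`` is a main effect, ``"o3:temperature"`` an interaction.
    """

    n_dyads: int = 897
    exposures: list[ExposureSpec] = field(default_factory=default_exposures)
    correlation: CorrelationSpec | np.ndarray = field(default_factory=CorrelationSpec)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    true_effects: dict[str, float] = field(
        default_factory=lambda: {
            "o3": -6.4,
            "temperature": 13.1,
            "o3:temperature": -162.0,
        }
    )
    residual_sd: float = 450.0
    outcome_mean: float = 3208.0
    adiposity_mean: float = 9.0
    adiposity_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 2:
            raise ValueError("n_dyads must be >= 2")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        names = [e.name for e in self.exposures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate exposure names")

    def correlation_matrix(self) -> np.ndarray:
        """The copula target correlation (after nearest-PD repair)."""
        if isinstance(self.correlation, CorrelationSpec):
            return self.correlation.build(self.exposures)
        groups = [e.group for e in self.exposures]
        return nearest_correlation(np.asarray(self.correlation, float), groups=groups)

    def exposure_names(self) -> list[str]:
        return [e.name for e in self.exposures]


_CONTINUOUS_COVARIATES = ("maternal_age", "cpss", "epds", "bmi", "lon", "lat")


def _standardized_predictor(term: str, cohort: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Population-standardized column (or product of columns) for a truth term.

    Products are centered by their population mean (the copula correlation
    for an exposure pair, 0 otherwise), so planted effects never shift the
    cohort's mean outcome away from ``outcome_mean``; the shift would only
    be absorbed by the analysis intercept anyway.
    """
    spec = {e.name: e for e in config.exposures}
    cov = config.covariates
    parts = term.split(":")
    out = np.ones(len(cohort))
    for name in parts:
        if name in spec:
            m, s = spec[name].mean, spec[name].sd
        elif name in _CONTINUOUS_COVARIATES:
            m, s = getattr(cov, name)
        else:
            raise ValueError(f"unknown term in true_effects: {name!r}")
        out = out * (cohort[name].to_numpy() - m) / s
    if len(parts) == 2:
        names = config.exposure_names()
        if parts[0] in names and parts[1] in names:
            corr = config.correlation_matrix()
            out = out - corr[names.index(parts[0]), names.index(parts[1])]
    elif len(parts) > 2:
        raise ValueError(f"true_effects supports at most two-way products: {term!r}")
    return out


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one complete cohort table; bit-identical given config + seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_dyads
    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(config.exposures))) @ chol.T
    cohort = pd.DataFrame({"dyad_id": np.arange(1, n + 1)})
    for k, e in enumerate(config.exposures):
        cohort[e.name] = e.mean + e.sd * z[:, k]

    cov = config.covariates
    cohort["race_ethnicity"] = rng.choice(cov.race_levels, size=n, p=_norm(cov.race_freqs))
    cohort["education"] = rng.choice(cov.education_levels, size=n, p=_norm(cov.education_freqs))
    cohort["smoking"] = np.where(rng.random(n) < cov.smoking_freq, "Yes", "No")
    cohort["shs"] = np.where(rng.random(n) < cov.shs_freq, "Yes", "No")
    cohort["infant_sex"] = np.where(rng.random(n) < cov.male_freq, "Male", "Female")
    cohort["maternal_age"] = cov.maternal_age[0] + cov.maternal_age[1] * rng.standard_normal(n)
    cohort["cpss"] = cov.cpss[0] + cov.cpss[1] * rng.standard_normal(n)
    cohort["epds"] = cov.epds[0] + cov.epds[1] * rng.standard_normal(n)
    cohort["bmi"] = np.clip(cov.bmi[0] + cov.bmi[1] * rng.standard_normal(n), 15.0, 55.0)
    cohort["days_to_peapod"] = np.round(
        np.abs(cov.days_to_peapod[0] + cov.days_to_peapod[1] * rng.standard_normal(n))
    ).astype(int)
    cohort["lon"] = cov.lon[0] + cov.lon[1] * rng.standard_normal(n)
    cohort["lat"] = cov.lat[0] + cov.lat[1] * rng.standard_normal(n)

    # conception uniform over the 2009-2014 recruitment window; gestation
    # Normal(275, 13) days truncated to [196, 301] (pre- to post-term)
    start, end = date(2009, 1, 1), date(2014, 12, 31)
    span = (end - start).days
    conception_offsets = rng.integers(0, span + 1, size=n)
    gest = cov_trunc_normal(rng, 275.0, 13.0, 196.0, 301.0, n)
    cohort["conception_date"] = [start + timedelta(days=int(d)) for d in conception_offsets]
    cohort["delivery_date"] = [
        c + timedelta(days=int(round(g))) for c, g in zip(cohort["conception_date"], gest)
    ]
    cohort["season_of_conception"] = [
        _season(d.month) for d in cohort["conception_date"]
    ]
    cohort["year_of_conception"] = [d.year for d in cohort["conception_date"]]
    cohort["stratum"] = np.where(
        cohort["race_ethnicity"] == "White non-Hispanic", "NHW", "Other"
    )

    signal = np.zeros(n)
    for term, effect in config.true_effects.items():
        signal += effect * _standardized_predictor(term, cohort, config)
    noise = config.residual_sd * rng.standard_normal(n)
    bw = config.outcome_mean + signal + noise
    cohort["birth_weight"] = np.maximum(bw, 300.0)  # physiological floor, grams
    cohort["adiposity"] = np.clip(
        config.adiposity_mean + config.adiposity_sd * rng.standard_normal(n), 0.0, 100.0
    )
    return cohort


def _norm(p) -> np.ndarray:
    p = np.asarray(p, float)
    return p / p.sum()


def _season(month: int) -> str:
    return {12: "Winter", 1: "Winter", 2: "Winter", 3: "Spring", 4: "Spring",
            5: "Spring", 6: "Summer", 7: "Summer", 8: "Summer", 9: "Fall",
            10: "Fall", 11: "Fall"}[month]


def cov_trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Truncated-Normal draws via inverse CDF (deterministic in the stream)."""
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(rng.random(n), a, b, loc=mean, scale=sd)


def simulate_monitors(
    n_monitors: int,
    region: tuple[float, float, float, float],
    field_spec: SpatialFieldSpec,
    n_days: int,
    seed: int,
    start_date: date = date(2009, 1, 1),
) -> pd.DataFrame:
    """Daily readings at fixed monitor sites from a stationary Gaussian field.

    ``region`` is (xmin, xmax, ymin, ymax) in projected km. Days are i.i.d.
    replicates of the spatial field (no temporal correlation). Returns a
    long-format table (monitor_id, x_km, y_km, date, value).
    """
    if n_monitors < 1:
        raise ValueError("n_monitors must be >= 1")
    xmin, xmax, ymin, ymax = region
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounding box {region}")
    if field_spec.sill < 0 or field_spec.nugget < 0 or field_spec.range_km <= 0:
        raise ValueError("field_spec requires sill >= 0, nugget >= 0, range > 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(xmin, xmax, n_monitors)
    y = rng.uniform(ymin, ymax, n_monitors)
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    cov = field_spec.covariance(d) + 1e-12 * np.eye(n_monitors)
    chol = np.linalg.cholesky(cov)
    vals = field_spec.mean + rng.standard_normal((n_days, n_monitors)) @ chol.T
    dates = [start_date + timedelta(days=i) for i in range(n_days)]
    return pd.DataFrame(
        {
            "monitor_id": np.repeat(np.arange(n_monitors), n_days),
            "x_km": np.repeat(x, n_days),
            "y_km": np.repeat(y, n_days),
            "date": dates * n_monitors,
            "value": vals.T.ravel(),
        }
    )


def write_cohort(cohort: pd.DataFrame, path, config: SimulationConfig | None = None) -> None:
    """CSV with a YAML metadata sidecar recording the generating seed."""
    cohort.to_csv(path, index=False)
    if config is not None:
        meta = {
            "seed": int(config.seed),
            "n_dyads": int(config.n_dyads),
            "outcome_mean": float(config.outcome_mean),
            "residual_sd": float(config.residual_sd),
            "true_effects": {k: float(v) for k, v in config.true_effects.items()},
            "exposures": [dataclasses.asdict(e) for e in config.exposures],
        }
        with open(str(path) + ".meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["conception_date", "delivery_date"])
    for c in ("conception_date", "delivery_date"):
        df[c] = df[c].dt.date
    return df
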