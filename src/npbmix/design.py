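"""Model-ready matrices: standardization, indicator coding, interactions.

The regression stages all consume a :class:`DesignMatrices` bundle:

* ``y`` — outcome in native units (grams, or % fat mass), so coefficients
  read directly as grams per 1 SD of exposure;
* ``X`` — standardized exposure block (mean 0, sample SD 1, n-1 denominator);
* ``Z`` — pairwise interaction block: every unordered exposure pair once,
  plus every exposure x interaction-eligible-covariate product, all computed
  from the standardized/indicator columns;
* ``W`` — covariate block: intercept, reference-coded indicators,
  standardized continuous covariates, and longitude x latitude.

Interaction-eligible covariates are all W columns except the intercept and
the longitude x latitude product (itself an interaction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScaleRecord",
    "DesignMatrices",
    "standardize",
    "encode_covariates",
    "expand_interactions",
    "coefficient_of_variation",
    "build_design",
    "exposure_summary",
]

log = logging.getLogger(__name__)

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "race_ethnicity": (
        "White non-Hispanic",  # reference
        "Hispanic/Latina",
        "African American",
        "Other",
    ),
    "education": (
        "Less than high school",  # reference
        "High school or GED",
        "Some college/Associate's",
        "Bachelor's degree",
        "Graduate degree",
    ),
    "smoking": ("No", "Yes"),
    "shs": ("No", "Yes"),
    "infant_sex": ("Female", "Male"),
    "season_of_conception": ("Winter", "Spring", "Summer", "Fall"),
}

CONTINUOUS_COVARIATES = ("bmi", "maternal_age", "cpss", "epds")


@dataclass(frozen=True)
class ScaleRecord:
    """Center/scale used to standardize one column (native units)."""

    name: str
    center: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0 for {self.name!r}, got {self.scale}")

    def inverse(self, standardized) -> np.ndarray:
        return np.asarray(standardized, float) * self.scale + self.center


def standardize(column, name: str = "column") -> tuple[np.ndarray, ScaleRecord]:
    """(v - mean) / sample SD (n-1 denominator); errors on constant input."""
    v = np.asarray(column, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError(f"{name!r}: need a 1-d column with >= 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name!r}: non-finite values")
    sd = float(v.std(ddof=1))
    if sd == 0.0 or len(np.unique(v)) < 2:
        raise ValueError(f"cannot standardize constant column {name!r}")
    mean = float(v.mean())
    return (v - mean) / sd, ScaleRecord(name, mean, sd)


def coefficient_of_variation(mean: float, sd: float) -> int:
    """CV = 100 * sd / |mean|, rounded to the nearest whole percent."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return int(np.floor(100.0 * sd / abs(mean) + 0.5))


def encode_covariates(
    cohort: pd.DataFrame,
    outcome_choice: str = "birth_weight",
    include_sex: bool = True,
    include_geography: bool = True,
    exclude: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, ScaleRecord], list[str]]:
    """Covariate block W.

    Returns (W, scale records for continuous covariates, names of the
    interaction-eligible columns). Reference-coded indicators for
    race/ethnicity, education, smoking, second-hand smoke, infant sex,
    season and year of conception; standardized BMI, maternal age, CPSS,
    EPDS; standardized longitude, latitude and their product; standardized
    days-to-measurement appended only for the adiposity outcome.
    """
    if outcome_choice not in ("birth_weight", "adiposity"):
        raise ValueError(f"unknown outcome {outcome_choice!r}")
    w = pd.DataFrame(index=cohort.index)
    w["intercept"] = 1.0
    records: dict[str, ScaleRecord] = {}

    cat_cols = [c for c in CATEGORICAL_LEVELS if c not in exclude]
    if not include_sex:
        cat_cols = [c for c in cat_cols if c != "infant_sex"]
    for col in cat_cols:
        levels = CATEGORICAL_LEVELS[col]
        seen = set(cohort[col].unique())
        unknown = seen - set(levels)
        if unknown:
            raise ValueError(f"unseen level(s) {sorted(unknown)} in covariate {col!r}")
        for lev in levels[1:]:  # first level is the reference
            ind = (cohort[col] == lev).astype(float)
            if ind.nunique() < 2:
                log.info("dropping constant indicator %s=%s", col, lev)
                continue
            w[f"{col}[{lev}]"] = ind

    if "year_of_conception" not in exclude:
        years = sorted(cohort["year_of_conception"].unique())
        for yr in years[1:]:
            ind = (cohort["year_of_conception"] == yr).astype(float)
            if ind.nunique() < 2:
                continue
            w[f"year[{yr}]"] = ind

    for col in CONTINUOUS_COVARIATES:
        if col in exclude:
            continue
        std, rec = standardize(cohort[col], col)
        w[col] = std
        records[col] = rec

    if include_geography and "lon" not in exclude:
        lon, rec_lon = standardize(cohort["lon"], "lon")
        lat, rec_lat = standardize(cohort["lat"], "lat")
        w["lon"] = lon
        w["lat"] = lat
        w["lon_x_lat"] = lon * lat
        records["lon"] = rec_lon
        records["lat"] = rec_lat

    if outcome_choice == "adiposity":
        std, rec = standardize(cohort["days_to_peapod"].astype(float), "days_to_peapod")
        w["days_to_peapod"] = std
        records["days_to_peapod"] = rec

    eligible = [c for c in w.columns if c not in ("intercept", "lon_x_lat")]
    return w, records, eligible


def expand_interactions(x: pd.DataFrame, w_int: pd.DataFrame | None = None) -> pd.DataFrame:
    """All two-way products: exposure pairs once, then exposure x covariate.

    Columns are sorted lexicographically by term name ("a:b"), giving a
    deterministic order independent of input column order.
    """
    if not np.all(np.isfinite(x.to_numpy())):
        raise ValueError("exposure block contains non-finite values")
    cols: dict[str, np.ndarray] = {}
    for a, b in combinations(x.columns, 2):
        cols[f"{a}:{b}"] = x[a].to_numpy() * x[b].to_numpy()
    if w_int is not None and w_int.shape[1]:
        if not np.all(np.isfinite(w_int.to_numpy())):
            raise ValueError("covariate block contains non-finite values")
        for a in x.columns:
            for c in w_int.columns:
                cols[f"{a}:{c}"] = x[a].to_numpy() * w_int[c].to_numpy()
    z = pd.DataFrame(cols, index=x.index)
    return z[sorted(z.columns)]


@dataclass
class DesignMatrices:
    """Outcome vector plus exposure / interaction / covariate blocks."""

    y: np.ndarray
    x: pd.DataFrame
    z: pd.DataFrame
    w: pd.DataFrame
    outcome: str
    scale_records: dict[str, ScaleRecord] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def term_names(self) -> list[str]:
        return list(self.x.columns) + list(self.z.columns) + list(self.w.columns)

    def validate(self) -> None:
        n = self.n
        for name, block in (("X", self.x), ("Z", self.z), ("W", self.w)):
            if len(block) != n:
                raise ValueError(f"{name} has {len(block)} rows, outcome has {n}")
            if not np.all(np.isfinite(block.to_numpy())):
                raise ValueError(f"{name} contains non-finite values")
        xv = self.x.to_numpy()
        if xv.shape[1]:
            if np.abs(xv.mean(axis=0)).max() > 1e-8:
                raise ValueError("X columns are not centered")
            if np.abs(xv.std(axis=0, ddof=1) - 1.0).max() > 1e-8:
                raise ValueError("X columns do not have unit sample SD")
        names = self.term_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate term names across blocks")
        if self.w.shape[1]:
            if list(self.w.columns).count("intercept") != 1:
                raise ValueError("W must contain exactly one intercept column")
            wv = self.w.drop(columns="intercept").to_numpy()
            if wv.shape[1] and (wv.std(axis=0) == 0).any():
                raise ValueError("constant non-intercept column in W")

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({self.outcome: self.y}).to_csv(path / "y.csv", index=False)
        self.x.to_csv(path / "X.csv", index=False)
        self.z.to_csv(path / "Z.csv", index=False)
        self.w.to_csv(path / "W.csv", index=False)
        manifest = pd.DataFrame(
            [
                {"term": t, "block": b, "center": r.center if r else "", "scale": r.scale if r else ""}
                for t, b, r in [
                    *[(c, "X", self.scale_records.get(c)) for c in self.x.columns],
                    *[(c, "Z", None) for c in self.z.columns],
                    *[(c, "W", self.scale_records.get(c)) for c in self.w.columns],
                ]
            ]
        )
        manifest.to_csv(path / "terms.csv", index=False)


def build_design(
    cohort: pd.DataFrame,
    outcome_choice: str = "birth_weight",
    exposure_names: list[str] | None = None,
    interactions: str = "all",
    include_sex: bool = True,
    include_geography: bool = True,
    exclude_covariates: tuple[str, ...] = (),
) -> DesignMatrices:
    """Assemble DesignMatrices from a cohort table.

    ``interactions``: "all" (exposure pairs + exposure x covariate),
    "exposure_pairs" (pairs only), or "none".
    """
    if exposure_names is None:
        from .synthetic import default_exposures

        exposure_names = [e.name for e in default_exposures() if e.name in cohort.columns]
    if not exposure_names:
        raise ValueError("no exposure columns found")
    records: dict[str, ScaleRecord] = {}
    x = pd.DataFrame(index=cohort.index)
    for name in exposure_names:
        std, rec = standardize(cohort[name], name)
        x[name] = std
        records[name] = rec
    w, w_records, eligible = encode_covariates(
        cohort,
        outcome_choice,
        include_sex=include_sex,
        include_geography=include_geography,
        exclude=exclude_covariates,
    )
    records.update(w_records)
    if interactions == "all":
        z = expand_interactions(x, w[eligible])
    elif interactions == "exposure_pairs":
        z = expand_interactions(x, None)
    elif interactions == "none":
        z = pd.DataFrame(index=cohort.index)
    else:
        raise ValueError(f"unknown interactions mode {interactions!r}")
    y = cohort[outcome_choice].to_numpy(dtype=float)
    dm = DesignMatrices(y=y, x=x, z=z, w=w, outcome=outcome_choice, scale_records=records)
    dm.validate()
    return dm


def exposure_summary(cohort: pd.DataFrame, exposure_names: list[str] | None = None) -> pd.DataFrame:
    """Mean, SD, min, median, max, and CV (%) per exposure column."""
    if exposure_names is None:
        from .synthetic import default_exposures

        exposure_names = [e.name for e in default_exposures() if e.name in cohort.columns]
    rows = []
    for name in exposure_names:
        v = cohort[name].to_numpy(dtype=float)
        mean, sd = float(v.mean()), float(v.std(ddof=1))
        rows.append(
            {
                "exposure": name,
                "mean": mean,
                "sd": sd,
                "min": float(v.min()),
                "median": float(np.median(v)),
                "max": float(v.max()),
                "cv_pct": coefficient_of_variation(mean, sd),
            }
        )
    return pd.DataFrame(rows)
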