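"""Per-visit cohort table: loading, validation, standardisation, summaries.

One row per clinic visit: dog id, visit (V0 = before / V1 = after
therapeutic weight reduction), age in months, sex, breed group, coat
colour, sampling season, comorbidity status, body fat percentage (may be
missing) and hair cortisol concentration (HCC, pg/mg).

The outcome is analysed as standardised log(HCC); continuous predictors are
standardised too.  All standardisation state is kept in :class:`Scaler`
objects so that effects estimated on the standardised scale can be
translated back to pg/mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

CATEGORIES = {
    "sex": ["female", "male"],
    "breed_group": ["mixed", "CKCS", "pug", "retriever", "other"],
    "coat": ["light", "mixed", "dark"],
    "season": ["spring", "summer", "autumn", "winter"],
    "comorbidity": ["no", "yes"],
}
# reference level is the first entry of each list

# design-matrix columns contributed by each model term
TERM_COLUMNS = {
    "age": ["age_z"],
    "sex": ["sex_male"],
    "breed": ["breed_CKCS", "breed_pug", "breed_retriever", "breed_other"],
    "coat": ["coat_mixed", "coat_dark"],
    "season": ["season_summer", "season_autumn", "season_winter"],
    "comorbidity": ["comorbidity_yes"],
    "body_fat": ["body_fat_z"],
    "log_hcc": ["log_hcc_z"],
}

REQUIRED_COLUMNS = [
    "dog_id",
    "visit",
    "age",
    "sex",
    "breed_group",
    "coat",
    "season",
    "comorbidity",
    "body_fat",
    "hcc",
]


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class VisitRecord:
    dog_id: str
    visit: str
    age: float
    sex: str
    breed_group: str
    coat: str
    season: str
    comorbidity: str
    body_fat: Optional[float]
    hcc: float


@dataclass
class Scaler:
    """Centering/scaling state, optionally after a natural-log transform."""

    mean: float
    sd: float
    log_applied: bool = False

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    def transform(self, x):
        x = np.asarray(x, dtype=float)
        if self.log_applied:
            x = np.log(x)
        return (x - self.mean) / self.sd

    def inverse(self, z):
        x = np.asarray(z, dtype=float) * self.sd + self.mean
        return np.exp(x) if self.log_applied else x


def standardise(values, log_first: bool = False) -> Tuple[np.ndarray, Scaler]:
    """Standardise to mean 0, SD 1 over non-missing entries.

    With ``log_first`` the natural log is taken before centering (all
    values must then be positive).  Missing entries pass through as NaN.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if log_first:
        if np.any(x[obs] <= 0):
            raise ValueError("log transform requires strictly positive values")
        x = np.where(obs, np.log(np.where(obs, x, 1.0)), np.nan)
    m = float(np.mean(x[obs]))
    s = float(np.std(x[obs], ddof=1))
    if s <= 0 or not np.isfinite(s):
        raise ValueError("zero variance: cannot standardise")
    scaler = Scaler(mean=m, sd=s, log_applied=log_first)
    return (x - m) / s, scaler


def _validate(df: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")
    for i, row in df.iterrows():
        if row["visit"] not in ("V0", "V1"):
            raise CohortValidationError(f"row {i}: visit must be V0 or V1")
        for col, levels in CATEGORIES.items():
            if row[col] not in levels:
                raise CohortValidationError(
                    f"row {i}: unknown {col} level {row[col]!r} (expected {levels})"
                )
        if not (row["hcc"] > 0):
            raise CohortValidationError(f"row {i}: hcc must be > 0, got {row['hcc']}")
        bf = row["body_fat"]
        if not pd.isna(bf) and not (0 < bf < 100):
            raise CohortValidationError(f"row {i}: body_fat must be in (0, 100)")
    dup = df.duplicated(subset=["dog_id", "visit"])
    if dup.any():
        raise CohortValidationError(
            f"duplicate (dog_id, visit) pairs at rows {list(df.index[dup])}"
        )
    v1_dogs = set(df.loc[df["visit"] == "V1", "dog_id"])
    v0_dogs = set(df.loc[df["visit"] == "V0", "dog_id"])
    orphans = v1_dogs - v0_dogs
    if orphans:
        raise CohortValidationError(f"V1 visits without a V0 visit: {sorted(orphans)}")


class Cohort:
    """Validated cohort table plus standardisation state.

    ``df`` keeps the raw columns; :meth:`prepare` adds standardised and
    dummy-coded columns and records the scalers used, including the
    log-HCC scaler needed to express effects in pg/mg.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        df["dog_id"] = df["dog_id"].astype(str)
        _validate(df)
        self.df = df
        self.scalers: Dict[str, Scaler] = {}
        self._prepared = False

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records: List[VisitRecord]) -> "Cohort":
        return cls(pd.DataFrame([r.__dict__ for r in records]))

    @property
    def records(self) -> List[VisitRecord]:
        out = []
        for _, row in self.df.iterrows():
            bf = row["body_fat"]
            out.append(
                VisitRecord(
                    dog_id=row["dog_id"],
                    visit=row["visit"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    breed_group=row["breed_group"],
                    coat=row["coat"],
                    season=row["season"],
                    comorbidity=row["comorbidity"],
                    body_fat=None if pd.isna(bf) else float(bf),
                    hcc=float(row["hcc"]),
                )
            )
        return out

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_dogs(self) -> int:
        return self.df["dog_id"].nunique()

    # -- standardisation and design columns --------------------------------

    def prepare(self) -> "Cohort":
        """Standardise continuous variables and add dummy columns in place.

        The full observed vector (both visits pooled) is standardised, and
        missing body fat stays missing: nothing is imputed here.
        """
        if self._prepared:
            return self
        df = self.df
        df["age_z"], self.scalers["age"] = standardise(df["age"].to_numpy())
        df["log_hcc_z"], self.scalers["log_hcc"] = standardise(
            df["hcc"].to_numpy(), log_first=True
        )
        bf = df["body_fat"].to_numpy(dtype=float)
        if np.sum(~np.isnan(bf)) >= 2 and np.nanstd(bf) > 0:
            df["body_fat_z"], self.scalers["body_fat"] = standardise(bf)
        else:
            df["body_fat_z"] = np.nan
        for var, levels in CATEGORIES.items():
            prefix = "breed" if var == "breed_group" else var
            for lev in levels[1:]:
                df[f"{prefix}_{lev}"] = (df[var] == lev).astype(float)
        self._prepared = True
        return self

    def design_matrix(self, terms: List[str]) -> Tuple[np.ndarray, List[str]]:
        """Intercept + one column per non-reference level of each term."""
        self.prepare()
        cols = ["intercept"]
        for t in terms:
            if t not in TERM_COLUMNS:
                raise KeyError(f"unknown model term {t!r}")
            cols.extend(TERM_COLUMNS[t])
        mat = np.column_stack(
            [np.ones(len(self.df))]
            + [self.df[c].to_numpy(dtype=float) for c in cols[1:]]
        )
        return mat, cols

    def group_index(self) -> Tuple[np.ndarray, List[str]]:
        """Per-row dog index and the ordered dog-id list."""
        dogs = sorted(self.df["dog_id"].unique())
        lookup = {d: i for i, d in enumerate(dogs)}
        return self.df["dog_id"].map(lookup).to_numpy(), dogs


def load_cohort(path) -> Cohort:
    """Read and validate a cohort CSV (see :data:`REQUIRED_COLUMNS`)."""
    return Cohort.from_csv(path)


# ---------------------------------------------------------------------------
# descriptive summary (baseline-characteristics table)
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    n_dogs: int
    n_visits: int
    n_single: int
    n_paired: int
    continuous: pd.DataFrame  # variable, stratum, n, mean, sd, median, min, max
    categorical: pd.DataFrame  # variable, level, stratum, n, pct


def _cont_rows(df, var, stratum, rows):
    x = df[var].dropna().to_numpy(dtype=float)
    if x.size == 0:
        return
    rows.append(
        {
            "variable": var,
            "stratum": stratum,
            "n": x.size,
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "sd_defined": x.size > 1,
            "median": float(np.median(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }
    )


def summarise_cohort(cohort: Cohort) -> CohortSummary:
    """Baseline summary stratified by sample group and visit.

    Continuous variables: mean (SD) and median (range) for every stratum in
    {all samples, V0 all dogs, V0 single-sample dogs, V0 paired dogs, V1
    paired dogs}.  Categorical variables: n (%) per level, by dog at V0.
    """
    df = cohort.df.copy()
    df["log_hcc"] = np.log(df["hcc"])
    paired_ids = set(df.loc[df["visit"] == "V1", "dog_id"])
    df["group"] = np.where(df["dog_id"].isin(paired_ids), "paired", "single")

    strata = {
        "all_samples": df,
        "V0_all": df[df["visit"] == "V0"],
        "V0_single": df[(df["visit"] == "V0") & (df["group"] == "single")],
        "V0_paired": df[(df["visit"] == "V0") & (df["group"] == "paired")],
        "V1_paired": df[(df["visit"] == "V1") & (df["group"] == "paired")],
    }
    cont_rows: list = []
    for name, sub in strata.items():
        for var in ("age", "body_fat", "hcc", "log_hcc"):
            _cont_rows(sub, var, name, cont_rows)

    cat_rows = []
    v0 = df[df["visit"] == "V0"]
    for name, sub in (("all_dogs", v0), ("single", strata["V0_single"]), ("paired", strata["V0_paired"])):
        for var, levels in CATEGORIES.items():
            counts = sub[var].value_counts()
            total = len(sub)
            for lev in levels:
                n = int(counts.get(lev, 0))
                cat_rows.append(
                    {
                        "variable": var,
                        "level": lev,
                        "stratum": name,
                        "n": n,
                        "pct": 100.0 * n / total if total else np.nan,
                    }
                )

    return CohortSummary(
        n_dogs=cohort.n_dogs,
        n_visits=len(df),
        n_single=int((v0["group"] == "single").sum()),
        n_paired=int((v0["group"] == "paired").sum()),
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
    )
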