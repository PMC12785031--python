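"""Body-condition indices for fur seal pups.

Two indices are computed from field biometrics (mass in kg, nose-to-tail
length in cm):

* **BCI1** — mass divided by length (kg/cm); a crude but long-used ratio
  index.
* **BCI2** — observed mass divided by *expected* mass, where expected mass
  comes from an ordinary least-squares regression of log mass on log length
  (a power-law allometry ``mass = exp(a) * length**b``). BCI2 > 1 means a
  pup is heavier than expected for its length, i.e. in better-than-expected
  condition.

The allometry reference set defaults to the pooled data — all pups at all
colonies in all years — so BCI2 compares every pup against the study-wide
mass-at-length relationship. Over that exact reference set the log
residuals sum to zero, so the geometric mean of BCI2 is exactly 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MASS_WINDOW_KG",
    "LENGTH_WINDOW_CM",
    "AllometryFit",
    "bci1",
    "fit_allometry",
    "expected_mass",
    "bci2",
    "add_condition_indices",
    "classify_condition",
    "load_biometrics",
]

logger = logging.getLogger(__name__)

# Plausibility windows padded outward from the observed field ranges
# (masses ~2-13 kg, late-January pups). Records outside are rejected on
# load with a logged warning, never silently.
MASS_WINDOW_KG = (1.0, 20.0)
LENGTH_WINDOW_CM = (40.0, 120.0)

BIOMETRIC_COLUMNS = ["colony", "year", "day", "sex", "mass_kg", "length_cm"]


@dataclass(frozen=True)
class AllometryFit:
    """OLS fit of log(mass) on log(length): log ExpM = a + b log Length."""

    intercept: float
    slope: float
    n: int
    residual_sd: float

    def expected_mass(self, length_cm):
        """Expected mass (kg) at the given length(s) under the power law."""
        return np.exp(self.intercept + self.slope * np.log(length_cm))


def bci1(mass_kg: float, length_cm: float) -> float:
    """Mass/length ratio index (kg/cm)."""
    if length_cm <= 0:
        raise ValueError(f"length must be positive, got {length_cm}")
    if mass_kg <= 0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    return mass_kg / length_cm


def fit_allometry(records: pd.DataFrame) -> AllometryFit:
    """Least-squares power-law allometry from pooled pup biometrics.

    ``records`` needs columns ``mass_kg`` and ``length_cm``. Requires at
    least 3 records spanning at least 2 distinct lengths (otherwise the
    log-log design is singular or saturated by noise).
    """
    mass = np.asarray(records["mass_kg"], dtype=float)
    length = np.asarray(records["length_cm"], dtype=float)
    if len(mass) < 3:
        raise ValueError(f"allometry fit needs >= 3 records, got {len(mass)}")
    if np.unique(length).size < 2:
        raise ValueError("all lengths identical: log-log design is singular")
    x = np.log(length)
    y = np.log(mass)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - 2, 1)
    return AllometryFit(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        n=len(y),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


def expected_mass(length_cm, fit: AllometryFit):
    """Expected mass (kg) for a pup of the given length under ``fit``."""
    return fit.expected_mass(length_cm)


def bci2(mass_kg: float, length_cm: float, fit: AllometryFit) -> float:
    """Observed over expected mass; > 1 means better-than-expected condition."""
    return mass_kg / float(fit.expected_mass(length_cm))


def add_condition_indices(
    records: pd.DataFrame, fit: AllometryFit | None = None
) -> tuple[pd.DataFrame, AllometryFit]:
    """Attach bci1, expected_mass and bci2 columns to a biometric table.

    When ``fit`` is None the allometry is fitted to ``records`` itself
    (the pooled all-colonies-all-years reference). Pass a fit to score
    records against a different reference population.
    """
    if fit is None:
        fit = fit_allometry(records)
    out = records.copy()
    out["bci1"] = out["mass_kg"] / out["length_cm"]
    out["expected_mass"] = fit.expected_mass(out["length_cm"].to_numpy(dtype=float))
    out["bci2"] = out["mass_kg"] / out["expected_mass"]
    return out, fit


def classify_condition(condition_records: pd.DataFrame) -> pd.DataFrame:
    """Per colony-year mean BCI2 and better/worse-than-expected status.

    Status is ``better`` iff the arithmetic mean of BCI2 in the group is
    strictly greater than 1 (a mean of exactly 1 is ``worse``).
    """
    if "bci2" not in condition_records.columns:
        raise ValueError("records lack a bci2 column; run add_condition_indices")
    if len(condition_records) == 0:
        raise ValueError("empty record set")
    grouped = (
        condition_records.groupby(["colony", "year"], sort=True)["bci2"]
        .agg(mean_bci2="mean", n="size")
        .reset_index()
    )
    grouped["status"] = np.where(grouped["mean_bci2"] > 1.0, "better", "worse")
    return grouped


def load_biometrics(path) -> pd.DataFrame:
    """Read and validate a pup biometric CSV.

    Required columns: colony, year, day, sex, mass_kg, length_cm. ``day``
    is the day of measurement counted from 1 January of the (later)
    season year, so late-January surveys sit around day 20-40. Records
    with non-positive or implausible mass/length are dropped with a
    logged warning; sex labels are normalised to male/female/unknown.
    """
    df = pd.read_csv(path)
    missing = [c for c in BIOMETRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"biometric table missing columns: {missing}")
    return validate_biometrics(df)


def validate_biometrics(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["sex"] = (
        df["sex"].astype(str).str.lower().str.strip().replace({"m": "male", "f": "female"})
    )
    df.loc[~df["sex"].isin(["male", "female"]), "sex"] = "unknown"
    ok = (
        df["mass_kg"].between(*MASS_WINDOW_KG)
        & df["length_cm"].between(*LENGTH_WINDOW_CM)
        & df["colony"].astype(str).str.len().gt(0)
        & df["year"].notna()
    )
    n_bad = int((~ok).sum())
    if n_bad:
        bad = df.loc[~ok, ["colony", "year", "mass_kg", "length_cm"]]
        logger.warning(
            "rejected %d biometric record(s) outside plausibility windows "
            "mass %s kg / length %s cm: %s",
            n_bad,
            MASS_WINDOW_KG,
            LENGTH_WINDOW_CM,
            bad.head(10).to_dict("records"),
        )
    return df.loc[ok].reset_index(drop=True)


def geometric_mean_bci2(condition_records: pd.DataFrame) -> float:
    """Geometric mean of BCI2; equals 1 over the allometry fitting set."""
    vals = np.asarray(condition_records["bci2"], dtype=float)
    return float(math.exp(np.mean(np.log(vals))))
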