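"""Linear models of pup mass and condition with AICc selection.

Pan-colony models regress pup mass (or BCI1) on Year (categorical), Sex,
Colony and Day of measurement (numeric), with optional pairwise
interactions. Candidate structures are ranked by the small-sample Akaike
criterion

    AICc = -2 logLik + 2k + 2k(k+1) / (n - k - 1) ,

where the Gaussian log-likelihood has the error variance profiled out and
k counts the mean parameters plus that variance.

Per-colony models drop Colony and, because measurement days span too few
values within single colonies to identify a day slope, hold the Day
coefficient fixed at the pan-colony value: the response is offset by
``-day_effect * (day - reference_day)`` before refitting Year/Sex terms.
The resulting "standardised" yearly means are predictions at the reference
day under a 50/50 sex mix, comparable across years even when surveys
happened earlier or later in the season.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "FittedModel",
    "StandardisedSeries",
    "fit_linear_model",
    "aicc",
    "select_model",
    "candidate_specs",
    "standardise_by_day",
    "inter_survey_change",
    "pair_mass_with_abundance_change",
    "mass_abundance_correlation",
]

logger = logging.getLogger(__name__)

TERMS = ("Year", "Sex", "Colony", "Day")

_TERM_FORMULA = {
    "Year": "C(year)",
    "Sex": "C(sex)",
    "Colony": "C(colony)",
    "Day": "day",
}

_RESPONSE_COLUMN = {"mass": "mass_kg", "bci1": "bci1"}


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model structure: response, main effects, interactions.

    Year enters as a categorical factor (its effect on pup mass is not
    monotone), Day as a numeric covariate; interactions are only allowed
    between included main effects. Treatment coding uses the alphabetically
    first colony, the earliest year and female sex as baselines.
    """

    response: str = "mass"
    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.response not in _RESPONSE_COLUMN:
            raise ValueError(f"response must be one of {set(_RESPONSE_COLUMN)}")
        bad = [t for t in self.terms if t not in TERMS]
        if bad:
            raise ValueError(f"unknown terms {bad}; allowed: {TERMS}")
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(
                    f"interaction {a}:{b} references a term not in {self.terms}"
                )

    def formula(self) -> str:
        rhs = [_TERM_FORMULA[t] for t in self.terms]
        rhs += [f"{_TERM_FORMULA[a]}:{_TERM_FORMULA[b]}" for a, b in self.interactions]
        return f"{_RESPONSE_COLUMN[self.response]} ~ " + (" + ".join(rhs) or "1")

    def label(self) -> str:
        parts = list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]
        return f"{self.response} ~ " + (" + ".join(parts) or "1")


@dataclass(frozen=True)
class FittedModel:
    """An OLS fit of a :class:`ModelSpec` with its AICc bookkeeping.

    ``k`` counts the estimated mean parameters plus the error variance.
    """

    spec: ModelSpec
    n: int
    k: int
    rss: float
    adj_r2: float
    loglik: float
    aicc: float
    coefficients: pd.DataFrame = field(repr=False)
    result: object = field(repr=False, default=None, compare=False)


@dataclass(frozen=True)
class StandardisedSeries:
    """Per-year day-standardised means for one colony and response."""

    colony: str
    response: str
    reference_day: int
    day_effect: float
    years: tuple[int, ...]
    means: tuple[float, ...]
    ses: tuple[float, ...]
    pct_changes: tuple[float, ...]


def _prepare(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = records
    if "Sex" in spec.terms and "sex" in df.columns:
        df = df[df["sex"].isin(["male", "female"])]
    col = _RESPONSE_COLUMN[spec.response]
    if col not in df.columns:
        raise ValueError(f"records lack response column {col!r}")
    return df.reset_index(drop=True)


def _check_rank(result) -> None:
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # QR with pivoting: trailing pivots index the aliased columns.
        from scipy.linalg import qr

        _, _, piv = qr(exog, pivoting=True, mode="economic")
        names = np.array(result.model.exog_names)
        aliased = sorted(names[piv[rank:]])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_linear_model(spec: ModelSpec, records: pd.DataFrame) -> FittedModel:
    """OLS fit of ``spec`` with coefficient table and AICc.

    Unknown-sex pups are excluded whenever Sex is among the terms. A
    rank-deficient design (aliased factor levels) raises, naming the
    offending columns.
    """
    df = _prepare(records, spec)
    result = smf.ols(spec.formula(), data=df).fit()
    _check_rank(result)
    n = int(result.nobs)
    k = len(result.params) + 1  # +1 for the error variance
    ci = result.conf_int(alpha=0.05)
    coefs = pd.DataFrame(
        {
            "coef": result.params,
            "se": result.bse,
            "ci_lower": ci[0],
            "ci_upper": ci[1],
            "p": result.pvalues,
        }
    )
    fitted = FittedModel(
        spec=spec,
        n=n,
        k=k,
        rss=float(result.ssr),
        adj_r2=float(result.rsquared_adj),
        loglik=float(result.llf),
        aicc=float("nan"),
        coefficients=coefs,
        result=result,
    )
    # the fit itself is valid even when n is too small for the AICc
    # correction; the criterion is then NaN and select_model annotates it
    return replace(
        fitted, aicc=aicc(fitted) if n - k - 1 > 0 else float("nan")
    )


def aicc(fitted: FittedModel) -> float:
    """Small-sample AICc of a fitted model (Gaussian profiled likelihood)."""
    n, k = fitted.n, fitted.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, k={k}")
    return -2.0 * fitted.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def candidate_specs(
    response: str = "mass",
    include_interactions: bool = True,
    always_include: Sequence[str] = (),
) -> list[ModelSpec]:
    """All main-effect subsets of {Year, Sex, Colony, Day}, optionally with
    pairwise interactions among included terms.

    Interaction sets are limited to one pair per spec — richer structures
    would carry large numbers of parameters (Year alone contributes one
    level per survey year) and invite overfitting.
    """
    specs: list[ModelSpec] = []
    for r in range(len(TERMS) + 1):
        for terms in itertools.combinations(TERMS, r):
            if any(t not in terms for t in always_include):
                continue
            specs.append(ModelSpec(response, terms))
            if include_interactions and len(terms) >= 2:
                for pair in itertools.combinations(terms, 2):
                    specs.append(ModelSpec(response, terms, (pair,)))
    return specs


def select_model(
    candidates: Sequence[ModelSpec],
    records: pd.DataFrame,
    max_params: int = 60,
) -> tuple[FittedModel, pd.DataFrame]:
    """Fit every candidate and return the minimum-AICc model plus ranking.

    Candidates whose fit fails, or whose parameter count exceeds
    ``max_params``, are annotated in the ranking table rather than
    aborting selection. Exact AICc ties go to the earlier candidate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate specs")
    rows = []
    fits: list[FittedModel | None] = []
    for i, spec in enumerate(candidates):
        try:
            fm = fit_linear_model(spec, records)
            if fm.k > max_params:
                raise ValueError(f"k={fm.k} exceeds max_params={max_params}")
        except Exception as exc:  # annotated, not fatal
            fits.append(None)
            rows.append(
                {"order": i, "model": spec.label(), "k": np.nan, "n": np.nan,
                 "aicc": np.nan, "note": str(exc)}
            )
            continue
        fits.append(fm)
        note = "" if np.isfinite(fm.aicc) else "AICc undefined (n too small)"
        rows.append(
            {"order": i, "model": spec.label(), "k": fm.k, "n": fm.n,
             "aicc": fm.aicc, "note": note}
        )
    ranking = pd.DataFrame(rows)
    if ranking["aicc"].isna().all():
        raise ValueError("no candidate could be fitted")
    best_aicc = ranking["aicc"].min()
    ties = ranking.index[ranking["aicc"] == best_aicc]
    if len(ties) > 1:
        logger.info("AICc tie among %d candidates; keeping the first", len(ties))
    best = fits[int(ties[0])]
    ranking["delta_aicc"] = ranking["aicc"] - best_aicc
    ranking = ranking.sort_values("aicc", kind="stable").reset_index(drop=True)
    return best, ranking


def standardise_by_day(
    spec: ModelSpec,
    records: pd.DataFrame,
    fixed_day_effect: float,
    reference_day: int | None = None,
) -> StandardisedSeries:
    """Per-colony yearly means standardised to a common measurement day.

    The Day coefficient is constrained to ``fixed_day_effect`` (from the
    pan-colony model) by offsetting the response, then a Year(+Sex) model
    is refit. Standardised means are predictions at ``reference_day``
    under a 50/50 sex mix. ``spec`` must not contain Colony or Day;
    ``records`` must come from a single colony.
    """
    colonies = records["colony"].unique()
    if len(colonies) != 1:
        raise ValueError(f"expected a single colony, got {list(colonies)}")
    if "Colony" in spec.terms or "Day" in spec.terms:
        raise ValueError("per-colony spec must exclude Colony and Day terms")
    if "Year" not in spec.terms:
        raise ValueError("per-colony spec needs a Year term")
    df = _prepare(records, spec)
    if reference_day is None:
        reference_day = int(np.median(df["day"]))
    dmin, dmax = df["day"].min(), df["day"].max()
    if not dmin <= reference_day <= dmax:
        logger.warning(
            "reference day %s outside observed range [%s, %s]: extrapolating",
            reference_day, dmin, dmax,
        )
    col = _RESPONSE_COLUMN[spec.response]
    df = df.copy()
    df[col] = df[col] - fixed_day_effect * (df["day"] - reference_day)
    result = smf.ols(spec.formula(), data=df).fit()

    years = sorted(df["year"].unique())
    means, ses = [], []
    exog_names = result.model.exog_names
    for yr in years:
        # prediction vector at this year, balanced sex mix
        vec = np.zeros(len(exog_names))
        for j, name in enumerate(exog_names):
            if name == "Intercept":
                vec[j] = 1.0
            elif name == f"C(year)[T.{yr}]":
                vec[j] = 1.0
            elif name.startswith("C(sex)[T."):
                vec[j] = 0.5
        means.append(float(vec @ result.params.to_numpy()))
        ses.append(float(np.sqrt(vec @ result.cov_params().to_numpy() @ vec)))
    changes = inter_survey_change(means)
    return StandardisedSeries(
        colony=str(colonies[0]),
        response=spec.response,
        reference_day=int(reference_day),
        day_effect=float(fixed_day_effect),
        years=tuple(int(y) for y in years),
        means=tuple(means),
        ses=tuple(ses),
        pct_changes=tuple(changes),
    )


def inter_survey_change(means: Sequence[float]) -> list[float]:
    """Consecutive-survey percent changes of standardised means."""
    if len(means) < 2:
        raise ValueError("need at least two surveyed years")
    out = []
    for a, b in zip(means[:-1], means[1:]):
        if a <= 0:
            raise ValueError(f"non-positive standardised mean {a}")
        out.append(100.0 * (b - a) / a)
    return out


def pair_mass_with_abundance_change(
    mass_by_year: Mapping[int, float], abundance_by_year: Mapping[int, float]
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Align standardised mass at survey t with the abundance change from
    the previous survey (abundance_t - abundance_{t-1}).

    The first survey of a colony has no preceding estimate and is dropped.
    """
    surveys = sorted(set(mass_by_year) & set(abundance_by_year))
    mass, dabund, years = [], [], []
    for prev, cur in zip(surveys[:-1], surveys[1:]):
        mass.append(mass_by_year[cur])
        dabund.append(abundance_by_year[cur] - abundance_by_year[prev])
        years.append(cur)
    return np.asarray(mass, float), np.asarray(dabund, float), years


def mass_abundance_correlation(
    mass: Sequence[float], abundance_change: Sequence[float]
) -> dict:
    """Pearson correlation (r, two-sided p from the t transform, n)."""
    x = np.asarray(mass, float)
    y = np.asarray(abundance_change, float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 paired surveys")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a series")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x)}
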