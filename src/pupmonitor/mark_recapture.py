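"""Mark-recapture abundance estimation for fur seal pup colonies.

A single marking event (M pups marked) is followed by Q replicate recapture
counts. Each replicate i records the total number of pups seen (Ci) and how
many of those carried a mark (Ri), and yields a Chapman-corrected ("modified")
Petersen estimate

    Pi = (M + 1)(Ci + 1) / (Ri + 1) - 1 .

The colony-year estimate P is the arithmetic mean of the Q replicate
estimates, with SE computed from their spread:

    SE = sqrt( (1 / (Q (Q - 1))) * sum_i (Pi - P)^2 ) ,

i.e. the sample standard deviation of the Pi divided by sqrt(Q). Tag loss
between marking and recapture is assumed to be zero (recaptures follow
marking by about a day), and ambiguous mark/unmark sightings are simply
absent from Ci — no correction terms are applied.

Dead pups counted during marking are kept out of the mark-recapture
arithmetic and summarised separately as a percentage of total (live + dead)
pups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "RecaptureSession",
    "AbundanceEstimate",
    "MortalityRecord",
    "petersen_replicate",
    "petersen_mean",
    "dead_pup_fraction",
    "period_percent_change",
    "compound_percent_changes",
    "annualized_percent_change",
    "estimate_sessions",
    "read_sessions_csv",
    "estimates_to_frame",
]


@dataclass(frozen=True)
class RecaptureSession:
    """One colony-year marking event with its replicate recapture counts.

    ``replicates`` is an ordered list of ``(total_count, marked_count)``
    pairs, one per recapture replicate.
    """

    colony: str
    year: int
    marked: int
    replicates: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.marked < 0:
            raise ValueError(f"marked must be >= 0, got {self.marked}")
        if len(self.replicates) < 1:
            raise ValueError(
                f"{self.colony} {self.year}: session needs at least one replicate"
            )
        reps = tuple((int(c), int(r)) for c, r in self.replicates)
        for i, (ci, ri) in enumerate(reps):
            if ci < 0 or ri < 0:
                raise ValueError(
                    f"{self.colony} {self.year} replicate {i}: negative count"
                )
            if ri > ci:
                raise ValueError(
                    f"{self.colony} {self.year} replicate {i}: marked count "
                    f"{ri} exceeds total count {ci}"
                )
            if ri > self.marked:
                raise ValueError(
                    f"{self.colony} {self.year} replicate {i}: marked count "
                    f"{ri} exceeds number marked {self.marked}"
                )
        object.__setattr__(self, "replicates", reps)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class AbundanceEstimate:
    """Mean Petersen estimate for one colony-year with normal-theory CI.

    ``se``/``ci_lower``/``ci_upper`` are ``None`` for single-replicate
    sessions, where the between-replicate spread is undefined (reporting
    zero would overstate certainty).
    """

    colony: str
    year: int
    mean_estimate: float
    se: float | None
    ci_lower: float | None
    ci_upper: float | None
    n_replicates: int
    replicate_estimates: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class MortalityRecord:
    """Dead-pup count and its share of total (live + dead) pups."""

    colony: str
    year: int
    dead_count: int
    live_estimate: float
    dead_fraction_pct: float


def petersen_replicate(marked: int, total_count: int, marked_count: int) -> float:
    """Chapman-corrected Petersen estimate from one recapture replicate.

    The +1 corrections reduce small-sample bias and keep the estimate
    finite when no marked pups are resighted (``marked_count`` = 0).
    """
    if marked < 0 or total_count < 0 or marked_count < 0:
        raise ValueError("counts must be non-negative")
    if marked_count > min(marked, total_count):
        raise ValueError(
            f"marked_count {marked_count} exceeds min(marked={marked}, "
            f"total_count={total_count}): inconsistent field data"
        )
    return (marked + 1) * (total_count + 1) / (marked_count + 1) - 1.0


def petersen_mean(
    session: RecaptureSession, ci_level: float = 0.95, ci_method: str = "t"
) -> AbundanceEstimate:
    """Mean-of-replicates abundance estimate with SE and CI.

    The CI is ``P ± q * SE`` truncated below at 0, with q a Student-t
    quantile on Q - 1 degrees of freedom by default: the SE comes from
    only Q (typically five) replicate estimates, and a plain normal
    quantile would undercover true abundance noticeably at that sample
    size. Pass ``ci_method="normal"`` for the z-quantile interval. With a
    single replicate the SE and CI are unavailable (``None``), not zero.
    """
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    if ci_method not in ("t", "normal"):
        raise ValueError(f"ci_method must be 't' or 'normal', got {ci_method!r}")
    pis = tuple(
        petersen_replicate(session.marked, ci, ri) for ci, ri in session.replicates
    )
    q = len(pis)
    mean = sum(pis) / q
    if q == 1:
        return AbundanceEstimate(
            session.colony, session.year, mean, None, None, None, q, pis
        )
    se = math.sqrt(sum((p - mean) ** 2 for p in pis) / (q * (q - 1)))
    if ci_method == "t":
        crit = stats.t.ppf(0.5 + ci_level / 2, q - 1)
    else:
        crit = stats.norm.ppf(0.5 + ci_level / 2)
    lo = max(0.0, mean - crit * se)
    hi = mean + crit * se
    return AbundanceEstimate(session.colony, session.year, mean, se, lo, hi, q, pis)


def dead_pup_fraction(dead_count: int, live_estimate: float) -> float:
    """Dead pups as a percentage of total pups (live + dead)."""
    if dead_count < 0 or live_estimate < 0:
        raise ValueError("counts must be non-negative")
    total = dead_count + live_estimate
    if total == 0:
        raise ValueError("empty colony-year record: no live or dead pups")
    return 100.0 * dead_count / total


def period_percent_change(start_value: float, end_value: float) -> float:
    """Percent change between two survey values, 100 * (end - start) / start."""
    if start_value <= 0:
        raise ValueError(f"start_value must be positive, got {start_value}")
    if end_value < 0:
        raise ValueError(f"end_value must be non-negative, got {end_value}")
    return 100.0 * (end_value - start_value) / start_value


def compound_percent_changes(changes: Sequence[float]) -> float:
    """Compose consecutive period percent changes multiplicatively.

    Two period declines of -78.7% and -20.5% compound to an overall change
    of 100 * (0.213 * 0.795 - 1) = -83.1%, not to their sum.
    """
    factor = 1.0
    for c in changes:
        if c <= -100:
            raise ValueError(f"percent change must exceed -100, got {c}")
        factor *= 1.0 + c / 100.0
    return 100.0 * (factor - 1.0)


def annualized_percent_change(
    start_value: float, end_value: float, n_years: int
) -> float:
    """Geometric (compound) annual average percent change over ``n_years``."""
    if start_value <= 0 or end_value <= 0:
        raise ValueError("values must be positive")
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    return 100.0 * ((end_value / start_value) ** (1.0 / n_years) - 1.0)


# ---------------------------------------------------------------------------
# Tabular interface


SESSION_COLUMNS = [
    "colony",
    "year",
    "marked",
    "replicate_id",
    "total_count",
    "marked_count",
]


def read_sessions_csv(path) -> list[RecaptureSession]:
    """Read a recapture-session table (one row per replicate) into sessions.

    Required columns: colony, year, marked, replicate_id, total_count,
    marked_count. Invariant violations (e.g. Ri > Ci) raise with the
    offending colony-year named.
    """
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session table missing columns: {missing}")
    return sessions_from_frame(df)


def sessions_from_frame(df: pd.DataFrame) -> list[RecaptureSession]:
    sessions = []
    for (colony, year), grp in df.groupby(["colony", "year"], sort=True):
        marked = grp["marked"].unique()
        if len(marked) != 1:
            raise ValueError(
                f"{colony} {year}: inconsistent 'marked' across replicates: {marked}"
            )
        grp = grp.sort_values("replicate_id")
        reps = tuple(
            (int(c), int(r))
            for c, r in zip(grp["total_count"], grp["marked_count"])
        )
        sessions.append(RecaptureSession(str(colony), int(year), int(marked[0]), reps))
    return sessions


def estimate_sessions(
    sessions: Sequence[RecaptureSession],
    ci_level: float = 0.95,
    ci_method: str = "t",
) -> list[AbundanceEstimate]:
    """Mean Petersen estimate for every session."""
    return [petersen_mean(s, ci_level, ci_method) for s in sessions]


def estimates_to_frame(estimates: Sequence[AbundanceEstimate]) -> pd.DataFrame:
    """Abundance estimates as a tidy table (one row per colony-year)."""
    return pd.DataFrame(
        {
            "colony": [e.colony for e in estimates],
            "year": [e.year for e in estimates],
            "mean_estimate": [e.mean_estimate for e in estimates],
            "se": [e.se for e in estimates],
            "ci_lower": [e.ci_lower for e in estimates],
            "ci_upper": [e.ci_upper for e in estimates],
            "n_replicates": [e.n_replicates for e in estimates],
        }
    )


def mortality_records(
    dead_counts: pd.DataFrame, estimates: Sequence[AbundanceEstimate]
) -> list[MortalityRecord]:
    """Join dead-pup counts with live abundance estimates by colony-year.

    ``dead_counts`` needs columns colony, year, dead_count. Colony-years
    without a matching live estimate are skipped.
    """
    live = {(e.colony, e.year): e.mean_estimate for e in estimates}
    out = []
    for row in dead_counts.itertuples(index=False):
        key = (str(row.colony), int(row.year))
        if key not in live:
            continue
        dead = int(row.dead_count)
        out.append(
            MortalityRecord(
                key[0], key[1], dead, live[key], dead_pup_fraction(dead, live[key])
            )
        )
    return out
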