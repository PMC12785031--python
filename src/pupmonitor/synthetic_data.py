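"""Synthetic colony-monitoring datasets with known ground truth.

Emulates a multi-decade pinniped pup monitoring programme: each colony has
a deterministic "true" pup-abundance trajectory (exponential long-term
decline, a sinusoidal quasi-cycle, and episodic single-season drops), from
which the generator draws

* replicate mark-recapture sessions — M = round(marking_fraction * N) pups
  marked, then Q independent replicate counts with Ci ~ Binomial(N,
  coverage) pups seen and Ri ~ Hypergeometric(N, M, Ci) of them marked
  (replicates are independent given N and M: pups mingle between counts,
  tag loss is zero);
* dead-pup counts — dead ~ Binomial(round(N / (1 - rate)), rate), so the
  expected dead fraction of total (live + dead) pups equals the configured
  rate;
* pup biometrics — length ~ Normal by sex, mass built from a power-law
  allometry with multiplicative log-normal noise plus additive sex, day,
  colony and year effects:
  mass = exp(a + b ln L + eps) + sex_eff * I(male) + day_eff * (day - day0)
         + colony_offset + year_effect.

Default effect sizes mirror a real fur seal monitoring programme: males
+0.69 kg, +0.04 kg per day of season, colony offsets 0 / -0.14 / -0.75 kg.
All randomness flows from one root seed through a documented splitting
scheme (seed, colony index, year index, stream id), so any colony-year and
stream can be regenerated independently and identical configs give
byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mark_recapture import RecaptureSession

__all__ = [
    "BiometricEffects",
    "ColonyConfig",
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "simulate_trajectory",
    "simulate_recapture_session",
    "simulate_biometrics",
    "simulate_dead_counts",
    "simulate_dataset",
]

# stream ids for the seed-splitting scheme
_STREAM_RECAPTURE = 0
_STREAM_DEAD = 1
_STREAM_BIOMETRICS = 2
_STREAM_YEAR_EFFECT = 3


@dataclass(frozen=True)
class BiometricEffects:
    """True coefficients of the biometric generator (mass in kg)."""

    allometry_a: float = -7.66  # log-kg at log-length zero
    allometry_b: float = 2.2  # mass-length elasticity
    sex_effect: float = 0.69  # additive, males (the model-scale sex gap)
    day_effect: float = 0.04  # kg per day of season
    colony_offset: float = 0.0  # additive vs the baseline colony
    day_origin: int = 30  # day at which the day effect is zero
    log_mass_sd: float = 0.10  # sd of the allometric log-noise
    year_effect_sd: float = 0.30  # sd of the shared colony-year effect
    # lengths share one distribution across sexes: the sex effect above is
    # the total model-scale mass gap, so none of it may also enter through
    # the mass-length allometry
    length_mean_female: float = 73.5  # cm
    length_mean_male: float = 73.5  # cm
    length_sd: float = 4.0  # cm


@dataclass(frozen=True)
class ColonyConfig:
    """Trajectory, sampling design and biometric effects for one colony."""

    name: str
    baseline: float = 900.0  # pups in the first season
    decline_rate: float = 0.02  # exponential rate per year
    sin_amplitude: float = 0.25  # fractional quasi-cycle amplitude
    sin_period: float = 14.0  # years
    episodic_drops: dict[int, float] = field(default_factory=dict)  # year -> multiplier
    marking_fraction: float = 0.5  # aim: mark > 50% of pups
    q_replicates: int = 5  # recapture counts per session
    coverage: float = 0.3  # fraction of pups seen per replicate
    mortality_rate: float = 0.03  # expected dead fraction of total pups
    n_pups_measured: int = 120  # biometric sample per colony-year
    day_range: tuple[int, int] = (20, 40)  # late-January survey window
    late_shift_years: dict[int, int] = field(default_factory=dict)  # year -> +days
    effects: BiometricEffects = field(default_factory=BiometricEffects)

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError(f"{self.name}: negative baseline")
        if not 0 < self.marking_fraction <= 1:
            raise ValueError(f"{self.name}: marking_fraction must be in (0, 1]")
        if not 0 < self.coverage <= 1:
            raise ValueError(f"{self.name}: coverage must be in (0, 1]")
        if not 0 <= self.mortality_rate < 1:
            raise ValueError(f"{self.name}: mortality_rate must be in [0, 1)")
        if self.q_replicates < 1:
            raise ValueError(f"{self.name}: need at least one replicate")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic colony world."""

    seed: int = 0
    start_year: int = 1991
    n_years: int = 35
    colonies: tuple[ColonyConfig, ...] = ()

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return _from_plain(yaml.safe_load(Path(path).read_text()))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(data: dict) -> SimulationConfig:
    colonies = []
    for c in data.get("colonies", []):
        c = dict(c)
        c["effects"] = BiometricEffects(**c.get("effects", {}))
        c["episodic_drops"] = {int(k): float(v) for k, v in c.get("episodic_drops", {}).items()}
        c["late_shift_years"] = {int(k): int(v) for k, v in c.get("late_shift_years", {}).items()}
        c["day_range"] = tuple(c["day_range"])
        colonies.append(ColonyConfig(**c))
    return SimulationConfig(
        seed=int(data["seed"]),
        start_year=int(data["start_year"]),
        n_years=int(data["n_years"]),
        colonies=tuple(colonies),
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """Three colonies loosely shaped like a west-coast monitoring study:
    ~35 seasons, long-term declines of different severity, shared episodic
    drops around seasons 2000 and 2023, one island colony with much higher
    pup mortality and lighter pups."""
    shared_drops = {2000: 0.6, 2023: 0.7}
    colonies = (
        ColonyConfig(
            name="Colony-North",
            baseline=850,
            decline_rate=0.054,
            episodic_drops=dict(shared_drops),
            mortality_rate=0.023,
            effects=BiometricEffects(colony_offset=-0.14),
        ),
        ColonyConfig(
            name="Colony-Central",
            baseline=300,
            decline_rate=0.0366,
            episodic_drops=dict(shared_drops),
            mortality_rate=0.03,
            effects=BiometricEffects(colony_offset=0.0),
        ),
        ColonyConfig(
            name="Colony-South-Island",
            baseline=900,
            decline_rate=0.0269,
            episodic_drops={2000: 0.65, 2023: 0.75},
            mortality_rate=0.127,
            effects=BiometricEffects(colony_offset=-0.75),
        ),
    )
    return SimulationConfig(seed=seed, colonies=colonies)


def coefficient_recovery_config(
    seed: int = 0,
    n_years: int = 8,
    n_pups_per_year: int = 209,
    year_effect_sd: float = 0.0,
) -> SimulationConfig:
    """Scenario for coefficient-recovery checks.

    Lengths share one distribution across sexes and colonies, so the
    additive sex/day/colony generator coefficients are exactly the
    estimands of a pan-colony linear model in Sex, Day and Colony (with
    sex-specific length means part of the mass-length allometry would leak
    into the sex coefficient). Shared colony-year effects are off by
    default so coefficient sampling distributions match the fitted model's
    iid-noise assumption; set ``year_effect_sd`` > 0 to add a true Year
    term to the generating structure.
    """
    def eff(offset: float) -> BiometricEffects:
        return BiometricEffects(
            colony_offset=offset,
            length_mean_female=73.5,
            length_mean_male=73.5,
            year_effect_sd=year_effect_sd,
        )

    common = dict(
        baseline=500.0,
        decline_rate=0.0,
        sin_amplitude=0.0,
        n_pups_measured=n_pups_per_year,
    )
    colonies = (
        ColonyConfig(name="Colony-Central", effects=eff(0.0), **common),
        ColonyConfig(name="Colony-North", effects=eff(-0.14), **common),
        ColonyConfig(name="Colony-South-Island", effects=eff(-0.75), **common),
    )
    return SimulationConfig(
        seed=seed, start_year=2018, n_years=n_years, colonies=colonies
    )


def _rng(config_seed: int, colony_idx: int, year_idx: int, stream: int) -> np.random.Generator:
    """One independent generator per (colony, year, stream) leaf."""
    return np.random.default_rng(
        np.random.SeedSequence([config_seed, colony_idx, year_idx, stream])
    )


# ---------------------------------------------------------------------------
# generators


def simulate_trajectory(colony: ColonyConfig, years: list[int]) -> pd.Series:
    """Deterministic true live-pup abundance per year.

    N(t) = round(baseline * exp(-r t) * (1 + A sin(2 pi t / T)) *
    episodic multipliers), floored at 0; t counts years from the first
    season.
    """
    t = np.arange(len(years), dtype=float)
    n = colony.baseline * np.exp(-colony.decline_rate * t)
    if colony.sin_amplitude:
        n *= 1.0 + colony.sin_amplitude * np.sin(2 * np.pi * t / colony.sin_period)
    mult = np.ones_like(n)
    for yr, m in colony.episodic_drops.items():
        if yr in years:
            mult[years.index(yr)] = m
    n = np.maximum(np.round(n * mult), 0.0).astype(int)
    return pd.Series(n, index=pd.Index(years, name="year"), name="true_n")


def simulate_recapture_session(
    true_n: int,
    marking_fraction: float,
    q: int,
    coverage: float,
    rng: np.random.Generator,
    colony: str = "synthetic",
    year: int = 0,
) -> RecaptureSession:
    """Draw one marking event with Q replicate recapture counts."""
    if true_n < 1:
        raise ValueError(f"true_n must be >= 1, got {true_n}")
    if not 0 < marking_fraction <= 1 or not 0 < coverage <= 1:
        raise ValueError("marking_fraction and coverage must be in (0, 1]")
    m = max(1, int(round(marking_fraction * true_n)))
    reps = []
    for _ in range(q):
        ci = int(rng.binomial(true_n, coverage))
        ri = int(rng.hypergeometric(m, true_n - m, ci)) if ci > 0 else 0
        reps.append((ci, ri))
    return RecaptureSession(colony, year, m, tuple(reps))


def simulate_dead_counts(
    true_n: int, mortality_rate: float, rng: np.random.Generator
) -> int:
    """Dead-pup count whose expected share of total pups is the rate."""
    if not 0 <= mortality_rate < 1:
        raise ValueError(f"mortality_rate must be in [0, 1), got {mortality_rate}")
    if mortality_rate == 0:
        return 0
    total = int(round(true_n / (1.0 - mortality_rate)))
    return int(rng.binomial(total, mortality_rate))


def simulate_biometrics(
    colony: ColonyConfig,
    year: int,
    n_pups: int,
    rng: np.random.Generator,
    year_effect: float = 0.0,
) -> pd.DataFrame:
    """Draw a colony-year biometric sample (one row per measured pup)."""
    if n_pups < 1:
        raise ValueError(f"n_pups must be >= 1, got {n_pups}")
    e = colony.effects
    male = rng.random(n_pups) < 0.5
    length = np.where(
        male,
        rng.normal(e.length_mean_male, e.length_sd, n_pups),
        rng.normal(e.length_mean_female, e.length_sd, n_pups),
    )
    length = np.clip(length, 45.0, 115.0)
    lo, hi = colony.day_range
    shift = colony.late_shift_years.get(year, 0)
    day = rng.integers(lo + shift, hi + shift + 1, n_pups)
    eps = rng.normal(0.0, e.log_mass_sd, n_pups)
    mass = (
        np.exp(e.allometry_a + e.allometry_b * np.log(length) + eps)
        + e.sex_effect * male
        + e.day_effect * (day - e.day_origin)
        + e.colony_offset
        + year_effect
    )
    mass = np.maximum(mass, 0.05)
    return pd.DataFrame(
        {
            "colony": colony.name,
            "year": year,
            "day": day.astype(int),
            "sex": np.where(male, "male", "female"),
            "mass_kg": np.round(mass, 3),
            "length_cm": np.round(length, 1),
        }
    )


# ---------------------------------------------------------------------------
# full dataset


@dataclass(frozen=True)
class SyntheticDataset:
    """All generated tables plus the immutable ground truth."""

    config: SimulationConfig
    sessions: pd.DataFrame  # one row per recapture replicate
    dead_counts: pd.DataFrame  # colony, year, dead_count
    biometrics: pd.DataFrame  # one row per measured pup
    ground_truth: pd.DataFrame  # per colony-year truth
    turning_truth: pd.DataFrame  # drop-free trajectory turning years

    def write(self, outdir) -> dict[str, str]:
        """Write the four CSVs plus the config YAML; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("recapture_sessions", self.sessions),
            ("dead_counts", self.dead_counts),
            ("biometrics", self.biometrics),
            ("ground_truth", self.ground_truth),
            ("true_turning_points", self.turning_truth),
        ]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        cfg = outdir / "simulation_config.yaml"
        self.config.to_yaml(cfg)
        paths["config"] = str(cfg)
        return paths


def smooth_turning_years(
    colony: ColonyConfig, n_years: int, start_year: int, shock_window: float = 2.0
) -> pd.DataFrame:
    """Turning years of the drop-free trajectory component, with a flag for
    proximity to episodic shocks.

    Episodic drops are transient single-season shocks, not changes of the
    underlying trajectory, so the generating trajectory's "true" turning
    points are those of baseline * exp(-r t) * (1 + A sin(2 pi t / T)).
    Turning points within ``shock_window`` years of a drop are flagged
    ``shock_adjacent``: around a shock the turning time is not identifiable
    from annual survey data, so recovery guarantees exclude them.
    """
    t = np.linspace(0.0, n_years - 1.0, max(100 * n_years, 1000))
    f = colony.baseline * np.exp(-colony.decline_rate * t)
    if colony.sin_amplitude:
        f = f * (1.0 + colony.sin_amplitude * np.sin(2 * np.pi * t / colony.sin_period))
    sign = np.sign(np.diff(f))
    idx = np.where(sign[:-1] * sign[1:] < 0)[0]
    years = start_year + t[idx + 1]
    directions = np.where(sign[idx] > 0, "positive_to_negative", "negative_to_positive")
    drops = np.array(sorted(colony.episodic_drops), dtype=float)
    adjacent = (
        np.array([np.min(np.abs(drops - y)) for y in years]) <= shock_window
        if len(drops) and len(years)
        else np.zeros(len(years), dtype=bool)
    )
    return pd.DataFrame(
        {
            "colony": colony.name,
            "turning_year": years,
            "direction": directions,
            "shock_adjacent": adjacent,
        }
    )


def trajectory_turning_years(traj: pd.Series) -> list[int]:
    """Years where the deterministic trajectory's annual difference
    changes sign (the generating trajectory's true turning points)."""
    diff = np.diff(traj.to_numpy(dtype=float))
    years = traj.index.to_numpy()
    out = []
    prev = 0.0
    for i, d in enumerate(diff):
        s = np.sign(d) or prev
        if prev != 0 and s != 0 and s != prev:
            out.append(int(years[i]))
        if s != 0:
            prev = s
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the complete dataset for every colony and year."""
    if not config.colonies:
        raise ValueError("config has no colonies")
    years = config.years
    sessions_rows, dead_rows, bio_frames, truth_rows = [], [], [], []
    turning_frames = []
    for ci_idx, colony in enumerate(config.colonies):
        traj = simulate_trajectory(colony, years)
        turning_frames.append(
            smooth_turning_years(colony, config.n_years, config.start_year)
        )
        for yi, year in enumerate(years):
            n = int(traj.loc[year])
            year_effect = float(
                _rng(config.seed, ci_idx, yi, _STREAM_YEAR_EFFECT).normal(
                    0.0, colony.effects.year_effect_sd
                )
            )
            if n >= 1:
                sess = simulate_recapture_session(
                    n,
                    colony.marking_fraction,
                    colony.q_replicates,
                    colony.coverage,
                    _rng(config.seed, ci_idx, yi, _STREAM_RECAPTURE),
                    colony=colony.name,
                    year=year,
                )
                for rid, (tc, mc) in enumerate(sess.replicates):
                    sessions_rows.append(
                        {
                            "colony": colony.name,
                            "year": year,
                            "marked": sess.marked,
                            "replicate_id": rid,
                            "total_count": tc,
                            "marked_count": mc,
                        }
                    )
            dead = simulate_dead_counts(
                n, colony.mortality_rate, _rng(config.seed, ci_idx, yi, _STREAM_DEAD)
            )
            dead_rows.append({"colony": colony.name, "year": year, "dead_count": dead})
            if n >= 1:
                bio_frames.append(
                    simulate_biometrics(
                        colony,
                        year,
                        colony.n_pups_measured,
                        _rng(config.seed, ci_idx, yi, _STREAM_BIOMETRICS),
                        year_effect=year_effect,
                    )
                )
            truth_rows.append(
                {
                    "colony": colony.name,
                    "year": year,
                    "true_n": n,
                    "true_dead": dead,
                    "year_effect": year_effect,
                    "allometry_a": colony.effects.allometry_a,
                    "allometry_b": colony.effects.allometry_b,
                    "sex_effect": colony.effects.sex_effect,
                    "day_effect": colony.effects.day_effect,
                    "colony_offset": colony.effects.colony_offset,
                    "mortality_rate": colony.mortality_rate,
                }
            )
    return SyntheticDataset(
        config=config,
        sessions=pd.DataFrame(sessions_rows),
        dead_counts=pd.DataFrame(dead_rows),
        biometrics=pd.concat(bio_frames, ignore_index=True),
        ground_truth=pd.DataFrame(truth_rows),
        turning_truth=pd.concat(turning_frames, ignore_index=True),
    )
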