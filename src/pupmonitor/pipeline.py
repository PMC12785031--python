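"""End-to-end pipeline: simulate -> estimate -> condition -> models -> trend.

Each stage reads and writes plain CSV tables in the run's output
directory, so every number in the summary report is traceable to a table
cell. A manifest (JSON) records the configuration, per-stage status and
output paths; a failed stage halts downstream stages but keeps completed
outputs. Identical configurations (including the seed) reproduce
byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import condition as cond
from . import condition_models as cm
from . import mark_recapture as mr
from . import trend as tr
from . import synthetic_data as sd

__all__ = ["RunConfig", "run_pipeline", "summary_report", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "estimate", "condition", "models", "trend")

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` is true (inputs are generated from ``sim_config``)
    or the three input CSV paths must point at existing files.
    """

    outdir: str
    simulate: bool = True
    sim_config: sd.SimulationConfig | None = None
    sessions_csv: str | None = None
    dead_csv: str | None = None
    biometrics_csv: str | None = None
    stages: tuple[str, ...] = STAGES
    ci_level: float = 0.95
    family_default: str = "gaussian_identity"
    family_by_colony: dict[str, str] = field(default_factory=dict)
    basis_dim: int = 10
    criterion: str = "gcv"
    reference_day: int | None = None
    include_interactions: bool = True
    max_params: int = 60
    split_year: int | None = None  # period boundary for the decline table

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; allowed: {STAGES}")
        if self.simulate:
            if self.sim_config is None:
                object.__setattr__(self, "sim_config", sd.default_config())
        else:
            for p in (self.sessions_csv, self.dead_csv, self.biometrics_csv):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path missing or absent: {p}")


def _family_for(config: RunConfig, colony: str) -> str:
    return config.family_by_colony.get(colony, config.family_default)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": config.sim_config.seed if config.sim_config else None,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
        "inputs": {},
    }
    halted = False
    for stage in STAGES:
        if stage not in config.stages or (stage == "simulate" and not config.simulate):
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        if halted:
            manifest["stages"][stage] = {"status": "not_run"}
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir, manifest)
            manifest["stages"][stage] = {"status": "complete"}
            manifest["outputs"].update(outputs)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
            halted = True
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _inputs(config: RunConfig, outdir: Path) -> dict[str, Path]:
    if config.simulate:
        return {
            "sessions": outdir / "recapture_sessions.csv",
            "dead": outdir / "dead_counts.csv",
            "biometrics": outdir / "biometrics.csv",
        }
    return {
        "sessions": Path(config.sessions_csv),
        "dead": Path(config.dead_csv),
        "biometrics": Path(config.biometrics_csv),
    }


def _stage_simulate(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    dataset = sd.simulate_dataset(config.sim_config)
    paths = dataset.write(outdir)
    manifest["inputs"] = {k: v for k, v in paths.items()}
    return paths


def _stage_estimate(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    paths = _inputs(config, outdir)
    sessions = mr.read_sessions_csv(paths["sessions"])
    estimates = mr.estimate_sessions(sessions, config.ci_level)
    est_df = mr.estimates_to_frame(estimates)
    est_path = outdir / "abundance_estimates.csv"
    est_df.to_csv(est_path, index=False)
    out = {"abundance_estimates": str(est_path)}
    if paths["dead"].exists():
        dead = pd.read_csv(paths["dead"])
        recs = mr.mortality_records(dead, estimates)
        mort = pd.DataFrame(
            {
                "colony": [m.colony for m in recs],
                "year": [m.year for m in recs],
                "dead_count": [m.dead_count for m in recs],
                "live_estimate": [m.live_estimate for m in recs],
                "dead_fraction_pct": [m.dead_fraction_pct for m in recs],
            }
        )
        mort_path = outdir / "mortality.csv"
        mort.to_csv(mort_path, index=False)
        out["mortality"] = str(mort_path)
    return out


def _stage_condition(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    paths = _inputs(config, outdir)
    bio = cond.load_biometrics(paths["biometrics"])
    with_idx, fit = cond.add_condition_indices(bio)
    cond_path = outdir / "condition.csv"
    with_idx.to_csv(cond_path, index=False)
    classes = cond.classify_condition(with_idx)
    cls_path = outdir / "condition_classification.csv"
    classes.to_csv(cls_path, index=False)
    allo_path = outdir / "allometry.csv"
    pd.DataFrame([dataclasses.asdict(fit)]).to_csv(allo_path, index=False)
    return {
        "condition": str(cond_path),
        "condition_classification": str(cls_path),
        "allometry": str(allo_path),
    }


def _stage_models(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    records = pd.read_csv(outdir / "condition.csv")
    est = pd.read_csv(outdir / "abundance_estimates.csv")
    out: dict[str, str] = {}
    standardised_frames = []
    corr_rows = []
    for response in ("mass", "bci1"):
        candidates = cm.candidate_specs(response, config.include_interactions)
        best, ranking = cm.select_model(candidates, records, config.max_params)
        ranking.to_csv(outdir / f"model_ranking_{response}.csv", index=False)
        best.coefficients.to_csv(outdir / f"model_coefficients_{response}.csv")
        out[f"model_ranking_{response}"] = str(outdir / f"model_ranking_{response}.csv")
        out[f"model_coefficients_{response}"] = str(
            outdir / f"model_coefficients_{response}.csv"
        )
        day_effect = (
            float(best.coefficients.loc["day", "coef"])
            if "day" in best.coefficients.index
            else 0.0
        )
        ref_day = (
            config.reference_day
            if config.reference_day is not None
            else int(np.median(records["day"]))
        )
        percolony_terms = tuple(
            t for t in best.spec.terms if t not in ("Colony", "Day")
        )
        if "Year" not in percolony_terms:
            percolony_terms = percolony_terms + ("Year",)
        spec = cm.ModelSpec(response, percolony_terms)
        for colony, grp in records.groupby("colony"):
            series = cm.standardise_by_day(spec, grp, day_effect, ref_day)
            standardised_frames.append(
                pd.DataFrame(
                    {
                        "colony": series.colony,
                        "response": response,
                        "year": series.years,
                        "standardised_mean": series.means,
                        "se": series.ses,
                        "reference_day": series.reference_day,
                    }
                )
            )
            if response == "mass":
                mass_by_year = dict(zip(series.years, series.means))
                sub = est[est["colony"] == colony]
                abund_by_year = dict(zip(sub["year"], sub["mean_estimate"]))
                mass, dab, yrs = cm.pair_mass_with_abundance_change(
                    mass_by_year, abund_by_year
                )
                if len(mass) >= 3 and np.std(mass) > 0 and np.std(dab) > 0:
                    res = cm.mass_abundance_correlation(mass, dab)
                    corr_rows.append({"colony": colony, **res})
    std_df = pd.concat(standardised_frames, ignore_index=True)
    std_path = outdir / "standardised_series.csv"
    std_df.to_csv(std_path, index=False)
    out["standardised_series"] = str(std_path)
    if corr_rows:
        corr_path = outdir / "mass_abundance_correlation.csv"
        pd.DataFrame(corr_rows).to_csv(corr_path, index=False)
        out["mass_abundance_correlation"] = str(corr_path)
    return out


def _stage_trend(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    est = pd.read_csv(outdir / "abundance_estimates.csv")
    trend_frames, tp_rows, period_rows = [], [], []
    for colony, grp in est.groupby("colony"):
        grp = grp.sort_values("year")
        if grp["year"].nunique() < 6:
            logger.warning("%s: too few years for a smooth, skipping", colony)
            continue
        fit = tr.fit_trend(
            grp["year"],
            grp["mean_estimate"],
            family=_family_for(config, str(colony)),
            basis_dim=config.basis_dim,
            criterion=config.criterion,
            colony=str(colony),
        )
        derivs = tr.derivative(fit)
        trend_frames.append(
            tr.trend_frame(fit, derivs).assign(edf=fit.edf, family=fit.family)
        )
        for p in tr.find_turning_points(derivs):
            tp_rows.append(
                {
                    "colony": colony,
                    "interval_start": p.interval[0],
                    "interval_end": p.interval[1],
                    "direction": p.direction,
                    "significant": p.significant,
                }
            )
        for per in tr.significant_periods(derivs):
            period_rows.append({"colony": colony, **per})
    out = {}
    for name, df in [
        ("trend", pd.concat(trend_frames, ignore_index=True) if trend_frames else pd.DataFrame()),
        ("turning_points", pd.DataFrame(tp_rows)),
        ("significant_periods", pd.DataFrame(period_rows)),
    ]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        out[name] = str(p)
    return out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "estimate": _stage_estimate,
    "condition": _stage_condition,
    "models": _stage_models,
    "trend": _stage_trend,
}


# ---------------------------------------------------------------------------
# report


def _decline_table(est: pd.DataFrame, split_year: int | None) -> pd.DataFrame:
    """Table-style period percent changes per colony: recorded maximum to a
    split year, the split year to the final survey, and their compound."""
    rows = []
    for colony, grp in est.groupby("colony"):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        vals = grp["mean_estimate"].to_numpy()
        imax = int(np.argmax(vals))
        split = split_year
        if split is None:
            split = int(years[0] + 0.7 * (years[-1] - years[0]))
        cand = [i for i, y in enumerate(years) if y >= years[imax] and y <= split]
        isplit = cand[-1] if cand else imax
        if isplit <= imax or isplit == len(years) - 1:
            # no usable middle survey: single period
            total = mr.period_percent_change(vals[imax], vals[-1])
            rows.append(
                {"colony": colony, "period": f"{years[imax]}-{years[-1]}",
                 "pct_change": total, "segment": "total"}
            )
            continue
        c1 = mr.period_percent_change(vals[imax], vals[isplit])
        c2 = mr.period_percent_change(vals[isplit], vals[-1])
        rows.append({"colony": colony, "period": f"{years[imax]}-{years[isplit]}",
                     "pct_change": c1, "segment": "first"})
        rows.append({"colony": colony, "period": f"{years[isplit]}-{years[-1]}",
                     "pct_change": c2, "segment": "second"})
        rows.append({"colony": colony, "period": f"{years[imax]}-{years[-1]}",
                     "pct_change": mr.compound_percent_changes([c1, c2]),
                     "segment": "total"})
    return pd.DataFrame(rows)


def summary_report(outdir, split_year: int | None = None) -> str:
    """Human-readable summary of a completed (or partial) run.

    Estimates are integer-rounded with the CI in parentheses; percentages
    carry one decimal. Partial runs produce partial reports with the gaps
    stated.
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [
        "Colony monitoring summary",
        "=" * 60,
        f"package {manifest['package_version']}, schema {manifest['schema_version']}, "
        f"seed {manifest.get('seed')}",
        "",
    ]
    est_path = outdir / "abundance_estimates.csv"
    if est_path.exists():
        est = pd.read_csv(est_path)
        lines.append("Live pup abundance estimates (mean, 95% CI)")
        lines.append("-" * 60)
        for colony, grp in est.groupby("colony"):
            lines.append(f"  {colony}:")
            for r in grp.sort_values("year").itertuples(index=False):
                if pd.notna(r.se):
                    lines.append(
                        f"    {r.year}: {r.mean_estimate:.0f} "
                        f"({r.ci_lower:.0f}-{r.ci_upper:.0f})"
                    )
                else:
                    lines.append(
                        f"    {r.year}: {r.mean_estimate:.0f} (single replicate; CI n/a)"
                    )
        lines.append("")
        decl = _decline_table(est, split_year)
        decl.to_csv(outdir / "decline_table.csv", index=False)
        lines.append("Percentage change in pup abundance by period")
        lines.append("-" * 60)
        for r in decl.itertuples(index=False):
            tag = " (compound total)" if r.segment == "total" else ""
            lines.append(f"  {r.colony} {r.period}: {r.pct_change:+.1f}%{tag}")
        lines.append("")
    else:
        lines.append("[estimate stage incomplete: no abundance table]")
        lines.append("")
    trend_path = outdir / "trend.csv"
    if trend_path.exists() and trend_path.stat().st_size > 1:
        trend = pd.read_csv(trend_path)
        if len(trend):
            lines.append("Smooth trend summaries")
            lines.append("-" * 60)
            for colony, grp in trend.groupby("colony"):
                lines.append(
                    f"  {colony}: family={grp['family'].iloc[0]}, "
                    f"edf={grp['edf'].iloc[0]:.2f}"
                )
            tp_path = outdir / "turning_points.csv"
            tps = pd.read_csv(tp_path) if tp_path.exists() else pd.DataFrame()
            if len(tps):
                lines.append("  Turning points:")
                for r in tps.itertuples(index=False):
                    sig = "significant" if r.significant else "not significant"
                    lines.append(
                        f"    {r.colony}: {r.interval_start:.2f}/{r.interval_end:.2f} "
                        f"{r.direction} ({sig})"
                    )
            else:
                lines.append("  No turning points found.")
            lines.append("")
    else:
        lines.append("[trend stage incomplete: no smooth summaries]")
        lines.append("")
    cls_path = outdir / "condition_classification.csv"
    if cls_path.exists():
        cls = pd.read_csv(cls_path)
        lines.append("Pup condition (BCI2) classification by colony")
        lines.append("-" * 60)
        for colony, grp in cls.groupby("colony"):
            nb = int((grp["status"] == "better").sum())
            lines.append(
                f"  {colony}: better-than-expected in {nb} of {len(grp)} years"
            )
        lines.append("")
    else:
        lines.append("[condition stage incomplete: no classification]")
        lines.append("")
    text = "\n".join(lines)
    (outdir / "report.txt").write_text(text)
    return text
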