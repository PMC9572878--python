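"""Pipeline orchestration and table reporting.

Runs the full analysis sequence — simulate or ingest session logs,
derive load metrics, robustly compare injured vs non-injured
player-weeks, fit the quartile injury GLMs — and writes the five study
tables as CSV:

* table1_descriptives.csv — median (IQR) per load metric, stratified
  overall / injured / not injured;
* table2_quantiles.csv — counts and within-stratum percentages per
  metric quartile;
* table3_acute_load.csv / table4_acwr.csv — robust Student-t comparison
  summaries;
* table5_glm.csv — logistic GLM coefficients and conditional injury
  probabilities for ACWR and ACWRr.

A machine-readable manifest records the configuration hash, seed and
library versions; the same config and seed reproduce identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, injury_glm, metrics, robust_compare, synthdata
from .robust_compare import MCMCSettings

__all__ = ["RunConfig", "run_pipeline", "descriptive_summary", "quantile_count_summary"]

logger = logging.getLogger(__name__)

DESCRIPTIVE_METRICS = [
    ("acwr", "ACWR"),
    ("acwrr", "ACWRr"),
    ("acute_load", "Acute Load"),
    ("cumulative_load_2w", "Cumulative Load (2 weeks)"),
    ("cumulative_load_3w", "Cumulative Load (3 weeks)"),
    ("cumulative_load_4w", "Cumulative Load (4 weeks)"),
    ("chronic_load", "Chronic Load (4 weeks)"),
]

QUANTILE_METRICS = [
    ("acute_quantile", "Acute Load"),
    ("acwr_quantile", "ACWR"),
    ("acwrr_quantile", "ACWRr"),
]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run; ``seed`` is mandatory."""

    out_dir: str
    seed: int
    sessions_path: str | None = None
    injuries_path: str | None = None
    synthetic: synthdata.SyntheticConfig | None = None
    metrics_list: tuple = ("acute_load", "acwr")
    n_chains: int = 4
    n_iterations: int = 10_000
    warmup: int = 2_000
    acwrr_mean: float = metrics.ACWRR_MEAN
    acwrr_sd: float = metrics.ACWRR_SD
    prior_intercept_sd: float = 2.0
    prior_deviation_scale: float = 2.0
    check_convergence: bool = True

    def __post_init__(self) -> None:
        if self.sessions_path is None and self.synthetic is None:
            object.__setattr__(
                self, "synthetic", synthdata.SyntheticConfig(seed=self.seed)
            )
        for path in (self.sessions_path, self.injuries_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def mcmc(self, seed_offset: int = 0) -> MCMCSettings:
        return MCMCSettings(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            warmup=self.warmup,
            seed=int(self.seed) + seed_offset,
            check=self.check_convergence,
        )

    def content_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land is not part of the analysis
        if self.synthetic is not None:
            payload["synthetic"] = dataclasses.asdict(self.synthetic)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _median_iqr(values: pd.Series) -> str:
    v = values.dropna().to_numpy(dtype=float)
    if v.size == 0:
        return ""
    lo, med, hi = np.percentile(v, [25, 50, 75])
    return f"{med:.2f} ({lo:.2f}, {hi:.2f})"


def descriptive_summary(observations: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) per load metric, stratified overall/injured/not injured."""
    if observations.empty:
        raise ValueError("observation table is empty")
    injured = observations[observations["injured"].astype(bool)]
    not_injured = observations[~observations["injured"].astype(bool)]
    strata = [
        (f"Overall, N = {len(observations)}", observations),
        (f"Injured, N = {len(injured)}", injured),
        (f"Not Injured, N = {len(not_injured)}", not_injured),
    ]
    rows = []
    for col, label in DESCRIPTIVE_METRICS:
        if col not in observations.columns:
            continue
        row = {"metric": label}
        for name, frame in strata:
            if frame.empty:
                logger.warning("descriptive summary: empty stratum %s", name)
                row[name] = ""
            else:
                row[name] = _median_iqr(frame[col])
        rows.append(row)
    return pd.DataFrame(rows)


def quantile_count_summary(observations: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-stratum percentages per metric quartile."""
    injured_mask = observations["injured"].astype(bool)
    strata = [
        ("Overall", observations),
        ("Injured", observations[injured_mask]),
        ("Not Injured", observations[~injured_mask]),
    ]
    ordinal = {1: "First", 2: "Second", 3: "Third", 4: "Fourth"}
    rows = []
    for col, label in QUANTILE_METRICS:
        if col not in observations.columns:
            continue
        for level in (1, 2, 3, 4):
            row = {"metric": label, "quantile": ordinal[level]}
            for name, frame in strata:
                sub = frame.dropna(subset=[col])
                count = int((sub[col].astype(int) == level).sum())
                pct = round(100.0 * count / len(sub)) if len(sub) else 0
                row[name] = f"{count} ({pct}%)"
            rows.append(row)
    return pd.DataFrame(rows)


def _comparison_table(result: robust_compare.RobustComparisonResult) -> pd.DataFrame:
    layout = [
        ("Injured", "Mu", result.mu_injured),
        ("Injured", "Sigma", result.sigma_injured),
        ("Not Injured", "Mu", result.mu_not_injured),
        ("Not Injured", "Sigma", result.sigma_not_injured),
        ("Group Diff.", "Nu", result.nu),
        ("Group Diff.", "Effect Size", result.effect_size),
        ("Group Diff.", "Mean Diff", result.mean_diff),
    ]
    return pd.DataFrame(
        {
            "group": [g for g, _, _ in layout],
            "parameter": [p for _, p, _ in layout],
            "mean": [round(s.mean, 2) for _, _, s in layout],
            "hdi_2.5": [round(s.hdi_low, 2) for _, _, s in layout],
            "hdi_97.5": [round(s.hdi_high, 2) for _, _, s in layout],
            "ess": [round(s.ess, 2) for _, _, s in layout],
            "psrf": [round(s.psrf, 4) for _, _, s in layout],
        }
    )


def _glm_table(result: injury_glm.GLMResult, metric_label: str, threshold: float) -> pd.DataFrame:
    rows = [("beta0", result.beta0)]
    rows += [(f"beta{q + 1}", result.beta[q]) for q in range(4)]
    rows.append((f"P(Inj | {metric_label} > {threshold:.2f})", result.p_quantile[3]))
    return pd.DataFrame(
        {
            "parameter": [n for n, _ in rows],
            "mean": [round(s.mean, 2) for _, s in rows],
            "hdi_2.5": [round(s.hdi_low, 2) for _, s in rows],
            "hdi_97.5": [round(s.hdi_high, 2) for _, s in rows],
            "ess": [round(s.ess, 2) for _, s in rows],
            "psrf": [round(s.psrf, 4) for _, s in rows],
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the table files + manifest.

    Returns a dict of the in-memory results keyed by stage.  Any stage
    failure raises with the stage name; files written so far remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "ingest"
    try:
        if config.sessions_path is not None:
            sessions = metrics.read_sessions(config.sessions_path)
            injuries = (
                metrics.read_injuries(config.injuries_path)
                if config.injuries_path
                else None
            )
            stage = "metrics"
            observations = metrics.build_observation_table(
                sessions,
                injuries,
                acwrr_mean=config.acwrr_mean,
                acwrr_sd=config.acwrr_sd,
                seed=config.seed,
            )
        else:
            stage = "simulate"
            sessions, injuries, observations = synthdata.generate_team_season(config.synthetic)
            sessions.to_csv(out / "sessions.csv", index=False)
            injuries.to_csv(out / "injuries.csv", index=False)
        results["observations"] = observations
        observations.to_csv(out / "observations.csv", index=False)

        stage = "descriptives"
        table1 = descriptive_summary(observations)
        table1.to_csv(out / "table1_descriptives.csv", index=False)
        table2 = quantile_count_summary(observations)
        table2.to_csv(out / "table2_quantiles.csv", index=False)
        results["table1"], results["table2"] = table1, table2

        injured_mask = observations["injured"].astype(bool)
        stage = "robust_compare"
        comparisons = {}
        for i, metric_name in enumerate(("acute_load", "acwr")):
            y_inj = observations.loc[injured_mask, metric_name].dropna()
            y_not = observations.loc[~injured_mask, metric_name].dropna()
            res = robust_compare.fit_robust_comparison(y_inj, y_not, config.mcmc(100 + i))
            comparisons[metric_name] = res
            idx = 3 if metric_name == "acute_load" else 4
            _comparison_table(res).to_csv(out / f"table{idx}_{metric_name}.csv", index=False)
            res.samples.to_long_frame().to_csv(
                out / f"draws_compare_{metric_name}.csv", index=False
            )
        results["comparisons"] = comparisons

        stage = "glm"
        glm_tables = []
        glms = {}
        for j, (metric_name, qcol) in enumerate(
            [("ACWR", "acwr_quantile"), ("ACWRr", "acwrr_quantile")]
        ):
            res = injury_glm.fit_quantile_glm(
                observations,
                quantile_column=qcol,
                mcmc=config.mcmc(200 + j),
                prior_intercept_sd=config.prior_intercept_sd,
                prior_deviation_scale=config.prior_deviation_scale,
            )
            glms[metric_name] = res
            threshold = float(
                np.nanpercentile(observations[metric_name.lower()].to_numpy(dtype=float), 75)
            )
            tab = _glm_table(res, metric_name, threshold)
            tab.insert(0, "model", metric_name)
            glm_tables.append(tab)
            res.samples.to_long_frame().to_csv(out / f"draws_glm_{metric_name}.csv", index=False)
        table5 = pd.concat(glm_tables, ignore_index=True)
        table5.to_csv(out / "table5_glm.csv", index=False)
        results["glms"] = glms
        results["table5"] = table5
        results["metric_comparison"] = injury_glm.compare_metrics(glms["ACWR"], glms["ACWRr"])

        stage = "diagnostics"
        diag = []
        for name, res in {**comparisons, **glms}.items():
            summ = res.samples.summary().reset_index()
            summ.insert(0, "model", name)
            diag.append(summ)
        diagnostics = pd.concat(diag, ignore_index=True)
        diagnostics.to_csv(out / "diagnostics.csv", index=False)
        results["diagnostics"] = diagnostics

        stage = "manifest"
        manifest = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "acwr_bayes_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "n_observations": int(len(observations)),
            "n_injured": int(observations["injured"].sum()),
            "metric_comparison_q4": results["metric_comparison"],
            "tables": {
                "table1_descriptives.csv": "observations.csv",
                "table2_quantiles.csv": "observations.csv",
                "table3_acute_load.csv": "draws_compare_acute_load.csv",
                "table4_acwr.csv": "draws_compare_acwr.csv",
                "table5_glm.csv": "draws_glm_ACWR.csv + draws_glm_ACWRr.csv",
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
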