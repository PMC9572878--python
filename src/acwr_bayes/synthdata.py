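"""Synthetic team-season generator.

Emulates one professional soccer squad monitored with session-RPE: 12
players followed for a full year (52 weeks) and 23 for half a year (26
weeks).  Weekly training volume follows a player-level AR(1) multiplier
on a log scale, producing autocorrelated, right-skewed weekly acute
loads whose pooled median and IQR sit at the squad scale of roughly
1800 (1400, 2300) AU.  Players miss some calendar weeks (rotation,
illness, travel), and a time-loss injury removes the player for the
following weeks, so roughly 815 usable player-week observations emerge
from ~1,222 nominal ones.

Injuries are drawn under one of three generative models:

* ``null`` — constant weekly hazard, independent of load;
* ``acute_dependent`` — log-odds linear in the acute-load quartile;
* ``acwr_dependent`` — log-odds linear in the ACWR quartile.

The null model is the key testbed: any apparent load–injury structure a
pipeline finds in it is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics

__all__ = ["SyntheticConfig", "generate_sessions", "generate_injuries", "generate_team_season"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and distributional knobs of the generator.

    Defaults reproduce the squad structure and load scale described in
    the module docstring; ``seed`` is mandatory.
    """

    n_players_full: int = 12
    weeks_full: int = 52
    n_players_half: int = 23
    weeks_half: int = 26
    sessions_per_week: tuple = (5, 6, 7)  # uniform over these counts
    duration_mean_sd: tuple = (75.0, 15.0)  # minutes
    rpe_mean_sd: tuple = (4.5, 1.5)  # CR-10 units
    weekly_load_autocorrelation: float = 0.6  # AR(1) on the log multiplier
    load_multiplier_median: float = 0.9
    load_multiplier_sigma: float = 0.3
    participation_prob: float = 0.79  # weekly availability outside injury absence
    injury_model: str = "null"  # null | acute_dependent | acwr_dependent
    baseline_weekly_injury_prob: float = 0.037  # ~30 injuries / 815 player-weeks
    effect_log_odds_per_quantile: float = 0.0
    days_lost_log_median: float = np.log(10.0)  # log-normal, median 10 days
    days_lost_log_sigma: float = 0.6
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if not 0.0 <= self.weekly_load_autocorrelation < 1.0:
            raise ValueError("weekly_load_autocorrelation must be in [0, 1)")
        for p in (self.participation_prob, self.baseline_weekly_injury_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must be in [0, 1], got {p}")
        if self.injury_model not in ("null", "acute_dependent", "acwr_dependent"):
            raise ValueError(f"unknown injury_model {self.injury_model!r}")
        if min(self.n_players_full, self.n_players_half) < 0 or (
            self.n_players_full + self.n_players_half
        ) <= 0:
            raise ValueError("player counts must be non-negative and total positive")


def _subseed(seed: int, stream: int) -> int:
    """Derived integer seed (< 2^31) for an internal random stream."""
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2**31))


def _player_plan(config: SyntheticConfig):
    plan = []
    for i in range(config.n_players_full):
        plan.append((f"P{i + 1:02d}", config.weeks_full))
    for i in range(config.n_players_half):
        plan.append((f"P{config.n_players_full + i + 1:02d}", config.weeks_half))
    return plan


def generate_sessions(config: SyntheticConfig) -> pd.DataFrame:
    """Session log for the whole squad (player_id, week, day, duration_min, rpe).

    Per player-week: the AR(1) log-multiplier scales session durations,
    the session count is uniform over ``sessions_per_week``, durations
    are Normal (clipped at 0) and RPE is Normal rounded to the nearest
    0.5 and clipped to [1, 10].  Weeks failing the participation draw
    are skipped entirely (no sessions).  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    dur_mu, dur_sd = config.duration_mean_sd
    rpe_mu, rpe_sd = config.rpe_mean_sd
    rho = config.weekly_load_autocorrelation
    counts = np.asarray(config.sessions_per_week, dtype=int)
    rows = []
    for pid, n_weeks in _player_plan(config):
        z = 0.0
        for week in range(1, n_weeks + 1):
            z = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal()
            mult = config.load_multiplier_median * np.exp(config.load_multiplier_sigma * z)
            available = rng.random() < config.participation_prob
            n_sessions = int(rng.choice(counts)) if counts.size else 0
            if not available or n_sessions == 0:
                continue
            days = rng.choice(np.arange(1, 8), size=min(n_sessions, 7), replace=False)
            days.sort()
            for day in days:
                duration = max(0.0, rng.normal(dur_mu * mult, dur_sd))
                rpe = float(np.clip(np.round(rng.normal(rpe_mu, rpe_sd) * 2) / 2, 1.0, 10.0))
                rows.append((pid, week, int(day), round(duration, 1), rpe))
    return pd.DataFrame(rows, columns=metrics.SESSION_COLUMNS)


def _quantile_column(config: SyntheticConfig) -> str:
    return {"acute_dependent": "acute_quantile", "acwr_dependent": "acwr_quantile"}.get(
        config.injury_model, ""
    )


def generate_injuries(weekly: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Injury records (player_id, onset_week, days_lost) from an observation table.

    Player-weeks are scanned in (player, week) order; each draws a
    Bernoulli onset for the *following* week with
    logit(p) = logit(baseline) + effect * (quantile_rank - 2.5)
    under the load-dependent models, or constant baseline under
    ``null``.  A player with an open injury (onset week + absence not
    yet elapsed) draws no new injury, so at most one injury is open at
    a time.  Days lost are log-normal (median ~10 days).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    with np.errstate(divide="ignore"):  # baseline 0 -> logit -inf -> hazard 0
        base_logit = np.log(config.baseline_weekly_injury_prob) - np.log1p(
            -config.baseline_weekly_injury_prob
        )
    qcol = _quantile_column(config)
    records = []
    open_until: dict = {}
    for row in weekly.sort_values(["player_id", "week"]).itertuples(index=False):
        pid, week = row.player_id, int(row.week)
        if week < open_until.get(pid, -1):
            continue
        logit_p = base_logit
        if qcol:
            q = getattr(row, qcol)
            if np.isfinite(q):
                logit_p = logit_p + config.effect_log_odds_per_quantile * (float(q) - 2.5)
        p = 1.0 / (1.0 + np.exp(-logit_p))
        if rng.random() < p:
            onset = week + 1
            days_lost = int(
                np.ceil(np.exp(rng.normal(config.days_lost_log_median, config.days_lost_log_sigma)))
            )
            records.append((pid, onset, days_lost))
            open_until[pid] = onset + int(np.ceil(days_lost / 7.0)) + 1
    return pd.DataFrame(records, columns=metrics.INJURY_COLUMNS)


def generate_team_season(config: SyntheticConfig):
    """Full synthetic dataset: (sessions, injuries, observations).

    Sessions are generated, a preliminary observation table provides the
    load quantiles that drive the injury hazard, injuries are drawn, the
    weeks a player spends absent are pruned from the session log, and
    the final observation table is rebuilt from the pruned log with the
    injury labels attached.
    """
    sessions = generate_sessions(config)
    prelim = metrics.build_observation_table(sessions, injuries=None, seed=_subseed(config.seed, 2))
    injuries = generate_injuries(prelim, config)
    absences = metrics.absence_weeks(injuries)
    if absences:
        keep = ~sessions.apply(
            lambda r: r["week"] in absences.get(r["player_id"], ()), axis=1
        )
        sessions = sessions.loc[keep].reset_index(drop=True)
    observations = metrics.build_observation_table(
        sessions, injuries=injuries, seed=_subseed(config.seed, 3)
    )
    return sessions, injuries, observations


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
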