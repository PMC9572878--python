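"""Session-RPE internal-load metrics and quantile discretization.

Internal training load is quantified from the session rating of
perceived exertion (sRPE): session duration in minutes multiplied by
the Borg CR-10 intensity rating, giving load in arbitrary units (AU),
e.g. 60 min at RPE 4 = 240 AU.  From weekly sums of session loads the
module derives:

* acute load — the weekly sum of session loads;
* cumulative loads over trailing 1–4 week windows;
* chronic load — the 4-week rolling mean of weekly acute load
  (coupled: the current week is included, so a constant load series
  has ACWR exactly 1);
* ACWR — acute:chronic workload ratio;
* ACWRr — a null comparator in which the chronic denominator is
  replaced by a random draw from a team-level Normal distribution,
  destroying all individual chronic-load information;
* monotony — weekly mean daily load divided by the SD of daily loads.

Metrics are pooled across players and discretized into quartile
categories for the downstream injury GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SessionRecord",
    "QuantileBinning",
    "session_load",
    "acute_load",
    "cumulative_load",
    "chronic_load",
    "acwr",
    "acwrr",
    "monotony",
    "fit_quantile_binning",
    "build_observation_table",
    "read_sessions",
    "read_injuries",
    "ACWRR_MEAN",
    "ACWRR_SD",
    "ACWRR_FLOOR",
]

logger = logging.getLogger(__name__)

SESSION_COLUMNS = ["player_id", "week", "day", "duration_min", "rpe"]
INJURY_COLUMNS = ["player_id", "onset_week", "days_lost"]

#: Team-level denominator of the random-denominator null metric ACWRr:
#: Normal(mean, sd) in AU, matching the squad's chronic-load scale.
ACWRR_MEAN = 1900.0
ACWRR_SD = 730.0
#: Draws at or below this floor (AU) are rejected and redrawn, keeping the
#: random denominator positive and bounded away from zero.
ACWRR_FLOOR = 50.0


@dataclass(frozen=True)
class SessionRecord:
    """One training or match session.

    rpe is on the modified Borg CR-10 scale; half-point ratings and the
    0 and 10 endpoints are accepted.
    """

    player_id: str
    week: int
    day: int
    duration_min: float
    rpe: float

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValueError(f"duration_min must be >= 0, got {self.duration_min}")
        if not 0.0 <= self.rpe <= 10.0:
            raise ValueError(f"rpe must be in [0, 10], got {self.rpe}")
        if self.week < 1:
            raise ValueError(f"week index must be >= 1, got {self.week}")
        if not 1 <= self.day <= 7:
            raise ValueError(f"day must be in 1..7, got {self.day}")

    @property
    def load(self) -> float:
        return session_load(self.duration_min, self.rpe)


def session_load(duration_min: float, rpe: float) -> float:
    """sRPE load in AU: duration (min) x CR-10 rating."""
    duration_min = np.asarray(duration_min, dtype=float)
    rpe = np.asarray(rpe, dtype=float)
    if np.any(duration_min < 0):
        raise ValueError("duration_min must be >= 0")
    if np.any((rpe < 0) | (rpe > 10)):
        raise ValueError("rpe must be in [0, 10]")
    out = duration_min * rpe
    return float(out) if out.ndim == 0 else out


def acute_load(sessions) -> float:
    """Weekly acute load: the sum of session loads of one player-week."""
    records = list(sessions)
    if not records:
        return 0.0
    keys = {(r.player_id, r.week) for r in records}
    if len(keys) > 1:
        raise ValueError(f"sessions span multiple player-weeks: {sorted(keys)}")
    return float(sum(r.load for r in records))


def cumulative_load(weekly_acute, k: int) -> float:
    """Sum of the last ``k`` weekly acute loads, k in 1..4."""
    if k not in (1, 2, 3, 4):
        raise ValueError(f"k must be in 1..4, got {k}")
    seq = np.asarray(list(weekly_acute), dtype=float)
    if seq.size < k:
        raise ValueError(f"need at least {k} trailing weeks, got {seq.size}")
    return float(seq[-k:].sum())


def chronic_load(weekly_acute) -> float:
    """4-week rolling mean of weekly acute load (current week included)."""
    seq = np.asarray(list(weekly_acute), dtype=float)
    if seq.size < 4:
        raise ValueError(f"chronic load needs 4 trailing weeks, got {seq.size}")
    return float(seq[-4:].mean())


def acwr(acute: float, chronic: float) -> float:
    """Acute:chronic workload ratio."""
    if chronic <= 0:
        raise ValueError(f"chronic load must be positive, got {chronic}")
    return float(acute) / float(chronic)


def acwrr(
    acute: float,
    denominator_mean: float = ACWRR_MEAN,
    denominator_sd: float = ACWRR_SD,
    rng: np.random.Generator | None = None,
    floor: float = ACWRR_FLOOR,
) -> float:
    """Random-denominator null ACWR: acute load over a Normal team-level draw.

    gamma is drawn once per observation from Normal(mean, sd^2) and
    redrawn while gamma <= ``floor`` so the ratio stays positive and
    finite.  With sd -> 0 this converges to acute/mean deterministically.
    """
    if denominator_sd <= 0:
        raise ValueError(f"denominator_sd must be positive, got {denominator_sd}")
    if acute < 0:
        raise ValueError(f"acute load must be >= 0, got {acute}")
    if rng is None:
        raise ValueError("an rng must be provided for reproducibility")
    gamma = rng.normal(denominator_mean, denominator_sd)
    n_reject = 0
    while gamma <= floor:
        gamma = rng.normal(denominator_mean, denominator_sd)
        n_reject += 1
    if n_reject:
        logger.debug("acwrr: rejected %d draws <= floor %.0f AU", n_reject, floor)
    return float(acute) / float(gamma)


def monotony(daily_loads) -> float:
    """Weekly mean daily load / SD of daily loads (sample SD, n-1).

    Undefined (raises) when fewer than 2 days have loads or the SD is
    zero — a perfectly constant week is maximally monotonous.
    """
    x = np.asarray(list(daily_loads), dtype=float)
    if x.size < 2:
        raise ValueError("monotony needs at least 2 daily loads")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("monotony undefined for constant daily loads (SD = 0)")
    return float(x.mean() / sd)


@dataclass(frozen=True)
class QuantileBinning:
    """Quartile discretization of a pooled metric.

    cut_points are the 25th/50th/75th empirical percentiles (linear
    interpolation); a value v maps to the smallest bin b with
    v <= cut_points[b], else bin 4 (half-open, upper-inclusive).
    """

    cut_points: tuple
    metric_name: str = ""

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.cut_points)
        if len(c) != 3 or not (c[0] <= c[1] <= c[2]):
            raise ValueError(f"cut points must be 3 ascending reals, got {c}")
        object.__setattr__(self, "cut_points", c)

    def assign(self, values) -> np.ndarray:
        """Bin labels in {1,2,3,4} for each value."""
        v = np.asarray(values, dtype=float)
        return (np.searchsorted(self.cut_points, v, side="left") + 1).astype(int)


def fit_quantile_binning(values, metric_name: str = "") -> QuantileBinning:
    """Quartile cut points from the pooled metric values."""
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if np.unique(v).size < 4:
        raise ValueError("quantile binning needs at least 4 distinct values")
    cuts = np.percentile(v, [25, 50, 75])  # linear interpolation
    return QuantileBinning(tuple(cuts), metric_name=metric_name)


def read_sessions(path) -> pd.DataFrame:
    """Read a session log CSV (player_id, week, day, duration_min, rpe)."""
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session file missing columns: {sorted(missing)}")
    return df[SESSION_COLUMNS]


def read_injuries(path) -> pd.DataFrame:
    """Read an injury record CSV (player_id, onset_week, days_lost)."""
    df = pd.read_csv(path)
    missing = set(INJURY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"injury file missing columns: {sorted(missing)}")
    return df[INJURY_COLUMNS]


def _validate_sessions_frame(sessions: pd.DataFrame) -> pd.DataFrame:
    df = sessions.copy()
    if (df["duration_min"] < 0).any():
        raise ValueError("negative session durations in log")
    if ((df["rpe"] < 0) | (df["rpe"] > 10)).any():
        raise ValueError("rpe outside [0, 10] in log")
    return df


def absence_weeks(injuries: pd.DataFrame) -> dict:
    """Calendar weeks each player is absent with a time-loss injury.

    An injury with onset in week w and d days lost removes the player
    for the ceil(d/7) weeks following the onset week; the (partial)
    onset week itself is kept.
    """
    out: dict = {}
    for row in injuries.itertuples(index=False):
        lost = getattr(row, "days_lost", 0) or 0
        weeks_out = int(np.ceil(float(lost) / 7.0)) if lost > 0 else 0
        w0 = int(row.onset_week)
        out.setdefault(row.player_id, set()).update(range(w0 + 1, w0 + 1 + weeks_out))
    return out


def build_observation_table(
    sessions: pd.DataFrame,
    injuries: pd.DataFrame | None = None,
    acwrr_mean: float = ACWRR_MEAN,
    acwrr_sd: float = ACWRR_SD,
    acwrr_floor: float = ACWRR_FLOOR,
    coupled: bool = True,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Assemble one row per player-week with all load metrics and labels.

    Per player, weekly acute loads are computed on the sequence of
    *retained* weeks — weeks spent absent with a time-loss injury are
    excluded entirely rather than recorded as zero-load rows, and the
    trailing windows (cumulative, chronic) run over that retained
    sequence.  Rows require 4 trailing retained weeks so that chronic
    load is defined.  ``injured`` flags the completed week immediately
    preceding an injury onset (onset in week+1).  With
    ``coupled=False`` the chronic mean covers the 4 weeks before the
    current one (uncoupled convention) and a 5th trailing week is
    required.

    Quartile labels (acwr_quantile, acwrr_quantile, acute_quantile) are
    fitted on the pooled retained rows.
    """
    sessions = _validate_sessions_frame(sessions)
    if injuries is None:
        injuries = pd.DataFrame(columns=INJURY_COLUMNS)
    if len(injuries):
        unknown = set(injuries["player_id"]) - set(sessions["player_id"])
        if unknown:
            raise ValueError(f"injuries reference unknown players: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    absences = absence_weeks(injuries)
    onsets: dict = {}
    for row in injuries.itertuples(index=False):
        onsets.setdefault(row.player_id, set()).add(int(row.onset_week))

    sessions = sessions.assign(load=sessions["duration_min"].to_numpy() * sessions["rpe"].to_numpy())
    weekly = (
        sessions.groupby(["player_id", "week"], sort=True)["load"].sum().rename("acute_load")
    )
    daily = sessions.groupby(["player_id", "week", "day"], sort=True)["load"].sum()

    rows = []
    n_absent_dropped = 0
    n_history_dropped = 0
    min_hist = 4 if coupled else 5
    for pid, series in weekly.groupby(level=0):
        series = series.droplevel(0).sort_index()
        absent = absences.get(pid, set())
        kept_weeks = [w for w in series.index if w not in absent]
        n_absent_dropped += len(series) - len(kept_weeks)
        loads = series.loc[kept_weeks].to_numpy(dtype=float)
        onset_set = onsets.get(pid, set())
        for i, w in enumerate(kept_weeks):
            if i + 1 < min_hist:
                n_history_dropped += 1
                continue
            hist = loads[: i + 1]
            al = loads[i]
            chron = float(hist[-4:].mean()) if coupled else float(hist[-5:-1].mean())
            row = {
                "player_id": pid,
                "week": int(w),
                "acute_load": al,
                "cumulative_load_2w": cumulative_load(hist, 2),
                "cumulative_load_3w": cumulative_load(hist, 3),
                "cumulative_load_4w": cumulative_load(hist, 4),
                "chronic_load": chron,
                "acwr": acwr(al, chron) if chron > 0 else np.nan,
                "acwrr": acwrr(al, acwrr_mean, acwrr_sd, rng=rng, floor=acwrr_floor),
                "injured": int(w) + 1 in onset_set,
            }
            try:
                row["monotony"] = monotony(daily.loc[(pid, w)].to_numpy(dtype=float))
            except (ValueError, KeyError):
                row["monotony"] = np.nan
            rows.append(row)

    for pid, wset in onsets.items():
        early = {w for w in wset if w <= min_hist}
        if early:
            logger.warning(
                "player %s: injury onset in week(s) %s precedes a defined chronic load; "
                "no model row carries it",
                pid,
                sorted(early),
            )
    logger.info(
        "observation table: %d rows (%d absence weeks excluded, %d short-history weeks dropped)",
        len(rows),
        n_absent_dropped,
        n_history_dropped,
    )
    obs = pd.DataFrame(rows)
    if obs.empty:
        return obs
    for metric, label in [("acwr", "acwr_quantile"), ("acwrr", "acwrr_quantile"), ("acute_load", "acute_quantile")]:
        vals = obs[metric].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        try:
            binning = fit_quantile_binning(vals[ok], metric_name=metric)
        except ValueError:
            obs[label] = np.nan
            continue
        labels = np.full(len(obs), np.nan)
        labels[ok] = binning.assign(vals[ok])
        obs[label] = labels
    return obs
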