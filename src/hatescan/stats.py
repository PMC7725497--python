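"""Stratified summaries, percent-change arithmetic and the hate-vs-cases
Pearson correlation.

Strata are either countries or the three study time periods
(2020-01-27..02-29, 03-01..03-31, 04-01..04-30; March 31 is folded into the
second window so every timestamp belongs to exactly one period).  For each
stratum the table reports hate/non-hate counts, the three hate-level counts,
their percentages (hate share relative to the stratum total, level shares
relative to the stratum's hate count) and the mean hate score of hate
tweets.  Reported percentages are rounded half-up to one decimal; raw values
are retained in machine-readable output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, datetime, timezone
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import TweetRecord

__all__ = [
    "StudyPeriods",
    "DEFAULT_PERIODS",
    "round_half_up",
    "tabulate",
    "percent_change",
    "share_of_total",
    "pearson",
    "build_report",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StudyPeriods:
    """Ordered, non-overlapping date windows (inclusive endpoints)."""

    windows: tuple[tuple[date, date], ...]

    def __post_init__(self) -> None:
        ws = tuple((w[0], w[1]) for w in self.windows)
        object.__setattr__(self, "windows", ws)
        for start, end in ws:
            if start > end:
                raise ValueError(f"window {start}..{end} is empty")
        for (_, e1), (s2, _) in zip(ws, ws[1:]):
            if s2 <= e1:
                raise ValueError("period windows must be ordered and disjoint")

    def period_of(self, ts: datetime) -> int:
        """0-based period index of a timestamp; raises if outside all windows."""
        day = ts.astimezone(timezone.utc).date() if ts.tzinfo else ts.date()
        for i, (start, end) in enumerate(self.windows):
            if start <= day <= end:
                return i
        raise ValueError(f"timestamp {ts.isoformat()} outside all study periods")

    def __len__(self) -> int:
        return len(self.windows)


DEFAULT_PERIODS = StudyPeriods((
    (date(2020, 1, 27), date(2020, 2, 29)),
    (date(2020, 3, 1), date(2020, 3, 31)),
    (date(2020, 4, 1), date(2020, 4, 30)),
))

_LEVEL_COLS = {"low": "n_low", "average": "n_average", "high": "n_high"}


def tabulate(
    records: Sequence[TweetRecord],
    stratifier: str,
    periods: StudyPeriods = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Stratified count/percentage table over a scored, geolocated corpus.

    ``stratifier`` is ``"country"`` or ``"period"``.  Every record must carry
    score/label/level (and country when stratifying by country).  Level
    percentages and the mean hate score are NaN for strata without hate
    tweets.
    """
    if stratifier not in ("country", "period"):
        raise ValueError("stratifier must be 'country' or 'period'")
    rows = []
    for rec in records:
        if rec.label is None or rec.level is None or rec.score is None:
            raise ValueError(f"record {rec.id} has not been scored")
        if stratifier == "country":
            if rec.country is None:
                raise ValueError(f"record {rec.id} has no resolved country")
            stratum: str | int = rec.country
        else:
            stratum = periods.period_of(rec.created_at)
        rows.append((stratum, rec.label == "hate", rec.level, rec.score))
    df = pd.DataFrame(rows, columns=["stratum", "is_hate", "level", "score"])

    out = []
    strata = sorted(df["stratum"].unique()) if len(df) else []
    for stratum in strata:
        g = df[df["stratum"] == stratum]
        n_total = len(g)
        n_hate = int(g["is_hate"].sum())
        level_counts = g.loc[g["is_hate"], "level"].value_counts()
        rec = {
            "stratum": stratum,
            "n_total": n_total,
            "n_hate": n_hate,
            "n_nonhate": n_total - n_hate,
        }
        for level, col in _LEVEL_COLS.items():
            rec[col] = int(level_counts.get(level, 0))
        rec["pct_hate"] = n_hate / n_total * 100.0
        for level, col in _LEVEL_COLS.items():
            rec[f"pct_{level}"] = (
                rec[col] / n_hate * 100.0 if n_hate else float("nan"))
        rec["mean_hate_score"] = (
            float(g.loc[g["is_hate"], "score"].mean()) if n_hate else float("nan"))
        out.append(rec)
    return pd.DataFrame(out).set_index("stratum") if out else pd.DataFrame(
        columns=["n_total", "n_hate", "n_nonhate", "n_low", "n_average",
                 "n_high", "pct_hate", "pct_low", "pct_average", "pct_high",
                 "mean_hate_score"])


def percent_change(before: float, after: float) -> float:
    """Signed percent change (after − before) / before × 100, one decimal."""
    if before <= 0:
        raise ValueError("percent change is undefined for before <= 0")
    return round_half_up((after - before) / before * 100.0, 1)


def share_of_total(part: float, total: float, ndigits: int = 1) -> float:
    """part / total × 100, rounded half-up to the reporting precision."""
    if total <= 0:
        raise ValueError("share is undefined for total <= 0")
    if not 0 <= part <= total:
        raise ValueError("part must lie in [0, total]")
    return round_half_up(part / total * 100.0, ndigits)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson is undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_report(
    records: Sequence[TweetRecord],
    epi: pd.DataFrame | None = None,
    periods: StudyPeriods = DEFAULT_PERIODS,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble country and period tables, percent changes and, when an
    epidemic series is supplied, the per-(country, period) hate-vs-cases
    Pearson correlation.

    ``epi`` needs columns country, period, cases, deaths.  When ``out_dir``
    is given, writes by_country.csv, by_period.csv and summary.json.
    """
    summary: dict = {
        "n_records": len(records),
        "periods": [[str(s), str(e)] for s, e in periods.windows],
        "period_note": "March 31 assigned to the second window",
    }
    if records:
        by_country = tabulate(records, "country", periods)
        by_period = tabulate(records, "period", periods)
        summary["total_hate"] = int(by_country["n_hate"].sum())
        changes = {}
        for name, col in (("tweets", "n_total"), ("hate_tweets", "n_hate")):
            series = by_period[col].reindex(range(len(periods)), fill_value=0)
            for i in range(1, len(series)):
                if series.iloc[i - 1] > 0:
                    changes[f"{name}_p{i}_to_p{i + 1}_pct"] = percent_change(
                        series.iloc[i - 1], series.iloc[i])
        summary["percent_changes"] = changes
    else:
        by_country = tabulate([], "country", periods)
        by_period = tabulate([], "period", periods)
        summary["total_hate"] = 0
        summary["percent_changes"] = {}

    if epi is not None and records:
        hate_by = {}
        for rec in records:
            if rec.label == "hate":
                key = (rec.country, periods.period_of(rec.created_at))
                hate_by[key] = hate_by.get(key, 0) + 1
        strata = [(str(r.country), int(r.period)) for r in epi.itertuples()]
        hate_vec = [hate_by.get(s, 0) for s in strata]
        case_vec = [int(r.cases) for r in epi.itertuples()]
        try:
            r, p = pearson(hate_vec, case_vec)
            summary["pearson_hate_vs_cases"] = {
                "r": r, "p": p, "n_strata": len(strata)}
        except ValueError as exc:
            summary["pearson_hate_vs_cases"] = {"error": str(exc)}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        by_country.to_csv(out_dir / "by_country.csv")
        by_period.to_csv(out_dir / "by_period.csv")
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, ensure_ascii=False, sort_keys=True),
            encoding="utf-8")
    summary["by_country"] = by_country
    summary["by_period"] = by_period
    return summary
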