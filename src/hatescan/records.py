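"""Tweet record container and JSONL / tabular I/O.

The pipeline's unit of data is a tweet record with the five attributes the
analysis retains: tweet id, text, creation time, user id and the free-form
profile location string.  Downstream stages annotate records in place with a
resolved country and with the classifier's score / label / hate level.

Corpora are exchanged as JSONL (one record per line, UTF-8); gazetteers and
lemma/stop-word resources as TSV; epidemic series as CSV.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "TweetRecord",
    "read_corpus",
    "write_corpus",
    "read_gazetteer",
    "write_gazetteer",
]


def _parse_ts(value: str | datetime) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass
class TweetRecord:
    """One tweet with the retained attributes plus pipeline annotations.

    ``country``, ``score``, ``label`` and ``level`` start as ``None`` and are
    filled in by the geolocation and scoring stages.
    """

    id: str
    text: str
    created_at: datetime
    user_id: str
    location: str = ""
    country: str | None = None
    score: float | None = None
    label: str | None = None
    level: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("tweet id must be nonempty")
        self.created_at = _parse_ts(self.created_at)

    def to_json(self) -> str:
        d = asdict(self)
        d["created_at"] = self.created_at.strftime("%Y-%m-%dT%H:%M:%SZ")
        for key in ("country", "score", "label", "level"):
            if d[key] is None:
                del d[key]
        return json.dumps(d, ensure_ascii=False)

    @classmethod
    def from_json(cls, line: str) -> "TweetRecord":
        d = json.loads(line)
        return cls(
            id=str(d["id"]),
            text=d["text"],
            created_at=d["created_at"],
            user_id=str(d.get("user_id", "")),
            location=d.get("location", "") or "",
            country=d.get("country"),
            score=d.get("score"),
            label=d.get("label"),
            level=d.get("level"),
        )


def read_corpus(path: str | Path) -> list[TweetRecord]:
    """Read a JSONL corpus; blank lines are ignored."""
    out: list[TweetRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TweetRecord.from_json(line))
    return out


def write_corpus(records: Iterable[TweetRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_gazetteer(path: str | Path) -> pd.DataFrame:
    """Read a gazetteer TSV with columns country, name, name_type."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = {"country", "name", "name_type"}
    if not expected.issubset(df.columns):
        raise ValueError(f"gazetteer must have columns {sorted(expected)}")
    return df


def write_gazetteer(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
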