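"""Synthetic corpora, gazetteers, training sets and epidemic series.

The real study corpus (hydrated Arabic COVID-19 tweets) cannot be
redistributed, so every pipeline stage is exercised against generated data
with the same statistical structure: Arabic-script token streams decorated
with URLs/mentions/emojis, a few percent hate prevalence, hate tweets built
around planted topic anchor vocabularies, free-form location strings drawn
from a gazetteer (optionally perturbed into informal aliases and clitic
variants), verbatim duplicates and retweet-marked records, timestamps
spanning the 2020-01-27..2020-04-30 study window, and an epidemic series
whose correlation with per-stratum hate counts is controlled exactly.

Tokens are synthetic strings over the Arabic alphabet plus genuine Arabic
function words (so normalization and stop-word logic meet real input); no
actual hate speech is generated — anchors are neutral placeholder tokens.

Generation is a pure function of (config, seed): identical seeds give
byte-identical corpora.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import EMOJI_NAMES
from .records import TweetRecord
from .stats import DEFAULT_PERIODS, StudyPeriods

__all__ = [
    "CorpusConfig",
    "EpiConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_gazetteer",
    "generate_labeled_training_set",
    "generate_epi_series",
    "DEFAULT_COUNTRY_SPECS",
    "default_gazetteer",
    "default_country_weights",
]

_ARABIC_LETTERS = "ابتثجحخدذرزسشصضطظعغفقكلمنهوي"

# Function words mixed into generated texts (raw forms; the preprocessing
# stop list carries their normalized spellings).
_FUNCTION_WORDS = ("في", "من", "على", "إلى", "عن", "هذا", "مع", "كل", "قد", "لا")

# (country, arabic country name, cities, informal aliases).  Names are
# unique across countries so that noise-free synthetic locations resolve
# unambiguously; deliberately ambiguous fixtures (e.g. a shared "Tripoli")
# can be built with generate_gazetteer.
DEFAULT_COUNTRY_SPECS: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = [
    ("Saudi Arabia", "السعودية",
     ("الرياض", "جدة", "مكة", "الدمام"),
     ("نجد", "Riyadh", "Jeddah", "Saudi", "KSA")),
    ("Kuwait", "الكويت", ("حولي", "الفروانية"),
     ("Q8", "Kuwait", "Kuwait City")),
    ("Egypt", "مصر", ("القاهرة", "الاسكندرية", "الجيزة"),
     ("Cairo", "Egypt", "ام الدنيا")),
    ("United Arab Emirates", "الامارات",
     ("دبي", "ابوظبي", "الشارقة", "العين"),
     ("دار زايد", "Dar Zayed", "UAE", "Dubai")),
    ("Lebanon", "لبنان", ("بيروت", "صيدا", "جونية"),
     ("Beirut", "Lebanon")),
    ("Yemen", "اليمن", ("صنعاء", "عدن", "تعز"), ("Yemen", "Sanaa")),
    ("Jordan", "الاردن", ("اربد", "الزرقاء", "العقبة"),
     ("Amman", "Jordan")),
    ("Oman", "عمان", ("مسقط", "صلالة"),
     ("Muscat", "Oman", "سلطنة عمان")),
    ("Iraq", "العراق", ("بغداد", "البصرة", "الموصل", "اربيل"),
     ("Baghdad", "Iraq")),
    ("Mauritania", "موريتانيا", ("نواكشوط",),
     ("Mauritania", "Nouakchott")),
    ("Palestine", "فلسطين", ("القدس", "غزة", "رام الله"),
     ("Palestine", "Gaza")),
    ("Algeria", "الجزائر", ("وهران", "قسنطينة"), ("Algeria", "Oran")),
    ("Libya", "ليبيا", ("طرابلس", "بنغازي"), ("Libya", "Tripoli")),
    ("Bahrain", "البحرين", ("المنامة",), ("Bahrain", "Manama")),
    ("Morocco", "المغرب", ("الرباط", "الدار البيضاء", "فاس", "مراكش"),
     ("Morocco", "Casablanca")),
    ("Qatar", "قطر", ("الدوحة",), ("Qatar", "Doha")),
    ("Sudan", "السودان", ("الخرطوم",), ("Sudan", "Khartoum")),
    ("Syria", "سوريا", ("دمشق", "حلب", "حمص"),
     ("Syria", "Damascus", "الشام")),
    ("Tunisia", "تونس", ("صفاقس", "سوسة"), ("Tunisia", "Tunis")),
    ("Comoros", "جزر القمر", ("موروني",), ("Comoros",)),
    ("Somalia", "الصومال", ("مقديشو",), ("Somalia", "Mogadishu")),
    ("Djibouti", "جيبوتي", (), ("Djibouti",)),
]

_UNRESOLVABLE_LOCATIONS = ("", "مكان ما", "كوكب الارض", "the moon", "🌍")


def generate_gazetteer(
    countries: Sequence[tuple[str, str, Sequence[str], Sequence[str]]],
) -> pd.DataFrame:
    """Build a (country, name, name_type) gazetteer table from specs.

    Each spec is (country, country name, city names, informal aliases).
    Duplicate (country, name) rows collapse; the same name under two
    countries is allowed (the resolver deals with the ambiguity).
    """
    rows = []
    for country, country_name, cities, aliases in countries:
        if not country_name:
            raise ValueError("country name must be nonempty")
        rows.append((country, country_name, "country"))
        rows.extend((country, c, "city") for c in cities if c)
        rows.extend((country, a, "alias") for a in aliases if a)
    df = pd.DataFrame(rows, columns=["country", "name", "name_type"])
    return df.drop_duplicates(subset=["country", "name"]).reset_index(drop=True)


def default_gazetteer() -> pd.DataFrame:
    return generate_gazetteer(DEFAULT_COUNTRY_SPECS)


def default_country_weights() -> dict[str, float]:
    """Country mixture shaped like the study's tweet-volume distribution:
    a Gulf/Egypt-heavy head and a long tail over the remaining countries."""
    named = {
        "Saudi Arabia": 0.24, "Kuwait": 0.15, "Egypt": 0.086,
        "United Arab Emirates": 0.056, "Lebanon": 0.051, "Yemen": 0.04,
        "Jordan": 0.03, "Oman": 0.028, "Iraq": 0.027, "Mauritania": 0.015,
    }
    rest = [c for c, *_ in DEFAULT_COUNTRY_SPECS if c not in named]
    share = (1.0 - sum(named.values())) / len(rest)
    named.update({c: share for c in rest})
    return named


def _check_prob_map(weights: Mapping, what: str) -> None:
    total = float(sum(weights.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {total!r})")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{what} must be nonnegative")


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the emulated study: a few percent hate prevalence, seven
    planted topics, a Gulf-heavy country mixture, the three-period time
    window with most traffic in March, and modest rates of informal-alias
    locations, verbatim duplicates, retweets and unresolvable locations.
    """

    n_tweets: int = 5000
    hate_prevalence: float = 0.03
    country_weights: Mapping[str, float] | None = None
    period_weights: Mapping[int, float] | None = None
    n_topics_planted: int = 7
    anchor_terms_per_topic: int = 4
    topic_weights: Sequence[float] | None = None
    alias_noise_rate: float = 0.15
    duplicate_rate: float = 0.05
    retweet_rate: float = 0.05
    unlocated_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tweets < 0:
            raise ValueError("n_tweets must be >= 0")
        for name in ("hate_prevalence", "alias_noise_rate", "duplicate_rate",
                     "retweet_rate", "unlocated_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_topics_planted < 1 or self.anchor_terms_per_topic < 3:
            raise ValueError("need >= 1 planted topic with >= 3 anchors each")
        if self.country_weights is not None:
            _check_prob_map(self.country_weights, "country_weights")
        if self.period_weights is not None:
            _check_prob_map(self.period_weights, "period_weights")
        if self.topic_weights is not None:
            _check_prob_map(dict(enumerate(self.topic_weights)), "topic_weights")


@dataclass
class SyntheticCorpus:
    """Generated records plus the ground truth the tests compare against."""

    records: list[TweetRecord]
    labels: pd.DataFrame   # id, is_hate, topic, country, period, is_retweet, duplicate_of
    anchors: list[list[str]]
    background_vocab: list[str]
    gazetteer: pd.DataFrame


def _unique_tokens(rng: np.random.Generator, count: int,
                   taken: set[str]) -> list[str]:
    letters = list(_ARABIC_LETTERS)
    out: list[str] = []
    while len(out) < count:
        length = int(rng.integers(3, 7))
        tok = "".join(rng.choice(letters, size=length))
        if tok not in taken:
            taken.add(tok)
            out.append(tok)
    return out


def _uniform_timestamp(rng: np.random.Generator, periods: StudyPeriods,
                       period: int) -> datetime:
    start, end = periods.windows[period]
    t0 = datetime(start.year, start.month, start.day, tzinfo=timezone.utc)
    t1 = datetime(end.year, end.month, end.day, tzinfo=timezone.utc)
    span = int((t1 - t0).total_seconds()) + 86_400
    return datetime.fromtimestamp(
        t0.timestamp() + int(rng.integers(0, span)), tz=timezone.utc)


def _weighted_choice(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights.keys())
    probs = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


_CLITICS_FOR_NOISE = ("ال", "و", "ب", "في")


def _location_for(rng: np.random.Generator, country: str,
                  gaz_by_country: Mapping[str, pd.DataFrame],
                  alias_noise_rate: float) -> str:
    rows = gaz_by_country[country]
    if float(rng.random()) < alias_noise_rate:
        aliases = rows[rows["name_type"] == "alias"]
        if len(aliases) and float(rng.random()) < 0.7:
            return str(aliases.iloc[int(rng.integers(len(aliases)))]["name"])
        base = str(rows.iloc[int(rng.integers(len(rows)))]["name"])
        if any("؀" <= ch <= "ۿ" for ch in base):
            return str(rng.choice(_CLITICS_FOR_NOISE)) + base
        return base
    plain = rows[rows["name_type"].isin(["country", "city"])]
    return str(plain.iloc[int(rng.integers(len(plain)))]["name"])


def generate_corpus(
    config: CorpusConfig,
    gazetteer: pd.DataFrame | None = None,
    periods: StudyPeriods = DEFAULT_PERIODS,
) -> SyntheticCorpus:
    """Generate a corpus with ground-truth labels.

    Hate tweets contain 3-5 anchor terms of exactly one planted topic on top
    of background vocabulary; non-hate tweets contain background vocabulary
    only.  A ``duplicate_rate`` fraction are verbatim copies of earlier
    records, a ``retweet_rate`` fraction are retweet-marked, and an
    ``unlocated_rate`` fraction carry unresolvable location strings.
    """
    gaz = default_gazetteer() if gazetteer is None else gazetteer
    country_weights = dict(config.country_weights or default_country_weights())
    missing = set(country_weights) - set(gaz["country"])
    if missing:
        raise ValueError(f"country_weights name countries absent from the "
                         f"gazetteer: {sorted(missing)}")
    period_weights = dict(config.period_weights or
                          {0: 0.217, 1: 0.464, 2: 0.319})
    if any(p not in range(len(periods)) for p in period_weights):
        raise ValueError("period_weights reference unknown period indices")
    topic_weights = (list(config.topic_weights)
                     if config.topic_weights is not None
                     else [1.0 / config.n_topics_planted] * config.n_topics_planted)
    if len(topic_weights) != config.n_topics_planted:
        raise ValueError("topic_weights length must equal n_topics_planted")

    rng = np.random.default_rng(config.seed)
    taken: set[str] = set(_FUNCTION_WORDS)
    background = _unique_tokens(rng, 250, taken)
    anchors = [_unique_tokens(rng, config.anchor_terms_per_topic, taken)
               for _ in range(config.n_topics_planted)]
    gaz_by_country = {c: g.reset_index(drop=True)
                      for c, g in gaz.groupby("country")}
    emojis = sorted(EMOJI_NAMES)

    records: list[TweetRecord] = []
    label_rows: list[dict] = []
    originals: list[int] = []   # indices of non-retweet fresh records

    for i in range(config.n_tweets):
        rid = f"t{i:06d}"
        period = int(_weighted_choice(rng, period_weights))
        created = _uniform_timestamp(rng, periods, period)
        user = f"u{int(rng.integers(0, max(config.n_tweets, 10))):06d}"

        if originals and float(rng.random()) < config.duplicate_rate:
            src = label_rows[int(rng.choice(originals))]
            rec = TweetRecord(id=rid, text=src["text"], created_at=created,
                              user_id=user, location=src["location"])
            label_rows.append({**src, "id": rid, "period": period,
                               "duplicate_of": src["id"]})
            records.append(rec)
            continue

        is_hate = float(rng.random()) < config.hate_prevalence
        topic = int(_weighted_choice(
            rng, dict(enumerate(topic_weights)))) if is_hate else -1
        country = str(_weighted_choice(rng, country_weights))

        length = int(rng.integers(8, 19))
        tokens = [str(rng.choice(background)) if rng.random() > 0.2
                  else str(rng.choice(_FUNCTION_WORDS))
                  for _ in range(length)]
        if is_hate:
            n_anchor = int(rng.integers(3, 6))
            for _ in range(n_anchor):
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, str(rng.choice(anchors[topic])))
        text = " ".join(tokens)
        if float(rng.random()) < 0.2:
            text += f" http://t.co/{int(rng.integers(0, 10**6)):06d}"
        if float(rng.random()) < 0.2:
            text += f" @user{int(rng.integers(0, 1000)):03d}"
        if float(rng.random()) < 0.15:
            text += " " + str(rng.choice(emojis))

        is_retweet = float(rng.random()) < config.retweet_rate
        if is_retweet:
            text = f"RT @user{int(rng.integers(0, 1000)):03d}: {text}"

        if float(rng.random()) < config.unlocated_rate:
            location = str(rng.choice(_UNRESOLVABLE_LOCATIONS))
        else:
            location = _location_for(rng, country, gaz_by_country,
                                     config.alias_noise_rate)

        rec = TweetRecord(id=rid, text=text, created_at=created,
                          user_id=user, location=location)
        label_rows.append({
            "id": rid, "text": text, "location": location,
            "is_hate": is_hate, "topic": topic, "country": country,
            "period": period, "is_retweet": is_retweet, "duplicate_of": "",
        })
        if not is_retweet:
            originals.append(i)
        records.append(rec)

    labels = pd.DataFrame(
        label_rows,
        columns=["id", "text", "location", "is_hate", "topic", "country",
                 "period", "is_retweet", "duplicate_of"],
    )
    return SyntheticCorpus(records=records, labels=labels, anchors=anchors,
                           background_vocab=background, gazetteer=gaz)


def generate_labeled_training_set(
    n: int, separability: float, seed: int = 0, hate_fraction: float = 0.5,
) -> pd.DataFrame:
    """Labeled texts for classifier training.

    Each hate text is drawn, with probability ``separability``, entirely
    from a hate-indicative token pool (disjoint from the benign pool);
    otherwise — like every non-hate text — entirely from the benign pool.
    At separability 1.0 the two classes therefore share no vocabulary.  The
    returned frame has columns text, label (1 = hate) and indicative (did
    the indicative pool fire), the latter supporting exact binomial checks.

    The emulated prior-work corpus's class balance is unknown, so
    ``hate_fraction`` is exposed as a parameter.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    hate_pool = _unique_tokens(rng, 60, taken)
    benign_pool = _unique_tokens(rng, 240, taken)
    rows = []
    for _ in range(n):
        label = int(rng.random() < hate_fraction)
        indicative = bool(label and float(rng.random()) < separability)
        pool = hate_pool if indicative else benign_pool
        length = int(rng.integers(8, 16))
        rows.append({
            "text": " ".join(str(rng.choice(pool)) for _ in range(length)),
            "label": label,
            "indicative": indicative,
        })
    return pd.DataFrame(rows, columns=["text", "label", "indicative"])


@dataclass(frozen=True)
class EpiConfig:
    """Controls for the synthetic epidemic series."""

    target_correlation: float = 0.2
    deaths_per_case: float = 0.05
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_correlation <= 1.0:
            raise ValueError("target_correlation must lie in [-1, 1]")
        if self.deaths_per_case < 0 or self.noise_scale < 0:
            raise ValueError("deaths_per_case and noise_scale must be >= 0")


def generate_epi_series(
    hate_counts: Mapping[tuple[str, int], int], config: EpiConfig,
) -> pd.DataFrame:
    """Case/death counts whose correlation with hate counts is controlled.

    The case vector is built from the standardized hate-count vector plus an
    orthogonalized noise vector, so before integer rounding the sample
    Pearson correlation equals ``target_correlation`` exactly;
    ``noise_scale`` adds further independent noise on top.  Deaths are
    ``deaths_per_case`` × cases plus noise, floored at zero.
    """
    strata = sorted(hate_counts.items())
    if len(strata) < 3:
        raise ValueError("need at least 3 strata for a defined correlation")
    h = np.asarray([v for _, v in strata], dtype=float)
    if np.ptp(h) == 0:
        raise ValueError("hate counts are constant; correlation is degenerate")
    rng = np.random.default_rng(config.seed)
    rho = config.target_correlation

    if abs(rho) == 1.0 and config.noise_scale == 0:
        scale = 10 if rho > 0 else -10
        base = 100 - scale * h.min() if rho > 0 else 100 - scale * h.max()
        cases = (base + scale * h).astype(int)
    else:
        hs = (h - h.mean()) / h.std()
        e = rng.standard_normal(len(h))
        e -= e.mean()
        e -= (e @ hs) / (hs @ hs) * hs          # orthogonal to hate counts
        if np.allclose(e, 0):
            e = np.ones_like(h)
            e -= (e @ hs) / (hs @ hs) * hs
        e /= e.std()
        y = rho * hs + np.sqrt(max(1 - rho * rho, 0.0)) * e
        cases_f = 2000.0 + 500.0 * y
        cases_f += config.noise_scale * rng.standard_normal(len(h))
        cases = np.maximum(np.rint(cases_f), 0).astype(int)

    deaths_f = config.deaths_per_case * cases
    deaths_f = deaths_f + config.noise_scale * rng.standard_normal(len(h))
    deaths = np.maximum(np.rint(deaths_f), 0).astype(int)

    return pd.DataFrame({
        "country": [c for (c, _), _ in strata],
        "period": [p for (_, p), _ in strata],
        "cases": cases,
        "deaths": deaths,
    })
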