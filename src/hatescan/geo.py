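"""Resolve free-form profile location strings to countries.

Twitter profile locations are free text ("Riyadh", "Q8", "دار زايد",
"somewhere on earth"), so resolution goes through a lexicon built from a
gazetteer of country names, city names and informal aliases.  Every name is
orthographically normalized and expanded with simple morphological variants
(the definite article and common proclitics), then matching collects
candidates over single tokens, contiguous token n-grams and the full string.

Conflicts are handled conservatively: a match on a country-type name outranks
city/alias matches, and any remaining multi-country tie yields UNRESOLVED
rather than an arbitrary assignment — silently misassigning a country would
corrupt every per-country statistic downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .preprocess import normalize_orthography
from .records import TweetRecord

__all__ = ["UNRESOLVED", "CountryLexicon", "build_lexicon", "resolve_location",
           "attach_countries"]

UNRESOLVED = "UNRESOLVED"

# Proclitic prefixes attached to place names in informal writing:
# wa- (and), bi- (in/with), li- (to/for), fi- (in).  Applied, together with
# the definite article al-, to Arabic-script names only.
_DEFINITE_ARTICLE = "ال"
_CLITICS = ("و", "ب", "ل", "في")


def _is_arabic(name: str) -> bool:
    return any("؀" <= ch <= "ۿ" for ch in name)


def name_variants(name: str) -> set[str]:
    """Morphological variants of a normalized name.

    The bare form; for Arabic-script names also the definite-article form and
    each proclitic attached to both.
    """
    variants = {name}
    if _is_arabic(name):
        forms = {name, _DEFINITE_ARTICLE + name}
        variants |= forms
        variants |= {clitic + form for clitic in _CLITICS for form in forms}
    return variants


@dataclass
class CountryLexicon:
    """Index from normalized name variants to (country, name_type) pairs."""

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, name: str, country: str, name_type: str) -> None:
        key = normalize_orthography(name)
        if not key:
            return
        self.entries.setdefault(key, set()).add((country, name_type))

    def lookup(self, key: str) -> set[tuple[str, str]]:
        return self.entries.get(key, set())

    @property
    def max_key_words(self) -> int:
        return max((key.count(" ") + 1 for key in self.entries), default=0)

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(gazetteer: pd.DataFrame) -> CountryLexicon:
    """Build the resolution lexicon from a (country, name, name_type) table.

    Names are normalized and expanded with :func:`name_variants`; all variants
    index back to the same (country, name_type).  An empty gazetteer yields an
    empty lexicon (resolution then always fails, which is not an error).
    """
    lex = CountryLexicon()
    for row in gazetteer.itertuples(index=False):
        base = normalize_orthography(str(row.name))
        if not base:
            continue
        for variant in name_variants(base):
            lex.add(variant, str(row.country), str(row.name_type))
    return lex


def resolve_location(raw: str, lexicon: CountryLexicon) -> str:
    """Resolve one free-form location string to a country or UNRESOLVED.

    The string receives the same normalization/cleaning as the lexicon names.
    Candidates are collected over contiguous token n-grams (longest first, so
    multiword aliases are caught) and the full string.  If the candidate set
    names exactly one country, that country wins; otherwise matches on
    country-type names outrank city/alias matches; any remaining tie is
    UNRESOLVED.
    """
    cleaned = normalize_orthography(raw)
    if not cleaned:
        return UNRESOLVED
    tokens = cleaned.split()
    max_n = min(len(tokens), max(lexicon.max_key_words, 1))
    hits: set[tuple[str, str]] = set()
    for n in range(max_n, 0, -1):
        for i in range(len(tokens) - n + 1):
            hits |= lexicon.lookup(" ".join(tokens[i:i + n]))
    hits |= lexicon.lookup(cleaned)
    if not hits:
        return UNRESOLVED
    countries = {c for c, _ in hits}
    if len(countries) == 1:
        return next(iter(countries))
    by_country_name = {c for c, t in hits if t == "country"}
    if len(by_country_name) == 1:
        return next(iter(by_country_name))
    return UNRESOLVED


def attach_countries(
    corpus: Sequence[TweetRecord], lexicon: CountryLexicon
) -> list[TweetRecord]:
    """Annotate records with their resolved country; drop unresolved ones.

    Mirrors the study design of retaining only tweets whose user profile
    location could be mapped to a country.
    """
    out: list[TweetRecord] = []
    for rec in corpus:
        country = resolve_location(rec.location, lexicon)
        if country != UNRESOLVED:
            rec.country = country
            out.append(rec)
    return out
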