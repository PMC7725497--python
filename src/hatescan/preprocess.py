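"""Tweet text cleaning and Arabic orthographic normalization.

Two cleaning modes mirror the two consumers of tweet text:

* ``classifier`` — emojis are replaced by description tokens (lower-cased,
  underscore-joined short names), because affect-bearing emoji carry signal
  for hate classification;
* ``topic`` — emojis are deleted, keeping the topic-model vocabulary purely
  lexical.

In both modes URLs become the literal token ``URL`` and @-mentions become
``mention``; punctuation, residual non-Arabic letters, immediately repeated
tokens and extra whitespace are removed.  Orthographic normalization maps
interchangeable Arabic letterforms (hamzated/madda alefs, alef maksura, teh
marbuta) to canonical ones and strips diacritics, so that spelling variants
of the same place or word compare equal.

Lemmatization is a pluggable table lookup: any token→lemma mapping (for
instance one exported from a morphological analyzer) can be injected.
"""
from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import TweetRecord

__all__ = [
    "ProcessedText",
    "normalize_orthography",
    "clean_text",
    "lemmatize",
    "remove_stopwords",
    "remove_retweets_and_duplicates",
    "preprocess_text",
    "DEFAULT_STOPWORDS",
    "EMOJI_NAMES",
]

MODES = ("classifier", "topic")

# Letterform folding: hamzated and madda alefs -> bare alef, alef maksura ->
# yeh, teh marbuta -> heh.
_LETTER_MAP = str.maketrans({
    "أ": "ا",  # alef with hamza above
    "إ": "ا",  # alef with hamza below
    "آ": "ا",  # alef with madda
    "ى": "ي",  # alef maksura -> yeh
    "ة": "ه",  # teh marbuta -> heh
})
_DIACRITICS_RE = re.compile("[ً-ٟ]")
_WS_RE = re.compile(r"\s+")

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+|\bt\.co/\S+)")
_MENTION_RE = re.compile(r"@\w+")

# Emoji codepoints handled by the cleaner: pictograph planes, misc
# symbols/dingbats/arrows, variation selectors and the zero-width joiner.
_EMOJI_RE = re.compile(
    "[\U0001F000-\U0001FAFF"
    "☀-➿"
    "⬀-⯿"
    "←-⇿"
    "︎️‍]"
)
_EMOJI_JOINERS = ("︎", "️", "‍")

# Short names (CLDR-style, lower-cased, underscore-joined) for the emoji the
# pipeline commonly meets; anything else maps to the generic token "emoji".
EMOJI_NAMES: dict[str, str] = {
    "\U0001F602": "face_with_tears_of_joy",
    "\U0001F621": "enraged_face",
    "\U0001F92C": "face_with_symbols_on_mouth",
    "\U0001F637": "face_with_medical_mask",
    "\U0001F9A0": "microbe",
    "\U0001F64F": "folded_hands",
    "\U0001F489": "syringe",
    "❤": "red_heart",
    "\U0001F62D": "loudly_crying_face",
    "\U0001F47F": "angry_face_with_horns",
    "\U0001F922": "nauseated_face",
    "\U0001F494": "broken_heart",
}
_GENERIC_EMOJI = "emoji"

# Private-use sentinels protect placeholder tokens through the
# non-Arabic-letter removal step.
_URL_SENTINEL = ""
_MENTION_SENTINEL = ""
_DESC_SENTINELS: dict[str, str] = {
    desc: chr(0xE010 + i)
    for i, desc in enumerate(sorted(set(EMOJI_NAMES.values()) | {_GENERIC_EMOJI}))
}
_SENTINEL_TO_TOKEN = {
    _URL_SENTINEL: "URL",
    _MENTION_SENTINEL: "mention",
    **{s: d for d, s in _DESC_SENTINELS.items()},
}
_LITERAL_PLACEHOLDER_RE = re.compile(
    r"\b(URL|mention|" + "|".join(map(re.escape, sorted(_DESC_SENTINELS))) + r")\b"
)
# Arabic letters/diacritics + sentinels survive cleaning; Arabic punctuation
# and digits go the way of all other punctuation and non-Arabic letters.
_NON_KEPT_RE = re.compile(
    "[^\u0620-\u065F\u0640\u066E-\u06D3\u06D5-\u06EF\u06FA-\u06FF"
    "\uE000-\uE0FF\\s]"
)


@dataclass(frozen=True)
class ProcessedText:
    """Token sequence produced by one of the two cleaning modes."""

    tokens: tuple[str, ...]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        object.__setattr__(self, "tokens", tuple(self.tokens))


def normalize_orthography(text: str) -> str:
    """Fold Arabic letterform variants and strip diacritics/punctuation.

    Idempotent; also case-folds Latin script so that e.g. ``Q8`` and ``q8``
    compare equal when matching gazetteer entries.
    """
    text = text.translate(_LETTER_MAP)
    text = _DIACRITICS_RE.sub("", text)
    text = "".join(
        " " if unicodedata.category(ch)[0] in ("P", "S") else ch for ch in text
    )
    text = text.casefold()
    return _WS_RE.sub(" ", text).strip()


def _collapse_repeats(tokens: list[str]) -> list[str]:
    out: list[str] = []
    for tok in tokens:
        if not out or out[-1] != tok:
            out.append(tok)
    return out


def clean_text(text: str, mode: str) -> ProcessedText:
    """Clean one tweet text into tokens for the given mode.

    URLs/mentions are replaced before non-Arabic letters are removed so the
    ``URL`` / ``mention`` placeholders survive; re-cleaning already-cleaned
    text is a no-op (placeholder tokens are recognized and preserved).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    s = _URL_RE.sub(f" {_URL_SENTINEL} ", text)
    s = _MENTION_RE.sub(f" {_MENTION_SENTINEL} ", s)
    s = _LITERAL_PLACEHOLDER_RE.sub(
        lambda m: {
            "URL": _URL_SENTINEL,
            "mention": _MENTION_SENTINEL,
        }.get(m.group(1), _DESC_SENTINELS.get(m.group(1), m.group(1))),
        s,
    )
    if mode == "classifier":
        s = _EMOJI_RE.sub(
            lambda m: (
                " " + _DESC_SENTINELS[EMOJI_NAMES.get(m.group(0), _GENERIC_EMOJI)] + " "
                if m.group(0) not in _EMOJI_JOINERS
                else " "
            ),
            s,
        )
    else:
        s = _EMOJI_RE.sub(" ", s)
    s = _NON_KEPT_RE.sub(" ", s)
    tokens = [_SENTINEL_TO_TOKEN.get(t, t) for t in s.split()]
    return ProcessedText(tuple(_collapse_repeats(tokens)), mode)


def lemmatize(tokens: Sequence[str], lemma_table: Mapping[str, str]) -> list[str]:
    """Replace each token by its lemma when present; length-preserving."""
    return [lemma_table.get(t, t) for t in tokens]


def remove_stopwords(tokens: Sequence[str], stoplist: Iterable[str]) -> list[str]:
    """Order-preserving stop-word filter; the stoplist is assumed normalized."""
    stops = set(stoplist)
    return [t for t in tokens if t not in stops]


def preprocess_text(
    text: str,
    mode: str,
    lemma_table: Mapping[str, str] | None = None,
    stopwords: Iterable[str] | None = None,
) -> ProcessedText:
    """Full text pipeline: clean, lemmatize (table lookup), drop stop words."""
    processed = clean_text(text, mode)
    tokens = list(processed.tokens)
    if lemma_table:
        tokens = lemmatize(tokens, lemma_table)
    if stopwords is not None:
        tokens = remove_stopwords(tokens, stopwords)
    return ProcessedText(tuple(tokens), mode)


_RT_MARKER = "RT @"


def remove_retweets_and_duplicates(corpus: Sequence[TweetRecord]) -> list[TweetRecord]:
    """Drop retweet-marked records, then deduplicate identical content.

    A record is a retweet if its text starts with ``RT @``.  Duplicate
    detection keys on the orthographically normalized text; within each
    duplicate group the record with the earliest ``created_at`` survives
    (ties broken by lexicographic id).  Output preserves input order.
    """
    candidates = [r for r in corpus if not r.text.startswith(_RT_MARKER)]
    best: dict[str, TweetRecord] = {}
    for rec in candidates:
        key = normalize_orthography(rec.text)
        cur = best.get(key)
        if cur is None or (rec.created_at, rec.id) < (cur.created_at, cur.id):
            best[key] = rec
    keep = {id(r) for r in best.values()}
    return [r for r in candidates if id(r) in keep]


# Common Arabic function words, stored in normalized orthography.
DEFAULT_STOPWORDS: frozenset[str] = frozenset({
    "في",          # fi (in)
    "من",          # min (from)
    "علي",    # ala (on; normalized)
    "الي",    # ila (to; normalized)
    "عن",          # an (about)
    "ان",          # inna/an
    "او",          # aw (or)
    "اذا",    # idha (if)
    "لا",          # la (no)
    "ما",          # ma (what/not)
    "لم",          # lam (not)
    "لن",          # lan (will not)
    "هذا",    # hadha (this)
    "هذه",    # hadhihi (this, fem.)
    "ذلك",    # dhalika (that)
    "التي",  # allati (which, fem.)
    "الذي",  # alladhi (which)
    "كان",    # kana (was)
    "كانت",  # kanat (was, fem.)
    "مع",          # maa (with)
    "هو",          # huwa (he)
    "هي",          # hiya (she)
    "هم",          # hum (they)
    "نحن",    # nahnu (we)
    "انا",    # ana (I)
    "انت",    # anta (you)
    "قد",          # qad
    "كل",          # kull (all)
    "بعد",    # baada (after)
    "قبل",    # qabla (before)
    "عند",    # inda (at)
    "بين",    # bayna (between)
    "حتي",    # hatta (until; normalized)
    "ثم",          # thumma (then)
    "لكن",    # lakin (but)
    "يا",          # ya (vocative)
    "اي",          # ayy (any)
    "غير",    # ghayr (other than)
    "بل",          # bal (rather)
    "و",                # wa (and)
})
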