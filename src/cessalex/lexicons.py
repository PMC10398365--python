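"""Category word banks ("lexicons") used for occurrence-frequency scoring.

A lexicon is an ordered mapping of category name -> set of single-token
match words.  Category order is part of the object's identity: it fixes
the dimension order of every frequency vector downstream, so two profiles
are comparable only if they were scored with the same lexicon.

Two default banks ship with the package:

* a 21-category emotion bank built around Plutchik's primary and secondary
  emotions plus the self-conscious/social emotions prominent in cessation
  posts (pride, gratitude, remorse, anxiety, ...);
* a 15-category time bank (morning, evening, week, year, ...) used as a
  non-emotional control vocabulary.

The shipped word lists are this package's own curation; every pipeline
stage accepts a user lexicon loaded from CSV or JSON instead.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Tuple

from .preprocess import preprocess_text

__all__ = [
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "default_emotion_lexicon",
    "default_time_lexicon",
]


class LexiconError(ValueError):
    """Raised for structurally invalid lexicon input."""


@dataclass(frozen=True)
class Lexicon:
    """An ordered category -> word-set mapping.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"emotion-21"``.
    categories:
        Ordered mapping category name -> frozenset of match words.  Every
        word must be a lowercase single token that survives preprocessing
        unchanged.
    """

    name: str
    categories: Mapping[str, FrozenSet[str]]
    _index: Dict[str, Tuple[int, ...]] = field(
        init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if not self.categories:
            raise LexiconError(f"lexicon {self.name!r} has no categories")
        for cat, words in self.categories.items():
            if not words:
                raise LexiconError(f"category {cat!r} has no words")
            for w in words:
                if preprocess_text(w) != [w]:
                    raise LexiconError(
                        f"word {w!r} in category {cat!r} is not a "
                        "normalised single token")
        # word -> tuple of category indices; a shared word maps to several
        index: Dict[str, List[int]] = {}
        for i, words in enumerate(self.categories.values()):
            for w in words:
                index.setdefault(w, []).append(i)
        overlap = sorted(w for w, idx in index.items() if len(idx) > 1)
        if overlap:
            warnings.warn(
                f"lexicon {self.name!r}: {len(overlap)} word(s) shared "
                f"between categories (e.g. {overlap[0]!r}); frequency "
                "percentages may exceed 100 in sum", stacklevel=2)
        object.__setattr__(
            self, "_index", {w: tuple(idx) for w, idx in index.items()})

    @property
    def K(self) -> int:
        """Number of categories (vector dimension)."""
        return len(self.categories)

    @property
    def category_names(self) -> Tuple[str, ...]:
        return tuple(self.categories)

    def word_index(self) -> Dict[str, Tuple[int, ...]]:
        """Mapping word -> category indices it belongs to."""
        return self._index

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column ``category,word`` CSV with header."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["category", "word"])
            for cat, words in self.categories.items():
                for w in sorted(words):
                    writer.writerow([cat, w])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({c: sorted(ws) for c, ws in self.categories.items()},
                      fh, indent=1)


def _build(name: str, pairs: Iterable[Tuple[str, str]]) -> Lexicon:
    """Assemble a Lexicon from (category, raw word) pairs.

    Words are pushed through the same preprocessing as post text so that
    lexicon matching and text tokenisation can never disagree on case or
    punctuation.  Duplicate (category, word) pairs collapse silently.
    """
    cats: Dict[str, List[str]] = {}
    seen: set = set()
    n = 0
    for cat, raw_word in pairs:
        n += 1
        tokens = preprocess_text(str(raw_word))
        if not tokens:
            raise LexiconError(
                f"word {raw_word!r} in category {cat!r} normalises to "
                "nothing (pure punctuation?)")
        if len(tokens) > 1:
            raise LexiconError(
                f"multi-token entry {raw_word!r} in category {cat!r}; "
                "lexicon entries must be single words")
        word = tokens[0]
        key = (str(cat), word)
        if key in seen:
            continue
        seen.add(key)
        cats.setdefault(str(cat), []).append(word)
    if n == 0:
        raise LexiconError(f"lexicon source for {name!r} is empty")
    return Lexicon(name, {c: frozenset(ws) for c, ws in cats.items()})


def load_lexicon(path: str | Path, format: str | None = None) -> Lexicon:
    """Load a lexicon from a ``category,word`` CSV or a JSON mapping.

    Parameters
    ----------
    path:
        CSV file (two columns ``category,word``, header required) or JSON
        file (object mapping category -> array of words).
    format:
        ``"csv"`` or ``"json"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    name = path.stem
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, dict) or not data:
            raise LexiconError(f"{path}: expected a non-empty JSON object")
        pairs = [(c, w) for c, words in data.items() for w in words]
        return _build(name, pairs)
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise LexiconError(f"{path}: empty lexicon file") from None
            if [h.strip().lower() for h in header[:2]] != ["category", "word"]:
                raise LexiconError(
                    f"{path}: expected header 'category,word', got {header}")
            pairs = [(row[0], row[1]) for row in reader if row]
        return _build(name, pairs)
    raise LexiconError(f"unknown lexicon format {format!r}")


# --------------------------------------------------------------------------
# Default word banks.
#
# The emotion bank covers Plutchik's eight primary emotions (joy, trust,
# fear, surprise, sadness, disgust, anger, anticipation), the secondary
# dyads (love, optimism, awe, submission, remorse, contempt, disapproval,
# aggressiveness), the intensity variant terror, and the social/self-
# conscious emotions pride, gratitude, anxiety and serenity: 21 categories.
# Word lists are deliberately compact, surface-form only (no stemming), and
# pairwise disjoint so the 21 percentages sum to 100.
# --------------------------------------------------------------------------

_EMOTION_BANK: Dict[str, Tuple[str, ...]] = {
    "anxiety": ("anxious", "anxiety", "worried", "worry", "worrying",
                "nervous", "stress", "stressed", "stressful", "uneasy",
                "restless", "tense", "jittery", "apprehensive"),
    "sadness": ("sad", "sadness", "unhappy", "depressed", "depressing",
                "miserable", "gloomy", "crying", "cried", "tearful",
                "sorrow", "grief", "heartbroken", "lonely"),
    "optimism": ("optimistic", "optimism", "hopeful", "hope", "hoping",
                 "confident", "positive", "encouraged", "encouraging",
                 "upbeat", "promising", "motivated", "determined"),
    "joy": ("happy", "happiness", "joy", "joyful", "glad", "cheerful",
            "delighted", "elated", "ecstatic", "merry", "smiling",
            "laughing"),
    "love": ("love", "loved", "loving", "adore", "affection", "caring",
             "cherish", "darling", "beloved", "fond", "sweetheart"),
    "disgust": ("disgust", "disgusted", "disgusting", "gross", "nasty",
                "revolting", "sickening", "repulsive", "yuck", "foul",
                "vile", "repugnant"),
    "pride": ("proud", "pride", "accomplished", "accomplishment",
              "achievement", "achieved", "triumphant", "triumph",
              "milestone"),
    "gratitude": ("grateful", "gratitude", "thankful", "thanks", "thank",
                  "appreciate", "appreciated", "appreciation", "blessed"),
    "remorse": ("remorse", "regret", "regretful", "guilty", "guilt",
                "ashamed", "shame", "sorry", "apologize", "repent"),
    "terror": ("terror", "terrified", "terrifying", "horror", "horrified",
               "horrific", "petrified", "dread", "dreading"),
    "fear": ("fear", "afraid", "scared", "scary", "frightened",
             "frightening", "fearful", "spooked", "panicking", "panic"),
    "anger": ("angry", "anger", "mad", "furious", "rage", "irritated",
              "irritable", "annoyed", "resentful", "outraged", "frustrated"),
    "trust": ("trust", "trusted", "trusting", "reliable", "faith",
              "faithful", "dependable", "loyal", "honest"),
    "surprise": ("surprise", "surprised", "surprising", "shocked", "shock",
                 "astonished", "amazed", "stunned", "unexpected"),
    "anticipation": ("anticipation", "anticipating", "eager", "eagerly",
                     "excited", "excitement", "expectant", "awaiting",
                     "craving", "looking"),
    "awe": ("awe", "awesome", "wonder", "wonderful", "marvelous",
            "magnificent", "breathtaking", "sublime", "amazing"),
    "contempt": ("contempt", "scorn", "disdain", "sneer", "mocking",
                 "condescending", "smug", "dismissive"),
    "submission": ("submissive", "submission", "obedient", "yielding",
                   "meek", "compliant", "deferential", "surrender"),
    "disapproval": ("disapproval", "disapprove", "objection", "criticize",
                    "criticism", "condemn", "rebuke", "disappointed",
                    "disappointing", "disappointment"),
    "aggressiveness": ("aggressive", "aggression", "hostile", "hostility",
                       "attack", "fight", "fighting", "combative",
                       "belligerent"),
    "serenity": ("serene", "serenity", "calm", "calmer", "peaceful",
                 "peace", "tranquil", "relaxed", "relaxing", "content",
                 "soothing"),
}

_TIME_BANK: Dict[str, Tuple[str, ...]] = {
    "morning": ("morning", "mornings", "dawn", "sunrise", "daybreak"),
    "afternoon": ("afternoon", "afternoons", "midday", "noon"),
    "evening": ("evening", "evenings", "dusk", "sunset", "twilight"),
    "night": ("night", "nights", "midnight", "overnight", "nighttime",
              "tonight"),
    "day": ("day", "days", "daily", "daytime"),
    "week": ("week", "weeks", "weekly", "fortnight"),
    "month": ("month", "months", "monthly"),
    "year": ("year", "years", "yearly", "annual", "anniversary"),
    "hour": ("hour", "hours", "hourly"),
    "minute": ("minute", "minutes", "moment", "moments"),
    "today": ("today", "nowadays", "currently"),
    "yesterday": ("yesterday", "earlier", "previously", "ago"),
    "tomorrow": ("tomorrow", "soon", "later", "upcoming"),
    "weekend": ("weekend", "weekends", "saturday", "sunday"),
    "season": ("season", "seasons", "spring", "summer", "autumn", "winter"),
}


def default_emotion_lexicon() -> Lexicon:
    """The shipped 21-category emotion word bank."""
    return _build("emotion-21",
                  [(c, w) for c, ws in _EMOTION_BANK.items() for w in ws])


def default_time_lexicon() -> Lexicon:
    """The shipped 15-category time word bank (non-emotional control)."""
    return _build("time-15",
                  [(c, w) for c, ws in _TIME_BANK.items() for w in ws])
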