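"""Word-bank match counting, occurrence-frequency profiles, the
median-split density filter, and percentile outlier detection.

The profile of a forum is the pooled count of lexicon matches over all its
posts, normalised once by the total match count and expressed as
percentages ("occurrence frequency"): a K-vector summing to 100.  The
total match count itself is the forum's emotion score, used to exclude
emotion-poor forums (those at or below the sample median).  A target forum
is an outlier on a category when its occurrence frequency exceeds the
95th percentile of the control forums' frequencies on that category.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np

from .corpus_io import Corpus
from .lexicons import Lexicon
from .preprocess import preprocess_text

__all__ = [
    "CategoryCounts",
    "CorpusProfile",
    "OutlierReport",
    "ScoringError",
    "count_matches",
    "corpus_profile",
    "emotion_score",
    "median_split_retain",
    "percentile_outliers",
]

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryCounts:
    """Per-category match counts for one token stream or pooled corpus."""

    lexicon_name: str
    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        """Total lexicon matches (the "emotion score" for an emotion bank)."""
        return int(sum(self.counts.values()))

    def as_array(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=float)


@dataclass(frozen=True)
class CorpusProfile:
    """A forum's normalised occurrence-frequency vector.

    ``frequencies[c] = 100 * counts[c] / total``; the K percentages sum to
    100 (for a lexicon with disjoint categories).
    """

    forum: str
    counts: CategoryCounts
    frequencies: Mapping[str, float]

    @property
    def lexicon_name(self) -> str:
        return self.counts.lexicon_name

    def vector(self) -> np.ndarray:
        return np.array(list(self.frequencies.values()), dtype=float)


@dataclass(frozen=True)
class OutlierReport:
    """Per-category outlier flags for one target forum vs controls."""

    forum: str
    q: float
    frequencies: Mapping[str, float]
    thresholds: Mapping[str, float]

    @property
    def outliers(self) -> Tuple[str, ...]:
        return tuple(c for c in self.frequencies
                     if self.frequencies[c] > self.thresholds[c])

    def is_outlier(self, category: str) -> bool:
        return self.frequencies[category] > self.thresholds[category]


def count_matches(tokens: Iterable[str], lexicon: Lexicon) -> CategoryCounts:
    """Count, per category, how many tokens belong to its word set.

    A token appearing in m categories increments all m counts.
    """
    names = lexicon.category_names
    counts = np.zeros(lexicon.K, dtype=np.int64)
    index = lexicon.word_index()
    for tok in tokens:
        hit = index.get(tok)
        if hit is not None:
            for i in hit:
                counts[i] += 1
    return CategoryCounts(lexicon.name,
                          dict(zip(names, (int(c) for c in counts))))


def _pooled_counts(corpus: Corpus, lexicon: Lexicon,
                   fields: str) -> CategoryCounts:
    if fields not in ("body", "title+body"):
        raise ScoringError(f"fields must be 'body' or 'title+body', "
                           f"got {fields!r}")
    names = lexicon.category_names
    index = lexicon.word_index()
    counts = np.zeros(lexicon.K, dtype=np.int64)
    for post in corpus.posts:
        text = post.body if fields == "body" else f"{post.title}\n{post.body}"
        for tok in preprocess_text(text):
            hit = index.get(tok)
            if hit is not None:
                for i in hit:
                    counts[i] += 1
    return CategoryCounts(lexicon.name,
                          dict(zip(names, (int(c) for c in counts))))


def corpus_profile(corpus: Corpus, lexicon: Lexicon,
                   fields: str = "body") -> CorpusProfile:
    """Pool match counts over all posts and normalise once.

    Counts are summed across posts and the percentages computed from the
    pooled totals (not averaged per post), so long posts weigh in
    proportion to their matches.
    """
    counts = _pooled_counts(corpus, lexicon, fields)
    total = counts.total
    if total == 0:
        raise ScoringError(
            f"no lexicon matches in corpus {corpus.forum!r}")
    freqs = {c: 100.0 * n / total for c, n in counts.counts.items()}
    return CorpusProfile(corpus.forum, counts, freqs)


def emotion_score(corpus: Corpus, lexicon: Lexicon,
                  fields: str = "body", per_token: bool = False) -> float:
    """Total lexicon matches in a corpus (optionally per-token rate)."""
    counts = _pooled_counts(corpus, lexicon, fields)
    if not per_token:
        return float(counts.total)
    n_tokens = sum(
        len(preprocess_text(p.body if fields == "body"
                            else f"{p.title}\n{p.body}"))
        for p in corpus.posts)
    return counts.total / n_tokens if n_tokens else 0.0


def median_split_retain(scores: Mapping[str, float]) -> set:
    """Retain forums whose score strictly exceeds the sample median.

    Forums at or below the median are the "emotion-poor" half and are
    excluded.  With n distinct scores this retains floor(n/2) forums.
    """
    if len(scores) < 2:
        raise ScoringError("median split needs at least 2 forums")
    values = np.array(list(scores.values()), dtype=float)
    med = float(np.median(values))
    retained = {f for f, s in scores.items() if s > med}
    if not retained:
        warnings.warn("median split retained no forums (all scores equal?)",
                      stacklevel=2)
    logger.info("median split: median=%.1f, retained %d of %d forums",
                med, len(retained), len(scores))
    return retained


def percentile_outliers(target: CorpusProfile,
                        controls: Sequence[CorpusProfile],
                        q: float = 95.0) -> OutlierReport:
    """Flag categories where the target exceeds the controls' q-th percentile.

    The threshold per category is the q-th percentile of the control
    forums' occurrence frequencies, computed with linear interpolation
    between order statistics; the flag is strict (``frequency > threshold``).
    """
    if not controls:
        raise ScoringError("need at least one control profile")
    for c in controls:
        if c.lexicon_name != target.lexicon_name:
            raise ScoringError(
                f"lexicon mismatch: target scored with "
                f"{target.lexicon_name!r}, control {c.forum!r} with "
                f"{c.lexicon_name!r}")
        if tuple(c.frequencies) != tuple(target.frequencies):
            raise ScoringError("control/target category order mismatch")
    if len(controls) < 20:
        warnings.warn(
            f"only {len(controls)} control profiles; percentile "
            "thresholds will be coarse", stacklevel=2)
    names = list(target.frequencies)
    ctrl = np.array([c.vector() for c in controls])  # (n_controls, K)
    thresholds = np.percentile(ctrl, q, axis=0)      # linear interpolation
    return OutlierReport(
        forum=target.forum, q=q,
        frequencies=dict(target.frequencies),
        thresholds=dict(zip(names, (float(t) for t in thresholds))))
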