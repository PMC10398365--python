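"""Abstinence-duration dynamics of emotion expression.

Posts on some cessation forums carry a self-reported number of days since
last substance use.  This module analyses that metadata:

* the share of posts made within the first 24 hours of abstinence,
  against the uniform-chance expectation over the observed duration range;
* the emotion profile of those first-day posts;
* emotion trajectories over 15 duration bins up to a 1000-day cutoff,
  split into short-term (< 100 days, 9 bins) and long-term (>= 100 days,
  6 bins) levels;
* a two-way fixed-effects ANOVA (emotion x abstinence level, bins as
  replicates within level) and Bonferroni-corrected post-hoc t tests.

Because each bin's percentages are normalised to sum to 100, the
abstinence main effect is analytically zero for any such table: both
level means are forced to 100/K.  Only the interaction can carry signal,
which is why the post-hoc contrasts are per-emotion comparisons of the
bin-level percentages across the two levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .lexicons import Lexicon
from .corpus_io import Post
from .preprocess import preprocess_text
from .scoring import CorpusProfile, count_matches

__all__ = [
    "AbstinenceBins",
    "BinnedEmotionTable",
    "AnovaEffect",
    "AnovaResult",
    "TTestResult",
    "AbstinenceError",
    "default_bins",
    "filter_abstinence_tagged",
    "first_day_fraction",
    "uniform_chance_first_day",
    "first_day_profile",
    "bin_posts",
    "two_way_anova",
    "posthoc_ttests",
]

logger = logging.getLogger(__name__)


class AbstinenceError(ValueError):
    pass


@dataclass(frozen=True)
class AbstinenceBins:
    """15 duration bins over [0, 1000] days.

    ``edges`` holds the 16 ascending bin edges; bins are half-open
    ``[edges[i], edges[i+1])`` except the last, which is closed at 1000.
    ``edges[9]`` must equal 100: the first 9 bins are the short-term
    level, the last 6 the long-term level.
    """

    edges: Tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) != 16:
            raise AbstinenceError(f"need 16 edges (15 bins), got {len(e)}")
        if np.any(np.diff(e) <= 0):
            raise AbstinenceError("edges must be strictly ascending")
        if e[9] != 100.0 or e[-1] != 1000.0:
            raise AbstinenceError(
                "edge 9 must be 100 (short/long boundary) and the last "
                "edge 1000 (cutoff)")
        object.__setattr__(self, "edges", tuple(float(x) for x in e))

    @property
    def n_bins(self) -> int:
        return 15

    @property
    def short_bins(self) -> Tuple[int, ...]:
        """Indices of bins entirely below 100 days."""
        return tuple(range(9))

    @property
    def long_bins(self) -> Tuple[int, ...]:
        """Indices of bins at or above 100 days."""
        return tuple(range(9, 15))

    def assign(self, day: float) -> Optional[int]:
        """Bin index for an abstinence duration, or None if beyond cutoff."""
        if day < 0 or day > self.edges[-1]:
            return None
        idx = int(np.searchsorted(self.edges, day, side="right")) - 1
        return min(idx, 14)   # day == 1000 falls in the final closed bin


def default_bins() -> AbstinenceBins:
    """Day-0 bin [0, 1) followed by 14 logarithmic bins from 1 to 1000.

    The log spacing is anchored so that exactly 9 bins lie below the
    100-day short/long boundary: 8 log-spaced bins on [1, 100) after the
    day-0 bin, then 6 log-spaced bins on [100, 1000].
    """
    short = 10.0 ** (2.0 * np.arange(9) / 8.0)          # 1 .. 100
    long = 100.0 * 10.0 ** (np.arange(1, 7) / 6.0)      # .. 1000
    edges = np.concatenate([[0.0], short, long])
    edges[9] = 100.0
    edges[-1] = 1000.0
    return AbstinenceBins(tuple(edges))


@dataclass(frozen=True)
class BinnedEmotionTable:
    """Category x bin occurrence-frequency table.

    ``counts`` is (n_bins, K) raw match counts; ``percentages`` the same
    with each non-empty bin normalised to sum to 100.  ``n_posts`` counts
    posts per bin.
    """

    forum: str
    lexicon_name: str
    categories: Tuple[str, ...]
    counts: np.ndarray
    percentages: np.ndarray
    n_posts: np.ndarray

    def empty_bins(self) -> List[int]:
        return [i for i in range(self.counts.shape[0])
                if self.counts[i].sum() == 0]


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects two-way ANOVA: emotion, abstinence level, interaction."""

    emotion: AnovaEffect
    abstinence: AnovaEffect
    interaction: AnovaEffect


@dataclass(frozen=True)
class TTestResult:
    emotion: str
    t: float
    df: float
    p: float
    alpha_adjusted: float
    significant: bool
    method: str = "pooled"


def filter_abstinence_tagged(posts: Sequence[Post],
                             n_keep: int = 1205) -> List[Post]:
    """Text posts carrying abstinence metadata, truncated to the most recent.

    If fewer than ``n_keep`` posts qualify, all of them are returned with
    a warning rather than an error (the truncation exists to equalise
    sample sizes across forums, not as a hard requirement).
    """
    tagged = [p for p in posts
              if p.abstinence_days is not None and p.has_text()]
    tagged.sort(key=lambda p: -p.created_utc)
    if not tagged:
        warnings.warn("no abstinence-tagged text posts", stacklevel=2)
        return []
    if len(tagged) < n_keep:
        warnings.warn(
            f"only {len(tagged)} abstinence-tagged posts "
            f"(< n_keep={n_keep}); returning all", stacklevel=2)
        return tagged
    return tagged[:n_keep]


def first_day_fraction(posts: Sequence[Post]) -> float:
    """Percentage of tagged posts made within the first 24 h of abstinence."""
    if not posts:
        raise AbstinenceError("no posts")
    n0 = sum(1 for p in posts if p.abstinence_days is not None
             and p.abstinence_days < 1.0)
    return 100.0 * n0 / len(posts)


def uniform_chance_first_day(range_days: float = 10000.0) -> float:
    """Expected first-day share (%) if posting were uniform over the range."""
    if range_days < 1:
        raise AbstinenceError("range_days must be >= 1")
    return 100.0 / range_days


def first_day_profile(posts: Sequence[Post], lexicon: Lexicon,
                      top_m: int = 5,
                      ) -> Tuple[CorpusProfile, List[Tuple[str, float]]]:
    """Emotion profile of posts made in the first 24 hours of abstinence.

    Returns the pooled profile over day-0 posts and the ``top_m``
    categories by occurrence frequency (ties broken lexicographically).
    """
    day0 = [p for p in posts if p.abstinence_days is not None
            and p.abstinence_days < 1.0]
    if not day0:
        raise AbstinenceError("no posts within the first 24 hours")
    forum = day0[0].forum
    tokens: List[str] = []
    for p in day0:
        tokens.extend(preprocess_text(p.body))
    counts = count_matches(tokens, lexicon)
    if counts.total == 0:
        raise AbstinenceError("no lexicon matches in first-day posts")
    freqs = {c: 100.0 * n / counts.total for c, n in counts.counts.items()}
    profile = CorpusProfile(forum, counts, freqs)
    ranked = sorted(freqs.items(), key=lambda cf: (-cf[1], cf[0]))
    return profile, ranked[:top_m]


def bin_posts(posts: Sequence[Post], lexicon: Lexicon,
              bins: Optional[AbstinenceBins] = None,
              forum: str = "") -> BinnedEmotionTable:
    """Assign tagged posts to duration bins and count matches per bin.

    Posts beyond the 1000-day cutoff are excluded.  Each non-empty bin's
    counts are normalised to percentages summing to 100.
    """
    if bins is None:
        bins = default_bins()
    K = lexicon.K
    index = lexicon.word_index()
    counts = np.zeros((bins.n_bins, K), dtype=np.int64)
    n_posts = np.zeros(bins.n_bins, dtype=np.int64)
    n_excluded = 0
    for p in posts:
        if p.abstinence_days is None:
            continue
        b = bins.assign(p.abstinence_days)
        if b is None:
            n_excluded += 1
            continue
        n_posts[b] += 1
        for tok in preprocess_text(p.body):
            hit = index.get(tok)
            if hit is not None:
                for i in hit:
                    counts[b, i] += 1
    if n_excluded:
        logger.info("bin_posts: excluded %d posts beyond %.0f-day cutoff",
                    n_excluded, bins.edges[-1])
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * counts / totals, 0.0)
    if not forum and posts:
        forum = posts[0].forum
    return BinnedEmotionTable(forum, lexicon.name, lexicon.category_names,
                              counts, pct, n_posts)


def _long_frame(table: BinnedEmotionTable,
                bins: AbstinenceBins) -> pd.DataFrame:
    empty = table.empty_bins()
    if empty:
        raise AbstinenceError(
            f"bin(s) {empty} contain no lexicon matches; the per-bin "
            "percentage response is undefined there")
    rows = []
    for b in range(bins.n_bins):
        level = "short" if b in bins.short_bins else "long"
        for k, cat in enumerate(table.categories):
            rows.append((cat, level, b, table.percentages[b, k]))
    return pd.DataFrame(rows, columns=["emotion", "level", "bin", "pct"])


def two_way_anova(table: BinnedEmotionTable,
                  bins: Optional[AbstinenceBins] = None) -> AnovaResult:
    """Two-way fixed-effects ANOVA on the per-bin emotion percentages.

    Factors: emotion category (K levels) and abstinence level (short/
    long), with the bins serving as replicates within each level.  Sums
    of squares are sequential (type I) with emotion entered first; since
    every bin's percentages sum to 100, both level means equal 100/K and
    the abstinence main effect is analytically zero regardless of order.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if bins is None:
        bins = default_bins()
    frame = _long_frame(table, bins)
    resp = frame["pct"].to_numpy()
    # degenerate table: no variation at all -> every effect is zero
    if np.ptp(resp) <= 1e-12 * max(1.0, abs(resp.mean())):
        k = len(table.categories)
        nb = bins.n_bins
        zero = lambda dfn: AnovaEffect(0.0, dfn, k * nb - 2 * k, 1.0)
        return AnovaResult(emotion=zero(k - 1), abstinence=zero(1),
                           interaction=zero(k - 1))
    model = ols("pct ~ C(emotion) * C(level)", data=frame).fit()
    aov = sm.stats.anova_lm(model, typ=1)

    def effect(term: str) -> AnovaEffect:
        row = aov.loc[term]
        F = float(row["F"])
        if not np.isfinite(F):
            F = 0.0
        p = float(row["PR(>F)"])
        if not np.isfinite(p):
            p = 1.0
        return AnovaEffect(F=max(F, 0.0), df_num=int(row["df"]),
                           df_den=int(aov.loc["Residual", "df"]), p=p)

    return AnovaResult(emotion=effect("C(emotion)"),
                       abstinence=effect("C(level)"),
                       interaction=effect("C(emotion):C(level)"))


def posthoc_ttests(table: BinnedEmotionTable,
                   bins: Optional[AbstinenceBins] = None,
                   emotions: Optional[Sequence[str]] = None,
                   alpha: float = 0.05,
                   method: str = "pooled") -> List[TTestResult]:
    """Per-emotion short vs long contrasts on bin-level percentages.

    Two-sided independent-samples t tests (pooled variance by default,
    ``method="welch"`` for the unequal-variance form) comparing an
    emotion's percentage across the 9 short bins vs the 6 long bins, with
    a Bonferroni threshold of ``alpha / len(emotions)``.
    """
    if bins is None:
        bins = default_bins()
    if emotions is None:
        emotions = list(table.categories)
    unknown = [e for e in emotions if e not in table.categories]
    if unknown:
        raise AbstinenceError(f"unknown emotion(s): {unknown}")
    if len(bins.short_bins) < 2 or len(bins.long_bins) < 2:
        raise AbstinenceError("each level needs >= 2 bins")
    alpha_adj = alpha / len(emotions)
    results = []
    cat_idx = {c: k for k, c in enumerate(table.categories)}
    short = list(bins.short_bins)
    long = list(bins.long_bins)
    for emo in emotions:
        k = cat_idx[emo]
        a = table.percentages[short, k]
        b = table.percentages[long, k]
        equal_var = method == "pooled"
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        if not np.isfinite(t):     # zero variance in both groups
            if np.isclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
            else:
                t = np.inf if a.mean() > b.mean() else -np.inf
                p = 0.0
            df = len(a) + len(b) - 2 if equal_var else float("nan")
        results.append(TTestResult(emotion=emo, t=t, df=df, p=p,
                                   alpha_adjusted=alpha_adj,
                                   significant=p < alpha_adj,
                                   method=method))
    return results
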