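"""Reading post dumps and applying the corpus inclusion filters.

Posts arrive as JSON Lines, one submission per line, with the fields
``forum, author, created_utc, title, body, abstinence_days`` (the last two
optional).  A :class:`Corpus` is the per-forum unit of analysis: the posts
from one fixed-size extraction window, ordered newest first.

The inclusion filters mirror the study design they implement:

* a forum enters the sample only if at least ``min_text`` of its
  ``window`` extracted posts carry body text (>= 1 token after
  preprocessing; image-only posts have none),
* retained forums are truncated to the same number of most-recent text
  posts so that every profile pools an identical number of posts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from .preprocess import preprocess_text

__all__ = [
    "Post",
    "Corpus",
    "CorpusError",
    "read_posts_jsonl",
    "write_posts_jsonl",
    "group_by_forum",
    "filter_text_posts",
    "passes_inclusion",
    "truncate_recent",
    "count_unique_authors",
]

logger = logging.getLogger(__name__)

DELETED_AUTHOR = "[deleted]"


class CorpusError(ValueError):
    pass


@dataclass(frozen=True)
class Post:
    """One forum submission."""

    forum: str
    author: str
    created_utc: float
    title: str = ""
    body: str = ""          # empty string = image-only post
    abstinence_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.created_utc <= 0:
            raise CorpusError(f"created_utc must be positive, "
                              f"got {self.created_utc}")
        if self.abstinence_days is not None and self.abstinence_days < 0:
            raise CorpusError("abstinence_days must be >= 0")

    def has_text(self) -> bool:
        """True if the body yields at least one token after preprocessing."""
        return bool(preprocess_text(self.body))


@dataclass(frozen=True)
class Corpus:
    """All posts from one forum's extraction window, newest first."""

    forum: str
    posts: Sequence[Post]
    window_size: int

    def __post_init__(self) -> None:
        for p in self.posts:
            if p.forum != self.forum:
                raise CorpusError(
                    f"post from forum {p.forum!r} in corpus {self.forum!r}")
        ts = [p.created_utc for p in self.posts]
        if any(a < b for a, b in zip(ts, ts[1:])):
            # normalise: sort newest first, stable so input order breaks ties
            ordered = sorted(self.posts,
                             key=lambda p: -p.created_utc)
            object.__setattr__(self, "posts", tuple(ordered))
        else:
            object.__setattr__(self, "posts", tuple(self.posts))

    def __len__(self) -> int:
        return len(self.posts)


def _parse_line(forum_line: str) -> Post:
    rec = json.loads(forum_line)
    return Post(
        forum=rec["forum"],
        author=rec["author"],
        created_utc=float(rec["created_utc"]),
        title=rec.get("title", ""),
        body=rec.get("body") or "",
        abstinence_days=(None if rec.get("abstinence_days") is None
                         else float(rec["abstinence_days"])),
    )


def read_posts_jsonl(path: str | Path,
                     max_malformed_frac: float = 0.05) -> List[Post]:
    """Read posts from a JSON Lines dump.

    Malformed lines are skipped and counted; if more than
    ``max_malformed_frac`` of non-blank lines fail to parse, the file is
    rejected with an error reporting the count.
    """
    path = Path(path)
    posts: List[Post] = []
    bad = 0
    total = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            total += 1
            try:
                posts.append(_parse_line(line))
            except (json.JSONDecodeError, KeyError, TypeError,
                    ValueError, CorpusError) as exc:
                bad += 1
                logger.warning("%s:%d skipped malformed line (%s)",
                               path, lineno, exc)
    if total == 0:
        raise CorpusError(f"{path}: no records")
    if bad / total > max_malformed_frac:
        raise CorpusError(
            f"{path}: {bad} of {total} lines malformed "
            f"(> {max_malformed_frac:.0%} allowed)")
    if bad:
        logger.info("%s: skipped %d malformed of %d lines", path, bad, total)
    return posts


def write_posts_jsonl(posts: Iterable[Post], path: str | Path) -> None:
    """Write posts in the same JSONL dialect ``read_posts_jsonl`` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = {"forum": p.forum, "author": p.author,
                   "created_utc": p.created_utc, "title": p.title,
                   "body": p.body}
            if p.abstinence_days is not None:
                rec["abstinence_days"] = p.abstinence_days
            fh.write(json.dumps(rec) + "\n")


def group_by_forum(posts: Iterable[Post],
                   window_size: Optional[int] = None) -> Dict[str, Corpus]:
    """Split a flat post list into per-forum corpora.

    ``window_size`` defaults to the number of posts seen per forum (the
    dump is assumed to hold the full extraction window for each forum).
    """
    buckets: Dict[str, List[Post]] = {}
    for p in posts:
        buckets.setdefault(p.forum, []).append(p)
    return {f: Corpus(f, ps, window_size if window_size is not None
                      else len(ps))
            for f, ps in buckets.items()}


def filter_text_posts(corpus: Corpus) -> Corpus:
    """Drop image-only posts (no body token after preprocessing)."""
    kept = [p for p in corpus.posts if p.has_text()]
    logger.info("filter_text_posts[%s]: %d -> %d posts",
                corpus.forum, len(corpus.posts), len(kept))
    return replace(corpus, posts=tuple(kept))


def passes_inclusion(corpus: Corpus, min_text: int = 3000,
                     window: int = 5025) -> bool:
    """Forum-level inclusion rule on the fixed extraction window.

    True iff at least ``min_text`` of the window's posts carry body text.
    """
    if corpus.window_size != window:
        raise CorpusError(
            f"{corpus.forum}: inclusion rule is defined on a window of "
            f"{window} posts, corpus has window_size={corpus.window_size}")
    n_text = sum(1 for p in corpus.posts if p.has_text())
    return n_text >= min_text


def truncate_recent(corpus: Corpus, n: int = 3003) -> Corpus:
    """Keep the ``n`` most recent posts (largest ``created_utc``).

    Ties at the boundary are broken by input order (stable sort in
    :class:`Corpus` ordering).
    """
    if len(corpus.posts) < n:
        raise CorpusError(
            f"{corpus.forum}: need {n} posts to truncate, have "
            f"{len(corpus.posts)} ({n - len(corpus.posts)} short)")
    return replace(corpus, posts=corpus.posts[:n])


def count_unique_authors(corpus: Corpus,
                         deleted_sentinel: str = DELETED_AUTHOR) -> int:
    """Distinct author pseudonyms, excluding the deleted-account sentinel."""
    return len({p.author for p in corpus.posts
                if p.author != deleted_sentinel})
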