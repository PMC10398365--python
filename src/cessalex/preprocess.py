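"""Text normalisation for word-bank matching.

Raw forum posts arrive with markup, punctuation and arbitrary casing.
Every count in the pipeline is a count over the token stream this module
produces, so the rules are deliberately minimal and fixed:

1. markup tags of the form ``<...>`` are removed first (so ``<b>`` cannot
   leak a ``b`` token),
2. every Unicode punctuation or symbol character is replaced by a space
   (so contractions split: ``don't`` -> ``don``, ``t``),
3. letters are lowercased (full Unicode casefold-free ``str.lower``),
4. tokens are maximal runs of non-whitespace; numerals are retained.

No stemming, stopword removal or negation handling is performed: the
scoring model counts surface forms only.
"""

from __future__ import annotations

import re
import unicodedata
from typing import List

__all__ = ["preprocess_text", "tokenize_words"]

_TAG_RE = re.compile(r"<[^<>]*>")


class _PunctTable(dict):
    """Lazy ``str.translate`` table mapping punctuation/symbols to a space.

    Unicode categories P* (punctuation) and S* (symbols) are mapped to
    U+0020; every other codepoint maps to itself.  Decisions are cached so
    repeated corpus passes pay the category lookup once per codepoint.
    """

    def __missing__(self, code: int) -> int:
        cat = unicodedata.category(chr(code))
        res = 0x20 if cat[0] in ("P", "S") else code
        self[code] = res
        return res


_PUNCT_TABLE = _PunctTable()


def preprocess_text(raw: str, *, strip_numerals: bool = False,
                    min_token_len: int = 1) -> List[str]:
    """Normalise ``raw`` into a list of lowercase, punctuation-free tokens.

    Parameters
    ----------
    raw:
        Any string; an empty string yields an empty list.
    strip_numerals:
        Drop tokens consisting entirely of digits.  Off by default.
    min_token_len:
        Minimum token length to retain (default 1, i.e. keep everything).

    Returns
    -------
    list of str
        The token stream; no token is empty or contains whitespace,
        punctuation or markup.
    """
    text = _TAG_RE.sub(" ", raw)
    text = text.translate(_PUNCT_TABLE).lower()
    tokens = text.split()
    if strip_numerals:
        tokens = [t for t in tokens if not t.isdigit()]
    if min_token_len > 1:
        tokens = [t for t in tokens if len(t) >= min_token_len]
    return tokens


# alias used by callers that care about the "token" framing
tokenize_words = preprocess_text
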