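"""Shared text utilities: tokenization and the stop-word list."""

from __future__ import annotations

import re

#: Small English function-word list; kept short on purpose — attribute labels
#: are terse and aggressive stop-wording would delete informative tokens.
STOP_WORDS = frozenset(
    """a an and are as at be by for from has have how in is it its of on or
    that the this to was were will with your you per""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str, drop_stop_words: bool = True) -> list[str]:
    """Lowercase, split on non-alphanumerics, optionally drop stop words."""
    toks = _TOKEN_RE.findall(text.casefold())
    if drop_stop_words:
        toks = [t for t in toks if t not in STOP_WORDS]
    return toks
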