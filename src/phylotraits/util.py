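"""Small shared helpers: label normalisation and seeding."""

from __future__ import annotations

import re

import numpy as np

# trailing authority strings like "(L.) Mill." or "Baker" after a binomial
_AUTHORITY = re.compile(r"\s*\(.*?\)\s*[A-Z].*$|\s+[A-Z][a-z]*\.$")


def normalize_label(label: str, *, casefold: bool = False, strip_authority: bool = False) -> str:
    """Normalise a taxon label: trim, collapse whitespace to underscores.

    Trait tables and trees often come from different sources; underscore
    normalisation makes ``Aloe vera`` and ``Aloe_vera`` the same tip.
    """
    s = label.strip().strip("'\"")
    if strip_authority:
        s = _AUTHORITY.sub("", s)
    s = re.sub(r"\s+", "_", s)
    if casefold:
        s = s.casefold()
    return s


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator.

    Every stochastic operation takes an explicit ``seed``; there is no
    hidden global RNG state anywhere in the package.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from ``seed``."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return ss.spawn(n)
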