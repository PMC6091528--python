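"""Compound-name canonicalization used when matching across sources.

Metabolite spellings vary across libraries and reports ("myo-inositol",
"Myoinositol", "myo inositol"); matching is done case-insensitively after
stripping whitespace, hyphens and underscores, with a small synonym map for
spellings that differ beyond punctuation.
"""

from __future__ import annotations

import re

#: synonym -> canonical spelling, applied after punctuation stripping
SYNONYMS = {
    "niacinamide": "nicotinamide",
    "vitaminb3": "nicotinamide",
    "dglucose": "glucose",
    "dgalactose": "galactose",
    "dmannose": "mannose",
    "dribose": "ribose",
}


def canonical_name(name: str) -> str:
    """Collapse a compound name to a spelling-insensitive canonical key."""
    key = re.sub(r"[\s\-_,()']+", "", name.strip().lower())
    return SYNONYMS.get(key, key)
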