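"""Five-state ordinal expression calls and their numeric encoding.

An *in situ* hybridization (ISH) signal in a tissue is scored on a
semi-quantitative ordinal scale: ``negative < weak < medium < strong``,
with a fifth state, ``na`` (not analyzed), for tissues where the signal
could not be determined reliably.  The ordinal codes used downstream for
rank correlation are ``0, 2, 3, 4`` — the gap between negative and weak
is part of the published scoring scheme and is kept verbatim; rank-based
statistics are invariant to it anyway.
"""
from __future__ import annotations

import enum


class ExpressionLevel(str, enum.Enum):
    """One exclusive expression call for a (gene, tissue) cell."""

    NOT_ANALYZED = "na"
    NEGATIVE = "negative"
    WEAK = "weak"
    MEDIUM = "medium"
    STRONG = "strong"

    def __str__(self) -> str:  # canonical lowercase token
        return self.value


#: Ordinal codes fed to rank-correlation; NOT_ANALYZED has no code and is
#: masked out of every rank computation.
ORDINAL_VALUE: dict[ExpressionLevel, float] = {
    ExpressionLevel.NEGATIVE: 0.0,
    ExpressionLevel.WEAK: 2.0,
    ExpressionLevel.MEDIUM: 3.0,
    ExpressionLevel.STRONG: 4.0,
}

#: States counted as "expressed" (any detectable signal).
EXPRESSED_STATES = frozenset(
    {ExpressionLevel.WEAK, ExpressionLevel.MEDIUM, ExpressionLevel.STRONG}
)

#: Canonical output tokens in scale order, NOT_ANALYZED first.
STATE_ORDER = (
    ExpressionLevel.NOT_ANALYZED,
    ExpressionLevel.NEGATIVE,
    ExpressionLevel.WEAK,
    ExpressionLevel.MEDIUM,
    ExpressionLevel.STRONG,
)

_ALIASES: dict[str, ExpressionLevel] = {
    "n.a.": ExpressionLevel.NOT_ANALYZED,
    "n/a": ExpressionLevel.NOT_ANALYZED,
    "na": ExpressionLevel.NOT_ANALYZED,
    "not analyzed": ExpressionLevel.NOT_ANALYZED,
    "not_analyzed": ExpressionLevel.NOT_ANALYZED,
    "neg": ExpressionLevel.NEGATIVE,
    "negative": ExpressionLevel.NEGATIVE,
    "weak": ExpressionLevel.WEAK,
    "med": ExpressionLevel.MEDIUM,
    "medium": ExpressionLevel.MEDIUM,
    "strong": ExpressionLevel.STRONG,
}


def parse_level(token: str) -> ExpressionLevel:
    """Parse a state token (case-insensitive, aliases accepted).

    Raises ``ValueError`` for anything that is not one of the five states
    or a known alias.
    """
    key = token.strip().lower()
    try:
        return _ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown expression state token: {token!r}") from None


def round_pct(count: int, total: int) -> float:
    """Percentage ``100*count/total`` rounded to one decimal.

    The product is formed before the division and both are carried out in
    IEEE double precision; the final rounding is round-half-to-even on the
    double (``%.1f`` semantics).  With counts out of 2000 every value lands
    on an exact tenth or a ``.x5`` tie, and this is the rule that reproduces
    the published summary table for every cell.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return float(f"{100 * count / total:.1f}")
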