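"""Gene-list overlap testing against a universe.

Overlap between a study gene list and an external list is summarized in a
2x2 contingency table over a fixed gene universe (the unique genes left
after probe filtering) and tested with Fisher's exact test, two-sided by the
minimum-likelihood rule. The reported odds ratio is the sample
cross-product ``a*d / (b*c)``, not the conditional MLE some packages print.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Collection

from scipy.stats import fisher_exact as _scipy_fisher

__all__ = ["ContingencyTable", "build_contingency", "fisher_exact_test"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap counts within a universe.

    a = in both lists, b = in list A only, c = in list B only,
    d = in neither. ``a + b + c + d`` equals the universe size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def build_contingency(
    set_a: Collection[str], set_b: Collection[str], universe: Collection[str]
) -> ContingencyTable:
    """Cross-tabulate membership of two gene lists within a universe.

    Genes outside the universe are logged and dropped; an empty universe is
    an error.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("gene universe is empty")
    sa, sb = set(set_a), set(set_b)
    stray = (sa | sb) - uni
    if stray:
        logger.warning(
            "%d gene(s) outside the universe dropped from overlap (e.g. %s)",
            len(stray),
            sorted(stray)[:3],
        )
        sa &= uni
        sb &= uni
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_exact_test(
    table: ContingencyTable, *, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``. The odds ratio is the sample cross-product
    ``a*d/(b*c)``; when ``b*c = 0`` it is ``inf`` (or ``nan`` when ``a*d``
    is also 0, i.e. undefined). The two-sided p sums hypergeometric
    probabilities of all tables with the observed margins that are no more
    likely than the observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    _, p = _scipy_fisher([[a, b], [c, d]], alternative=alternative)
    return odds, float(p)
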