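"""Exact 2x2 enrichment test of transferred genes among DE genes.

Cross-classifies the gene universe by horizontal-transfer call and
differential-expression flag and tests for association with Fisher's exact
test (two-sided, point-probability criterion), reporting the sample odds
ratio (a*d)/(b*c).  A chi-squared variant is offered for large tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .io import ValidationError


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a = HGT&DE, b = HGT&~DE, c = ~HGT&DE, d = ~HGT&~DE."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_table(
    hgt_flags: Mapping[str, bool],
    de_flags: Mapping[str, bool],
    universe: Iterable[str] | None = None,
) -> ContingencyTable:
    """Cross-classify genes by HGT call and DE flag.

    ``hgt_flags`` and ``de_flags`` must cover the same gene universe (or the
    explicit ``universe`` when given, e.g. to restrict to expressed genes);
    any gene missing from either input is an error.
    """
    genes = set(universe) if universe is not None else set(hgt_flags) | set(de_flags)
    missing_h = genes - set(hgt_flags)
    missing_d = genes - set(de_flags)
    if missing_h or missing_d:
        example = sorted(missing_h | missing_d)[:3]
        raise ValidationError(
            f"{len(missing_h)} genes missing HGT calls, {len(missing_d)} missing "
            f"DE flags (e.g. {example})"
        )
    a = b = c = d = 0
    for g in genes:
        if hgt_flags[g]:
            if de_flags[g]:
                a += 1
            else:
                b += 1
        elif de_flags[g]:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_exact(table: ContingencyTable, method: str = "fisher") -> tuple[float, float]:
    """Odds ratio and two-sided p-value for a 2x2 table.

    The odds ratio is (a*d)/(b*c): +inf when b*c = 0 with a*d > 0, and NaN
    in the degenerate 0/0 case.  With ``method="fisher"`` the p-value sums
    hypergeometric point probabilities no larger than the observed one at
    fixed margins; ``method="chi2"`` gives the chi-squared approximation.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if method == "fisher":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    elif method == "chi2":
        _, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return odds, float(p)
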