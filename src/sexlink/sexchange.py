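"""Longitudinal sex-change summary statistics.

Individuals sexed at two consecutive maturation seasons are counted per
phenotype class (FF, MM, FM, MF) and summarized as:

* overall reversal rate (FM + MF over all individuals);
* conditional change rates given the primary sex (FM over female-first
  individuals, MF over male-first);
* whole-population class fractions.

Rates are exact rationals; rendered percentages round half-up to 2 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .genotype_io import SexRecord

logger = logging.getLogger(__name__)

__all__ = ["SexChangeSummary", "summarize_sex_change", "percent"]

PHENOTYPE_CODES = ("FM", "FF", "MM", "MF")


def percent(frac: Fraction, digits: int = 2) -> str:
    """Render an exact fraction as a percentage, round-half-up."""
    value = Decimal(frac.numerator) * 100 / Decimal(frac.denominator)
    quantum = Decimal(1).scaleb(-digits)
    return f"{value.quantize(quantum, rounding=ROUND_HALF_UP)}%"


@dataclass(frozen=True)
class SexChangeSummary:
    """Counts and exact rates for a two-season sex-observation cohort."""

    counts: dict[str, int]  # phenotype code -> count
    n_total: int
    rate_overall_reversal: Fraction
    rate_f_to_m_given_f: Fraction
    rate_m_to_f_given_m: Fraction
    population_fractions: dict[str, Fraction]
    conditional_rates: dict[str, Fraction]  # per class, over its primary sex

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like the published two-season summary."""
        label = {
            "FM": "Female to male",
            "FF": "Female to female",
            "MM": "Male to male",
            "MF": "Male to female",
        }
        rows = []
        for code in PHENOTYPE_CODES:
            rows.append(
                {
                    "transition": label[code],
                    "count": self.counts[code],
                    "rate_given_primary_sex": percent(self.conditional_rates[code]),
                    "rate_in_population": percent(self.population_fractions[code]),
                }
            )
        rows.append(
            {
                "transition": "Total",
                "count": self.n_total,
                "rate_given_primary_sex": percent(self.rate_overall_reversal),
                "rate_in_population": percent(Fraction(1)),
            }
        )
        return pd.DataFrame(rows)


def summarize_sex_change(records: Sequence[SexRecord]) -> SexChangeSummary:
    """Summarize a cohort of two-season sex records.

    Records with unknown second-season sex are excluded (logged count);
    a cohort with no usable records is an error. Order-invariant.
    """
    usable = [r for r in records if r.phenotype is not None]
    dropped = len(records) - len(usable)
    if dropped:
        logger.info("summarize_sex_change: excluded %d record(s) with unknown sex_t2", dropped)
    if not usable:
        raise ValueError("no records with both seasons known")
    counts = {code: 0 for code in PHENOTYPE_CODES}
    for r in usable:
        counts[r.phenotype] += 1
    n = len(usable)
    n_female_first = counts["FF"] + counts["FM"]
    n_male_first = counts["MM"] + counts["MF"]
    conditional = {}
    for code in PHENOTYPE_CODES:
        denom = n_female_first if code[0] == "F" else n_male_first
        conditional[code] = Fraction(counts[code], denom) if denom else Fraction(0)
    return SexChangeSummary(
        counts=counts,
        n_total=n,
        rate_overall_reversal=Fraction(counts["FM"] + counts["MF"], n),
        rate_f_to_m_given_f=conditional["FM"],
        rate_m_to_f_given_m=conditional["MF"],
        population_fractions={c: Fraction(counts[c], n) for c in PHENOTYPE_CODES},
        conditional_rates=conditional,
    )
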