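"""Published summary values from the 2015 Hamadan post-reproductive survey
(812 women aged 45+) that this package re-analyses.

The raw woman-level data were never deposited, so these printed aggregates
are the only quantities that can be recomputed exactly; everything model-
based is validated by simulation instead.  Counts are nested: 770 women had
at least one child, 671 at least two, and so on.
"""

from __future__ import annotations

#: Cohort size and number of women reaching each birth order.
N_WOMEN = 812
WOMEN_WITH_AT_LEAST = {1: 770, 2: 671, 3: 254, 4: 73}

#: First-delivery denominator and the count of women whose first pregnancy
#: came at age 18 or younger.
FIRST_DELIVERY_N = 770
FIRST_PREGNANCY_LE18_N = 163

#: Published sex ratio at first birth (males per 100 females).
SEX_RATIO_FIRST_BIRTH = 104

#: Published median birth intervals (years) for the 2nd, 3rd and 4th child.
MEDIAN_INTERVALS_YEARS = {2: 4.53, 3: 4.65, 4: 5.27}

#: Published parity-progression-ratio grid: rows are the truncation window C
#: in years (5..10), columns the transitions marriage->1st .. 3rd->4th.
PPR_GRID_BY_C_YEARS = {
    5: (0.918, 0.820, 0.557, 0.307),
    6: (0.925, 0.832, 0.568, 0.315),
    7: (0.944, 0.849, 0.574, 0.347),
    8: (0.967, 0.851, 0.580, 0.351),
    9: (0.981, 0.854, 0.596, 0.361),
    10: (0.983, 0.861, 0.592, 0.354),
}


def ppr_grid_column(transition: int) -> tuple[float, ...]:
    """The six published PPR estimates for one parity transition (0-based)."""
    return tuple(row[transition] for row in PPR_GRID_BY_C_YEARS.values())
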