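"""Published reference tables from the 14-country SWI burden study.

These are the study's *printed outputs* (not its unpublished input
extraction table): the base-case per-country burden (``BASE_CASE_BURDEN``)
and the PSA median annual burden (``PSA_MEDIAN_BURDEN``), both in 2017 US$.
They serve as worked-example data for the aggregation utilities — the
published cross-country summary statistics (total burden US$557.7M, median
cost per SWI US$13 995, median cost per CABG US$900, the 60% US share) are
all recomputable from ``BASE_CASE_BURDEN`` — and as regression anchors for
the table arithmetic.  Monetary values are as printed, rounded to the
nearest dollar.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["base_case_burden", "psa_median_burden"]

# country, procedures, SWI events, burden (US$), mean cost/SWI, mean cost/CABG
_BASE_CASE = [
    ("FRA", 19280, 717, 8496817, 11845, 441),
    ("DEU", 50472, 2836, 36876758, 13003, 731),
    ("ITA", 20930, 1378, 18940618, 13741, 905),
    ("GBR", 16529, 539, 7200434, 13357, 436),
    ("NLD", 9685, 814, 18365837, 22551, 1896),
    ("ESP", 8294, 726, 8715780, 12008, 1051),
    ("AUS", 13063, 535, 11683094, 21831, 894),
    ("ISR", 4037, 150, 2323092, 15508, 575),
    ("JPN", 21313, 1099, 59566162, 54180, 2795),
    ("BRA", 20198, 1223, 9996520, 8172, 495),
    ("CAN", 20868, 1239, 33091101, 26707, 1586),
    ("TWN", 1510, 103, 1467327, 14249, 971),
    ("THA", 6581, 518, 4972120, 9600, 756),
    ("USA", 159063, 9139, 336028904, 36768, 2113),
]

# country, median annual cost burden (US$ millions), median ICU days,
# median GW days, median readmissions (PSA medians)
_PSA_MEDIAN = [
    ("FRA", 12.97, 1900, 9500, 430),
    ("DEU", 43.57, 6300, 33500, 1450),
    ("ITA", 20.37, 3100, 17000, 600),
    ("GBR", 12.34, 1800, 9800, 290),
    ("NLD", 12.97, 2200, 12300, 230),
    ("ESP", 8.69, 1200, 7000, 280),
    ("AUS", 13.13, 1900, 10800, 260),
    ("ISR", 3.24, 600, 3400, 70),
    ("JPN", 47.25, 8500, 50000, 320),
    ("BRA", 16.12, 2900, 16300, 520),
    ("CAN", 29.49, 3200, 17300, 490),
    ("TWN", 1.85, 400, 2300, 40),
    ("THA", 7.58, 1400, 7900, 160),
    ("USA", 299.40, 22600, 125100, 4280),
]


def base_case_burden() -> pd.DataFrame:
    """Published base-case per-country burden table."""
    return pd.DataFrame(
        _BASE_CASE,
        columns=[
            "country_code",
            "procedures",
            "swi_events",
            "swi_burden_usd2017",
            "cost_per_swi_usd2017",
            "cost_per_cabg_usd2017",
        ],
    )


def psa_median_burden() -> pd.DataFrame:
    """Published PSA median annual burden per country."""
    return pd.DataFrame(
        _PSA_MEDIAN,
        columns=[
            "country_code",
            "cost_burden_musd2017",
            "icu_days",
            "gw_days",
            "readmissions",
        ],
    )
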