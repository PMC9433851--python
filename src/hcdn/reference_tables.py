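"""Published hit tallies from the large-cohort social-support analysis.

These are the mode-by-category hit counts reported for the ~40 000
participant UK Biobank analysis that this package's pipeline models.  They
are inputs for worked arithmetic examples and cross-checks of the tally
operations — at desk scale the underlying restricted data cannot be re-run,
but the printed table arithmetic (margins, shares) can be reproduced
exactly.

The published numbers are internally inconsistent in places and are encoded
as printed, never reconciled:

* the hippocampus table's body cells sum to 33 (PrS column 5) while its
  printed Total row reads 32 (PrS 4); the running text quotes "32" and
  "five PrS hits";
* the text quotes 17 prefrontal and 11 parietal hits where the
  default-network table margins give 14 and 14;
* the text quotes "24 HC subregion hits (70.6%)" for modes 1-3 where the
  cells sum to 25.

Both readings are therefore exposed: the cell grids (from which the tally
operations compute margins) and the printed margin rows.
"""

from __future__ import annotations

import pandas as pd

from .atlas import DN_CATEGORIES, HC_CATEGORIES
from .report import HitTable

# Hippocampus-side hits per mode and subfield category (modes 1-7; no hits
# were reported beyond mode 7).
_HC_ROWS = {
    1: [0, 3, 3, 4, 2, 0, 1, 2, 0, 0, 0, 0],
    2: [0, 0, 0, 0, 0, 2, 2, 1, 0, 0, 0, 2],
    3: [0, 2, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],
    4: [0, 0, 0, 0, 1, 0, 1, 0, 0, 1, 0, 0],
    5: [0, 0, 0, 0, 0, 0, 1, 1, 0, 1, 1, 0],
    6: [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    7: [0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0],
}

# Default-network-side hits per mode and lobe category (modes 1-6).
_DN_ROWS = {
    1: [8, 7, 10, 1],
    2: [0, 0, 0, 0],
    3: [0, 5, 2, 0],
    4: [1, 2, 0, 1],
    5: [0, 0, 0, 1],
    6: [8, 0, 2, 2],
}

#: the Total rows exactly as printed beneath each table (see module note:
#: the HC row does not equal the column sums of the cells above it)
_HC_PRINTED_TOTAL = [0, 5, 3, 4, 3, 3, 4, 5, 0, 2, 1, 2]
_DN_PRINTED_TOTAL = [17, 14, 14, 5]

#: subfield categories called out as carrying most of the reported effect
TOP_HC_CATEGORIES = ["PrS", "Sub", "CA2/3", "DG", "CA4"]


def published_hc_hit_table() -> HitTable:
    """Hippocampal hit counts, as printed."""
    counts = pd.DataFrame.from_dict(_HC_ROWS, orient="index",
                                    columns=HC_CATEGORIES)
    counts.index.name = "mode"
    return HitTable(counts=counts)


def published_dn_hit_table() -> HitTable:
    """Default-network hit counts, as printed."""
    counts = pd.DataFrame.from_dict(_DN_ROWS, orient="index",
                                    columns=DN_CATEGORIES)
    counts.index.name = "mode"
    return HitTable(counts=counts)


def published_hc_margin_row() -> pd.Series:
    """The HC table's printed Total row (differs from the cell sums)."""
    return pd.Series(_HC_PRINTED_TOTAL, index=HC_CATEGORIES)


def published_dn_margin_row() -> pd.Series:
    """The DN table's printed Total row (consistent with the cell sums)."""
    return pd.Series(_DN_PRINTED_TOTAL, index=DN_CATEGORIES)
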