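"""Default anatomy labels for the two subregion sets.

The hippocampus (HC) side follows the FreeSurfer hippocampal sub-segmentation
scheme: 19 measures per hemisphere (38 total), with most subfields split into
a head and a body portion.  CA2 cannot be demarcated separately on MRI, so it
is merged with CA3 into a combined "CA2/3" category, as is standard for this
atlas.

The default-network (DN) side carries 91 parcels in the style of the
Schaefer-Yeo 400-parcel atlas restricted to the default network.  The
parcel-to-lobe mapping used here (temporal 26, prefrontal 33, parietal 20,
posterior cingulate 12) is a reconstruction chosen so that every reporting
category is populated; it is not a published lookup table.

Each atlas is a :class:`pandas.DataFrame` indexed by subregion name with
columns ``structure`` ("HC" or "DN"), ``hemisphere`` ("L"/"R"), ``category``
(the reporting group) and ``segment`` ("head"/"body"/"whole", HC only).
"""

from __future__ import annotations

import pandas as pd

# (FreeSurfer-style base name, reporting category, segment)
_HC_SCHEME = [
    ("Hippocampal_tail", "Tail", "whole"),
    ("subiculum-head", "Sub", "head"),
    ("subiculum-body", "Sub", "body"),
    ("CA1-head", "CA1", "head"),
    ("CA1-body", "CA1", "body"),
    ("hippocampal-fissure", "Fissure", "whole"),
    ("presubiculum-head", "PrS", "head"),
    ("presubiculum-body", "PrS", "body"),
    ("parasubiculum", "Para", "whole"),
    ("molecular_layer_HP-head", "ML", "head"),
    ("molecular_layer_HP-body", "ML", "body"),
    ("GC-ML-DG-head", "DG", "head"),
    ("GC-ML-DG-body", "DG", "body"),
    ("CA3-head", "CA2/3", "head"),
    ("CA3-body", "CA2/3", "body"),
    ("CA4-head", "CA4", "head"),
    ("CA4-body", "CA4", "body"),
    ("fimbria", "Fimbria", "whole"),
    ("HATA", "HATA", "whole"),
]

HC_CATEGORIES = [
    "CA1", "CA2/3", "CA4", "DG", "HATA", "Para",
    "PrS", "Sub", "Fissure", "Fimbria", "ML", "Tail",
]

# per-hemisphere parcel counts; L gets the extra prefrontal parcel
_DN_SCHEME = [
    ("Temp", "Temporal", 13, 13),
    ("PFC", "Prefrontal", 17, 16),
    ("Par", "Parietal", 10, 10),
    ("PCC", "Posterior cingulate", 6, 6),
]

DN_CATEGORIES = ["Temporal", "Prefrontal", "Parietal", "Posterior cingulate"]


def hippocampus_atlas() -> pd.DataFrame:
    """38-subregion HC atlas (19 FreeSurfer measures per hemisphere)."""
    rows = []
    for hemi in ("L", "R"):
        for base, category, segment in _HC_SCHEME:
            rows.append(
                {
                    "subregion": f"{hemi}_{base}",
                    "structure": "HC",
                    "hemisphere": hemi,
                    "category": category,
                    "segment": segment,
                }
            )
    return pd.DataFrame(rows).set_index("subregion")


def default_network_atlas() -> pd.DataFrame:
    """91-parcel DN atlas grouped into four lobe categories."""
    rows = []
    for abbrev, category, n_left, n_right in _DN_SCHEME:
        for hemi, n in (("L", n_left), ("R", n_right)):
            for i in range(1, n + 1):
                rows.append(
                    {
                        "subregion": f"{hemi}H_Default_{abbrev}_{i}",
                        "structure": "DN",
                        "hemisphere": hemi,
                        "category": category,
                        "segment": "whole",
                    }
                )
    return pd.DataFrame(rows).set_index("subregion")
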