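"""Hit tallies by anatomy and derived summary fractions.

Bootstrap hits (subregions whose canonical-weight group difference excludes
zero) are tabulated per mode and per anatomical reporting category —
12 hippocampal subfield categories and 4 default-network lobe categories —
with per-mode totals, per-category totals and a grand total.  Derived
fractions (a mode's share of all hits, a category's share, the
left-hemisphere share, the head vs body share within the hippocampus) are
computed from the raw counts; percentages are rounded to one decimal for
display only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import DN_CATEGORIES, HC_CATEGORIES
from .contrast import ContrastResult
from .errors import ValidationError


@dataclass
class HitTable:
    """Modes x anatomical-categories table of nonnegative hit counts."""

    counts: pd.DataFrame  # index: mode (1-based), columns: categories

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("hit counts must be nonnegative integers")

    # -- margins ---------------------------------------------------------
    def mode_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def category_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    # -- derived fractions ----------------------------------------------
    def mode_share(self, mode: int) -> float | None:
        """A mode's hits as a fraction of the grand total (None if empty)."""
        total = self.grand_total()
        if total == 0:
            return None
        return float(self.mode_totals().loc[mode]) / total

    def category_share(self, category: str) -> float | None:
        total = self.grand_total()
        if total == 0:
            return None
        return float(self.category_totals().loc[category]) / total

    def categories_share(self, categories: list[str]) -> float | None:
        """Combined share of several categories (e.g. top subfields)."""
        total = self.grand_total()
        if total == 0:
            return None
        return float(self.category_totals().loc[categories].sum()) / total

    def modes_total(self, modes: list[int]) -> int:
        return int(self.mode_totals().loc[modes].sum())

    # -- rendering -------------------------------------------------------
    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.mode_totals()
        out.loc["Total"] = out.sum(axis=0)
        return out

    def to_markdown(self) -> str:
        df = self.with_margins()
        header = "| Mode | " + " | ".join(str(c) for c in df.columns) + " |"
        sep = "|" + "---|" * (len(df.columns) + 1)
        lines = [header, sep]
        for idx, row in df.iterrows():
            lines.append("| " + " | ".join(
                [str(idx)] + [str(int(v)) for v in row]) + " |")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.with_margins().to_csv(path, sep="\t", index_label="mode")


def _check_metadata(labels: list[str], meta: pd.DataFrame) -> None:
    unmapped = [l for l in labels if l not in meta.index]
    if unmapped:
        raise ValidationError(f"subregions without anatomy metadata: {unmapped}")


def _tally_side(result: ContrastResult, meta: pd.DataFrame, side: str,
                categories: list[str]) -> HitTable:
    cols = [i for i, s in enumerate(result.sides) if s == side]
    labels = [result.labels[i] for i in cols]
    _check_metadata(labels, meta)
    cats = meta.loc[labels, "category"]
    bad = sorted(set(cats) - set(categories))
    if bad:
        raise ValidationError(f"unknown {side} categories: {bad}")
    counts = pd.DataFrame(0, index=pd.RangeIndex(1, result.k + 1, name="mode"),
                          columns=categories)
    for l in range(result.k):
        for i, label in zip(cols, labels):
            if result.hit_flags[l, i]:
                counts.loc[l + 1, cats.loc[label]] += 1
    return HitTable(counts=counts)


def tally_hits(result: ContrastResult, meta: pd.DataFrame
               ) -> tuple[HitTable, HitTable]:
    """Count hits per mode and category; returns (HC table, DN table).

    ``meta`` must map every subregion named in the result to exactly one
    category and hemisphere (the concatenation of the two atlas frames).
    """
    hc = _tally_side(result, meta, "HC", HC_CATEGORIES)
    dn = _tally_side(result, meta, "DN", DN_CATEGORIES)
    return hc, dn


def laterality_summary(result: ContrastResult, meta: pd.DataFrame,
                       modes: list[int] | None = None,
                       side: str | None = None) -> pd.Series:
    """Hits per hemisphere (and left share) over a mode subset.

    ``modes`` is 1-based; ``side`` restricts to "HC" or "DN" entries.
    """
    _check_metadata(result.labels, meta)
    if modes is None:
        modes = list(range(1, result.k + 1))
    counts = {"L": 0, "R": 0}
    for l in modes:
        for i, label in enumerate(result.labels):
            if side is not None and result.sides[i] != side:
                continue
            if result.hit_flags[l - 1, i]:
                counts[meta.loc[label, "hemisphere"]] += 1
    total = counts["L"] + counts["R"]
    left_share = counts["L"] / total if total else None
    return pd.Series({"left": counts["L"], "right": counts["R"],
                      "left_share": left_share})


def segment_summary(result: ContrastResult, meta: pd.DataFrame,
                    modes: list[int] | None = None) -> pd.Series:
    """Head vs body hit counts for HC subregions that have that split."""
    _check_metadata(result.labels, meta)
    if modes is None:
        modes = list(range(1, result.k + 1))
    counts = {"head": 0, "body": 0, "whole": 0}
    for l in modes:
        for i, label in enumerate(result.labels):
            if result.sides[i] != "HC":
                continue
            if result.hit_flags[l - 1, i]:
                counts[meta.loc[label, "segment"]] += 1
    split_total = counts["head"] + counts["body"]
    head_share = counts["head"] / split_total if split_total else None
    return pd.Series({"head": counts["head"], "body": counts["body"],
                      "whole": counts["whole"], "head_share": head_share})


def format_pct(fraction: float | None) -> str:
    """One-decimal display rounding; raw fractions stay in machine output."""
    return "undefined" if fraction is None else f"{100 * fraction:.1f}%"
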