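"""Mode matching between two CCA solutions.

Mode order and sign are not identifiable across CCA refits: a resampled fit
may return the "same" modes shuffled and with flipped signs.  Before two
solutions can be subtracted they are matched mode-by-mode: a k x k similarity
matrix of absolute Pearson correlations between concatenated canonical
vectors [v_l; u_l] is built, the assignment maximizing total similarity is
solved exactly (Hungarian algorithm), and a sign of -1 is recorded wherever
the matched pair's signed correlation is negative.

Matching on the concatenation of both views means a mode is identified by
its full anatomical signature, not by one side alone.  Matches with absolute
correlation below ``flag_threshold`` (default 0.5) are flagged so downstream
consumers can count or exclude degenerate replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cca import CcaSolution
from .errors import ValidationError

DEFAULT_FLAG_THRESHOLD = 0.5


@dataclass
class ModeMatch:
    """Permutation + sign vector aligning another solution to a reference.

    ``permutation[l]`` is the index of the other-solution mode matched to
    reference mode ``l``; ``signs[l]`` is +-1; ``match_scores[l]`` is the
    absolute Pearson correlation achieved by the matched pair.
    """

    permutation: np.ndarray
    signs: np.ndarray
    match_scores: np.ndarray
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation)
        if sorted(perm.tolist()) != list(range(len(perm))):
            raise ValidationError("permutation is not a bijection on 0..k-1")
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValidationError("signs must be +-1")

    @property
    def k(self) -> int:
        return len(self.permutation)

    @property
    def flagged(self) -> np.ndarray:
        """True where the match quality is below the flag threshold."""
        return self.match_scores < self.flag_threshold

    def to_json(self) -> str:
        return json.dumps({
            "permutation": self.permutation.tolist(),
            "signs": self.signs.tolist(),
            "match_scores": self.match_scores.tolist(),
            "flag_threshold": self.flag_threshold,
        })

    @classmethod
    def from_json(cls, text: str) -> "ModeMatch":
        d = json.loads(text)
        return cls(
            permutation=np.asarray(d["permutation"], dtype=int),
            signs=np.asarray(d["signs"], dtype=int),
            match_scores=np.asarray(d["match_scores"], dtype=float),
            flag_threshold=float(d["flag_threshold"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of a and columns of b."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / np.linalg.norm(a, axis=0)
    b = b / np.linalg.norm(b, axis=0)
    return a.T @ b


def match_modes(reference: CcaSolution, other: CcaSolution, *,
                flag_threshold: float = DEFAULT_FLAG_THRESHOLD) -> ModeMatch:
    """Optimal mode-by-mode assignment of ``other`` onto ``reference``."""
    if reference.k != other.k:
        raise ValidationError(
            f"solutions have different mode counts: {reference.k} vs {other.k}")
    if (reference.dn_labels != other.dn_labels
            or reference.hc_labels != other.hc_labels):
        raise ValidationError("solutions were fitted on different column sets")
    signed = _corr_matrix(reference.stacked_weights(), other.stacked_weights())
    rows, cols = linear_sum_assignment(-np.abs(signed))
    perm = np.empty(reference.k, dtype=int)
    perm[rows] = cols
    pair_corr = signed[np.arange(reference.k), perm]
    signs = np.where(pair_corr < 0, -1, 1)
    return ModeMatch(
        permutation=perm, signs=signs,
        match_scores=np.abs(pair_corr),
        flag_threshold=flag_threshold,
    )


def apply_match(other: CcaSolution, match: ModeMatch) -> CcaSolution:
    """Reorder and sign-flip ``other`` so its mode l aligns with reference mode l."""
    if match.k != other.k:
        raise ValidationError("match and solution have different mode counts")
    perm, signs = match.permutation, match.signs
    return CcaSolution(
        v_weights=other.v_weights[:, perm] * signs,
        u_weights=other.u_weights[:, perm] * signs,
        dn_variates=other.dn_variates[:, perm] * signs,
        hc_variates=other.hc_variates[:, perm] * signs,
        canonical_correlations=other.canonical_correlations[perm],
        dn_labels=other.dn_labels,
        hc_labels=other.hc_labels,
    )
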