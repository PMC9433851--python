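"""Bootstrap group-difference test on matched CCA modes.

For a binary phenotype (low vs adequate social support), the question is
whether the canonical vectors that define each HC-DN co-variation mode are
systematically different between the two groups.  The procedure:

1. fit a reference CCA on the full cohort;
2. in each of B bootstrap iterations (default 100), resample each group with
   replacement to its own original size and fit one CCA per group;
3. align each group solution to the reference mode-by-mode in order and sign
   (absolute-Pearson matching on the concatenated canonical vectors);
4. record the elementwise difference of the aligned canonical vectors per
   mode (low-support group minus adequate-support group);
5. aggregate the B difference draws per mode and subregion into a percentile
   interval (default 10th/90th, an 80%-coverage two-sided interval); a
   subregion is a *hit* for a mode when that interval excludes zero.

Aligning both group solutions to one full-cohort reference fixes their
mutual alignment and a stable orientation across replicates at the same
time.  Resampling is stratified within group by default so every replicate
yields a fittable model per group; pooled resampling is available for
sensitivity checks.  No multiple-testing correction is applied across the
k x (p+q) tests; the result records how many tests were performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import DEFAULT_FLAG_THRESHOLD, apply_match, match_modes
from .cca import CcaSolution, fit_cca_arrays
from .deconfound import VolumeMatrix
from .errors import ValidationError


@dataclass
class ContrastResult:
    """Bootstrap difference distributions with interval bounds and hit flags."""

    differences: np.ndarray           # B x k x (p+q), group1 - group0
    ci_lower: np.ndarray              # k x (p+q)
    ci_upper: np.ndarray              # k x (p+q)
    hit_flags: np.ndarray             # k x (p+q) bool
    replicate_match_scores: np.ndarray  # B x k (min over the two groups)
    labels: list[str]                 # DN labels then HC labels
    sides: np.ndarray                 # "DN"/"HC" per entry of labels
    lower_pct: float
    upper_pct: float
    seed: int
    reference: CcaSolution | None = None

    @property
    def B(self) -> int:
        return self.differences.shape[0]

    @property
    def k(self) -> int:
        return self.differences.shape[1]

    @property
    def n_tests(self) -> int:
        """Number of uncorrected interval tests performed."""
        return self.k * self.differences.shape[2]

    def flagged_replicate_fraction(
            self, threshold: float = DEFAULT_FLAG_THRESHOLD) -> float:
        """Fraction of replicate-mode alignments below the quality threshold."""
        return float((self.replicate_match_scores < threshold).mean())

    def hit_table_frame(self, meta: pd.DataFrame) -> pd.DataFrame:
        """Long-format hit table: mode, subregion, anatomy, bounds, hit."""
        rows = []
        for l in range(self.k):
            for j, name in enumerate(self.labels):
                m = meta.loc[name]
                rows.append({
                    "mode": l + 1,
                    "subregion": name,
                    "structure": m["structure"],
                    "hemisphere": m["hemisphere"],
                    "category": m["category"],
                    "segment": m["segment"],
                    "ci_lower": self.ci_lower[l, j],
                    "ci_upper": self.ci_upper[l, j],
                    "hit": bool(self.hit_flags[l, j]),
                })
        return pd.DataFrame(rows)

    # -- serialization: npz array bundle + TSV hit table ------------------
    def to_dir(self, path: str | Path, meta: pd.DataFrame | None = None) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path / "contrast_arrays.npz",
            differences=self.differences,
            ci_lower=self.ci_lower, ci_upper=self.ci_upper,
            hit_flags=self.hit_flags,
            replicate_match_scores=self.replicate_match_scores,
            sides=self.sides.astype("U2"),
        )
        (path / "contrast_meta.json").write_text(json.dumps({
            "labels": self.labels,
            "lower_pct": self.lower_pct, "upper_pct": self.upper_pct,
            "B": self.B, "k": self.k, "seed": self.seed,
            "n_tests": self.n_tests,
        }, indent=2))
        if meta is not None:
            self.hit_table_frame(meta).to_csv(
                path / "hits.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "ContrastResult":
        path = Path(path)
        arrays = np.load(path / "contrast_arrays.npz")
        info = json.loads((path / "contrast_meta.json").read_text())
        return cls(
            differences=arrays["differences"],
            ci_lower=arrays["ci_lower"], ci_upper=arrays["ci_upper"],
            hit_flags=arrays["hit_flags"].astype(bool),
            replicate_match_scores=arrays["replicate_match_scores"],
            labels=info["labels"], sides=arrays["sides"],
            lower_pct=info["lower_pct"], upper_pct=info["upper_pct"],
            seed=info["seed"],
        )


def _interval_and_hits(differences: np.ndarray, lower_pct: float,
                       upper_pct: float
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = np.percentile(differences, lower_pct, axis=0)
    hi = np.percentile(differences, upper_pct, axis=0)
    hits = (lo > 0) | (hi < 0)
    return lo, hi, hits


def determine_hits(result: ContrastResult, lower_pct: float,
                   upper_pct: float) -> np.ndarray:
    """Recompute hit flags at other percentile bounds without refitting."""
    if not (0 < lower_pct < upper_pct < 100):
        raise ValidationError(
            f"percentiles must satisfy 0 < lower < upper < 100, got "
            f"{lower_pct}/{upper_pct}")
    _, _, hits = _interval_and_hits(result.differences, lower_pct, upper_pct)
    return hits


def _solution_from_arrays(x: np.ndarray, y: np.ndarray, k: int, ridge: float,
                          dn_labels: list[str], hc_labels: list[str]
                          ) -> CcaSolution:
    v, u, lx, ly, rho = fit_cca_arrays(x, y, k, ridge=ridge)
    return CcaSolution(v, u, lx, ly, rho, dn_labels, hc_labels)


def bootstrap_group_difference(
        dn: VolumeMatrix, hc: VolumeMatrix, groups, *,
        B: int = 100, k: int = 25, seed: int = 0,
        lower_pct: float = 10.0, upper_pct: float = 90.0,
        ridge: float = 0.0, pooled_resampling: bool = False,
        flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
        keep_reference: bool = True,
        identity_resample: bool = False) -> ContrastResult:
    """Run the full bootstrap contrast; deterministic given ``seed``.

    ``groups`` is a binary vector aligned with the participant rows
    (1 = low social support).  Differences are reported as group 1 minus
    group 0, so a positive difference means a larger canonical weight in the
    low-support group.
    """
    x = dn.values.to_numpy(dtype=float)
    y = hc.values.to_numpy(dtype=float)
    groups = np.asarray(groups).astype(int)
    if groups.shape[0] != x.shape[0]:
        raise ValidationError("group labels do not match participant count")
    if set(np.unique(groups)) != {0, 1}:
        raise ValidationError("groups must contain both labels 0 and 1")
    idx0 = np.flatnonzero(groups == 0)
    idx1 = np.flatnonzero(groups == 1)
    for name, idx in (("adequate-support", idx0), ("low-support", idx1)):
        if len(idx) < k + 1:
            raise ValidationError(
                f"{name} group has {len(idx)} participants; need > k={k}")

    dn_labels, hc_labels = dn.subregions, hc.subregions
    reference = _solution_from_arrays(x, y, k, ridge, dn_labels, hc_labels)

    rng = np.random.default_rng(seed)
    p_plus_q = x.shape[1] + y.shape[1]
    differences = np.empty((B, k, p_plus_q))
    match_scores = np.empty((B, k))
    for b in range(B):
        if identity_resample:
            take0, take1 = idx0, idx1  # diagnostic mode: no resampling
        elif pooled_resampling:
            take0 = rng.integers(0, x.shape[0], size=len(idx0))
            take1 = rng.integers(0, x.shape[0], size=len(idx1))
        else:
            take0 = idx0[rng.integers(0, len(idx0), size=len(idx0))]
            take1 = idx1[rng.integers(0, len(idx1), size=len(idx1))]
        aligned = []
        scores = []
        for take in (take0, take1):
            sol = _solution_from_arrays(x[take], y[take], k, ridge,
                                        dn_labels, hc_labels)
            match = match_modes(reference, sol, flag_threshold=flag_threshold)
            aligned.append(apply_match(sol, match).stacked_weights())
            scores.append(match.match_scores)
        differences[b] = (aligned[1] - aligned[0]).T
        match_scores[b] = np.minimum(scores[0], scores[1])

    lo, hi, hits = _interval_and_hits(differences, lower_pct, upper_pct)
    sides = np.array(["DN"] * len(dn_labels) + ["HC"] * len(hc_labels))
    return ContrastResult(
        differences=differences, ci_lower=lo, ci_upper=hi, hit_flags=hits,
        replicate_match_scores=match_scores,
        labels=dn_labels + hc_labels, sides=sides,
        lower_pct=lower_pct, upper_pct=upper_pct, seed=seed,
        reference=reference if keep_reference else None,
    )
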