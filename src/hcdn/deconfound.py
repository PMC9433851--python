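"""Volume containers and nuisance removal.

Per-subregion gray-matter volumes are cleaned in two steps before any
multivariate modelling: each column is residualized on a table of nuisance
covariates (body/head-size proxies, motion, scanner position, site, plus age,
age^2, sex, sex*age, sex*age^2) by ordinary least squares, and then z-scored
to zero mean and unit sample variance.  Deconfounding happens once, on the
full cohort, before any group split.

Conventions pinned here:

* z-scoring uses the sample standard deviation (``ddof=1``);
* interaction terms (age^2, sex*age, sex*age^2) are derived from *uncentered*
  age when absent from the confound table;
* missing values are rejected, not imputed (complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ValidationError

_META_COLS = ["structure", "hemisphere", "category", "segment"]

#: derived nuisance columns and how to compute them from age/sex
_DERIVED_CONFOUNDS = {
    "age2": lambda c: c["age"] ** 2,
    "sex_age": lambda c: c["sex"] * c["age"],
    "sex_age2": lambda c: c["sex"] * c["age"] ** 2,
}


@dataclass
class VolumeMatrix:
    """Participants x subregions volume table with per-column anatomy labels.

    ``values`` is indexed by participant_id; ``meta`` is indexed by subregion
    name and carries structure / hemisphere / category / segment labels for
    every column.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValidationError(
                "volume columns and anatomy metadata rows do not match"
            )
        missing = [c for c in _META_COLS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"anatomy metadata lacks columns: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("volume table contains missing/non-finite values")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def subregions(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="participant_id",
                           float_format="%.17g")
        if meta_path is None:
            meta_path = path.with_suffix(".meta.tsv")
        self.meta.to_csv(meta_path, sep="\t", index_label="subregion")

    @classmethod
    def from_tsv(cls, path: str | Path, meta_path: str | Path | None = None
                 ) -> "VolumeMatrix":
        path = Path(path)
        if meta_path is None:
            meta_path = path.with_suffix(".meta.tsv")
        values = pd.read_csv(path, sep="\t", index_col="participant_id",
                             float_precision="round_trip")
        meta = pd.read_csv(meta_path, sep="\t", index_col="subregion")
        return cls(values=values, meta=meta)


@dataclass
class ConfoundTable:
    """Numeric nuisance covariates, one row per participant.

    Sex is coded {0, 1}.  ``ensure_interactions`` adds age^2, sex*age and
    sex*age^2 (from uncentered age) when they are absent, so callers can
    provide only the measured columns.
    """

    values: pd.DataFrame
    interaction_policy: str = "uncentered"  # documented convention

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = self.values.columns[~np.isfinite(arr).all(axis=0)].tolist()
            raise ValidationError(f"confound table has missing values in: {bad}")

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def ensure_interactions(self) -> "ConfoundTable":
        if not {"age", "sex"} <= set(self.values.columns):
            return self
        out = self.values.copy()
        for name, fn in _DERIVED_CONFOUNDS.items():
            if name not in out.columns:
                out[name] = fn(out)
        return replace(self, values=out)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="participant_id",
                           float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfoundTable":
        return cls(values=pd.read_csv(path, sep="\t",
                                      index_col="participant_id",
                                      float_precision="round_trip"))


def _design_matrix(confounds: ConfoundTable) -> tuple[np.ndarray, list[str]]:
    cols = confounds.values.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(cols)), cols])
    names = ["intercept"] + confounds.columns
    return design, names


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    # pivoted QR: columns pivoted beyond the numerical rank are the culprits
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        collinear = [names[i] for i in piv[rank:]]
        raise ValidationError(
            f"confound design is rank deficient; collinear columns: {collinear}"
        )


def residualize(volumes: VolumeMatrix, confounds: ConfoundTable) -> VolumeMatrix:
    """OLS-residualize every volume column on the full confound design.

    The design includes an intercept plus every confound column (after
    ``ensure_interactions``).  Anatomy metadata is preserved.  Participant id
    sets must be identical; the confound rows are aligned to the volume rows.
    """
    if set(volumes.values.index) != set(confounds.values.index):
        raise ValidationError("participant ids of volumes and confounds differ")
    confounds = ConfoundTable(
        confounds.ensure_interactions().values.loc[volumes.values.index]
    )
    design, names = _design_matrix(confounds)
    _check_full_rank(design, names)
    y = volumes.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return VolumeMatrix(
        values=pd.DataFrame(resid, index=volumes.values.index,
                            columns=volumes.values.columns),
        meta=volumes.meta,
    )


def zscore_columns(volumes: VolumeMatrix) -> VolumeMatrix:
    """Standardize each column to mean 0, sample (ddof=1) standard deviation 1."""
    y = volumes.values.to_numpy(dtype=float)
    sd = y.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [volumes.subregions[i] for i in constant]
        raise ValidationError(f"constant volume columns cannot be z-scored: {names}")
    z = (y - y.mean(axis=0)) / sd
    return VolumeMatrix(
        values=pd.DataFrame(z, index=volumes.values.index,
                            columns=volumes.values.columns),
        meta=volumes.meta,
    )


def deconfound(volumes: VolumeMatrix, confounds: ConfoundTable) -> VolumeMatrix:
    """Residualize then z-score: the standard cleaning applied before CCA."""
    return zscore_columns(residualize(volumes, confounds))
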