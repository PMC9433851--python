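"""Two-view canonical correlation decomposition.

Given a deconfounded, z-scored DN volume matrix X (n x p) and HC volume
matrix Y (n x q), canonical correlation analysis finds weight vectors v_l,
u_l maximizing corr(X v_l, Y u_l), with successive pairs uncorrelated with
all previous ones within each view.  Each (v_l, u_l) pair is a *mode* of
structural co-variation; the per-participant projections X v_l and Y u_l are
the mode expressions (canonical variates).

Implementation: SVD of the whitened cross-covariance.  With S_xx, S_yy the
within-view sample covariances (Cholesky-whitened, optional ridge) and S_xy
the cross-covariance, the singular values of
``L_x^{-1} S_xy L_y^{-T}`` are the canonical correlations and the rotated
singular vectors give the weights.  This is numerically more stable than the
generalized-eigenvalue formulation.

Conventions:

* modes ordered by canonical correlation, descending (ties keep SVD order);
* weights scaled so every variate has unit sample (ddof=1) variance;
* deterministic sign: per mode, the HC-side weight of largest magnitude is
  made positive, so repeated fits are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .deconfound import VolumeMatrix
from .errors import NumericalError, ValidationError

DEFAULT_K = 25  # number of modes examined downstream


@dataclass
class CcaSolution:
    """Fitted canonical correlation decomposition for k modes."""

    v_weights: np.ndarray          # p x k, DN side (columns v_l)
    u_weights: np.ndarray          # q x k, HC side (columns u_l)
    dn_variates: np.ndarray        # n x k, X V
    hc_variates: np.ndarray        # n x k, Y U
    canonical_correlations: np.ndarray  # length k, non-increasing, in [0, 1]
    dn_labels: list[str]
    hc_labels: list[str]

    @property
    def k(self) -> int:
        return self.v_weights.shape[1]

    @property
    def n(self) -> int:
        return self.dn_variates.shape[0]

    def stacked_weights(self) -> np.ndarray:
        """(p+q) x k matrix of concatenated [v_l; u_l] canonical vectors."""
        return np.vstack([self.v_weights, self.u_weights])

    # -- serialization: JSON + TSV bundle with exact round-trip ----------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        modes = [f"mode_{i + 1}" for i in range(self.k)]
        fmt = "%.17g"  # enough digits for exact float round-trip
        pd.DataFrame(self.v_weights, index=self.dn_labels, columns=modes).to_csv(
            path / "v_weights.tsv", sep="\t", index_label="subregion",
            float_format=fmt)
        pd.DataFrame(self.u_weights, index=self.hc_labels, columns=modes).to_csv(
            path / "u_weights.tsv", sep="\t", index_label="subregion",
            float_format=fmt)
        pd.DataFrame(self.dn_variates, columns=modes).to_csv(
            path / "dn_variates.tsv", sep="\t", index_label="row",
            float_format=fmt)
        pd.DataFrame(self.hc_variates, columns=modes).to_csv(
            path / "hc_variates.tsv", sep="\t", index_label="row",
            float_format=fmt)
        meta = {
            "k": self.k,
            "n": self.n,
            "canonical_correlations": [float(r) for r in
                                       self.canonical_correlations],
        }
        (path / "solution.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "CcaSolution":
        path = Path(path)
        meta = json.loads((path / "solution.json").read_text())

        def read(name, col):
            # round_trip parsing keeps the %.17g serialization lossless
            return pd.read_csv(path / name, sep="\t", index_col=col,
                               float_precision="round_trip")

        v = read("v_weights.tsv", "subregion")
        u = read("u_weights.tsv", "subregion")
        lx = read("dn_variates.tsv", "row")
        ly = read("hc_variates.tsv", "row")
        return cls(
            v_weights=v.to_numpy(), u_weights=u.to_numpy(),
            dn_variates=lx.to_numpy(), hc_variates=ly.to_numpy(),
            canonical_correlations=np.asarray(meta["canonical_correlations"]),
            dn_labels=list(v.index), hc_labels=list(u.index),
        )


def _chol_whitener(cov: np.ndarray, side: str) -> np.ndarray:
    msg = (f"within-view covariance of the {side} side is numerically "
           "singular; reduce k, increase n, or pass ridge > 0")
    try:
        chol = scipy.linalg.cholesky(cov, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(msg) from exc
    diag = np.diag(chol)
    # relative pivot below 1e-6 ~ condition number beyond 1e12: treat as
    # singular rather than silently amplifying noise through the whitener
    if diag.min() < 1e-6 * diag.max():
        raise NumericalError(msg)
    return chol


def fit_cca_arrays(x: np.ndarray, y: np.ndarray, k: int, *,
                   ridge: float = 0.0, center: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                              np.ndarray, np.ndarray]:
    """Core fit on plain arrays; returns (V, U, L_X, L_Y, rho).

    ``ridge`` adds ``ridge * I`` to each within-view covariance, useful for
    small-n synthetic runs; the default 0 reproduces plain CCA.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    q = y.shape[1]
    if y.shape[0] != n:
        raise ValidationError("views have different numbers of participants")
    if k > min(p, q):
        raise ValidationError(f"k={k} exceeds min(p, q)={min(p, q)}")
    if n <= p + q:
        warnings.warn(
            f"n={n} <= p+q={p + q}: CCA will overfit; interpret with care",
            stacklevel=2,
        )
    if center:
        x = x - x.mean(axis=0)
        y = y - y.mean(axis=0)
    denom = n - 1
    sxx = x.T @ x / denom + ridge * np.eye(p)
    syy = y.T @ y / denom + ridge * np.eye(q)
    sxy = x.T @ y / denom
    lx = _chol_whitener(sxx, "DN")
    ly = _chol_whitener(syy, "HC")
    kmat = scipy.linalg.solve_triangular(lx, sxy, lower=True)
    kmat = scipy.linalg.solve_triangular(ly, kmat.T, lower=True).T
    a, s, bt = scipy.linalg.svd(kmat, full_matrices=False)
    rho = np.clip(s[:k], 0.0, 1.0)
    v = scipy.linalg.solve_triangular(lx, a[:, :k], lower=True, trans="T")
    u = scipy.linalg.solve_triangular(ly, bt[:k].T, lower=True, trans="T")
    # deterministic sign: largest-|weight| HC entry positive per mode
    flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    v *= flip
    u *= flip
    return v, u, x @ v, y @ u, rho


def fit_cca(dn: VolumeMatrix, hc: VolumeMatrix, k: int = DEFAULT_K, *,
            ridge: float = 0.0) -> CcaSolution:
    """Fit the top-k canonical modes linking DN and HC volume matrices.

    Inputs are expected deconfounded and z-scored; the fit centers each
    column but does not rescale, so the unit-variance convention on the
    variates is exact on the fitting sample.
    """
    if list(dn.values.index) != list(hc.values.index):
        raise ValidationError("DN and HC tables list different participants")
    v, u, lxv, lyv, rho = fit_cca_arrays(
        dn.values.to_numpy(), hc.values.to_numpy(), k, ridge=ridge)
    return CcaSolution(
        v_weights=v, u_weights=u, dn_variates=lxv, hc_variates=lyv,
        canonical_correlations=rho,
        dn_labels=dn.subregions, hc_labels=hc.subregions,
    )


def project(solution: CcaSolution, dn_new: VolumeMatrix, hc_new: VolumeMatrix
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply fitted weights to new (already standardized) data.

    Returns the paired mode-expression matrices ``(X_new V, Y_new U)`` used
    e.g. as predictors in the genetic-association stage.
    """
    for labels, vm, side in ((solution.dn_labels, dn_new, "DN"),
                             (solution.hc_labels, hc_new, "HC")):
        if list(vm.values.columns) != list(labels):
            extra = sorted(set(vm.values.columns) ^ set(labels))
            raise ValidationError(
                f"{side} columns do not match the fitted solution: {extra}")
    return (dn_new.values.to_numpy() @ solution.v_weights,
            hc_new.values.to_numpy() @ solution.u_weights)


def population_canonical_correlations(sxx: np.ndarray, syy: np.ndarray,
                                      sxy: np.ndarray) -> np.ndarray:
    """Closed-form population canonical correlations of a joint covariance.

    Square roots of the eigenvalues of Sxx^{-1} Sxy Syy^{-1} Syx, sorted
    descending.  Used as an oracle against sample estimates.
    """
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    eig = np.linalg.eigvals(m).real
    eig = np.clip(eig, 0.0, 1.0)
    return np.sqrt(np.sort(eig)[::-1])
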