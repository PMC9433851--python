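"""Synthetic cohorts with planted HC-DN co-variation structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage can be tested against a known ground
truth without any data download:

* ``k_true`` latent factors per participant, z_l ~ N(0, s_l^2) with strictly
  decreasing strengths s_l, are mixed into both views through sparse
  unit-norm loading vectors: ``DN = Z A^T + noise``, ``HC = Z B^T + noise``.
  For this linear model plain CCA is consistent and the population canonical
  correlations are available in closed form, which is what makes it a usable
  oracle.
* A binary group label models low vs adequate social support.  For the
  "low support" group, designated loading entries are shifted by ``delta``
  before mixing — a perturbation of the co-variation *pattern*, not of mean
  volumes, because the group contrast operates on canonical vectors.
* Confound columns (age, sex, their interactions, and three scanner-like
  nuisances) are added to every volume column with known linear
  coefficients.
* Genotypes are drawn binomially from per-SNP allele frequencies (no LD).
  When ``prs_mode_coupling`` is nonzero, the designated mode's latent factor
  is constructed as a mixture of the standardized weighted genotype score
  and fresh noise, so the polygenic score correlates with that mode's
  expression by approximately the coupling coefficient.

One global seed drives a splittable RNG with named sub-streams per data
block, so e.g. changing ``n_snps`` does not change the volume tables.
Volumes are unitless: the analysis consumes z-scored residuals, so only
relative scales (factor strengths vs noise_sd) matter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import default_network_atlas, hippocampus_atlas
from .deconfound import ConfoundTable, VolumeMatrix
from .errors import ValidationError

_STREAMS = ("loadings", "factors", "noise", "confounds", "genotypes", "labels")

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort; defaults are the study conditions.

    ``perturbed_entries`` is a list of ``(mode, side, subregion_index)``
    triplets with side in {"dn", "hc"}; the loading entry at each triplet is
    shifted by ``delta`` for low-support participants.
    """

    n_per_group: int = 1000
    p_dn: int = 91
    q_hc: int = 38
    k_true: int = 5
    factor_strengths: tuple[float, ...] = (3.0, 2.5, 2.0, 1.5, 1.0)
    loading_sparsity: float = 0.3
    noise_sd: float = 1.0
    delta: float = 0.0
    perturbed_entries: tuple[tuple[int, str, int], ...] = ()
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    prs_mode_coupling: float = 0.0
    coupled_mode: int = 0
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            "n_per_group": self.n_per_group, "p_dn": self.p_dn,
            "q_hc": self.q_hc, "k_true": self.k_true,
            "loading_sparsity": self.loading_sparsity,
            "noise_sd": self.noise_sd, "delta": self.delta,
            "n_snps": self.n_snps,
            "prs_mode_coupling": self.prs_mode_coupling, "seed": self.seed,
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValidationError(f"CohortSpec.{name} is not finite")
        if not np.all(np.isfinite(self.factor_strengths)):
            raise ValidationError("CohortSpec.factor_strengths is not finite")
        s = np.asarray(self.factor_strengths, dtype=float)
        if len(s) != self.k_true:
            raise ValidationError("factor_strengths length must equal k_true")
        if np.any(s <= 0) or np.any(np.diff(s) >= 0):
            raise ValidationError(
                "factor_strengths must be positive and strictly decreasing")
        if not 0 < self.loading_sparsity <= 1:
            raise ValidationError("loading_sparsity must be in (0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if not 0 <= abs(self.prs_mode_coupling) <= 1:
            raise ValidationError("prs_mode_coupling must be in [-1, 1]")
        if self.prs_mode_coupling and not 0 <= self.coupled_mode < self.k_true:
            raise ValidationError("coupled_mode out of range")
        sizes = {"dn": self.p_dn, "hc": self.q_hc}
        for mode, side, idx in self.perturbed_entries:
            if side not in sizes:
                raise ValidationError(f"perturbed entry side {side!r} unknown")
            if not 0 <= mode < self.k_true:
                raise ValidationError(
                    f"perturbed entry references out-of-range mode {mode}")
            if not 0 <= idx < sizes[side]:
                raise ValidationError(
                    f"perturbed entry references out-of-range subregion {idx} "
                    f"on side {side!r}")
        if self.n_per_group < self.p_dn + self.q_hc:
            warnings.warn(
                f"n_per_group={self.n_per_group} < p_dn+q_hc="
                f"{self.p_dn + self.q_hc}: per-group CCA will overfit",
                stacklevel=2,
            )

    # -- YAML configuration format --------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["factor_strengths"] = list(d["factor_strengths"])
        d["maf_range"] = list(d["maf_range"])
        d["perturbed_entries"] = [list(e) for e in d["perturbed_entries"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["factor_strengths"] = tuple(d["factor_strengths"])
        d["maf_range"] = tuple(d["maf_range"])
        d["perturbed_entries"] = tuple(
            (int(m), str(s), int(i)) for m, s, i in d.get("perturbed_entries", []))
        return cls(**d)


@dataclass
class CohortTruth:
    """Everything planted by the generator, for recovery tests."""

    loadings_dn: np.ndarray        # k x p, unit norm rows
    loadings_hc: np.ndarray        # k x q, unit norm rows
    factor_strengths: np.ndarray
    factors: np.ndarray            # n x k latent factors (scaled)
    confound_contrib_dn: np.ndarray
    confound_contrib_hc: np.ndarray
    perturbed_entries: tuple[tuple[int, str, int], ...]
    delta: float
    prs_true: np.ndarray           # weighted genotype score, all SNPs
    prs_mode_coupling: float
    coupled_mode: int

    def to_json(self, path: str | Path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        d["perturbed_entries"] = [list(e) for e in self.perturbed_entries]
        Path(path).write_text(json.dumps(d))


@dataclass
class SyntheticCohort:
    dn_volumes: VolumeMatrix
    hc_volumes: VolumeMatrix
    confounds: ConfoundTable
    group_labels: pd.Series        # 1 = low social support
    genotypes: pd.DataFrame        # participants x SNPs, dosages {0,1,2}
    snp_effects: pd.DataFrame      # snp_id, alleles, beta, maf, info
    truth: CohortTruth

    @property
    def participant_ids(self) -> list[str]:
        return list(self.dn_volumes.values.index)


def _sparse_unit_loadings(rng: np.random.Generator, k: int, size: int,
                          sparsity: float) -> np.ndarray:
    m = max(1, int(round(sparsity * size)))
    out = np.zeros((k, size))
    for l in range(k):
        support = rng.choice(size, size=m, replace=False)
        vals = rng.normal(size=m)
        out[l, support] = vals / np.linalg.norm(vals)
    return out


def _atlas_slice(atlas: pd.DataFrame, size: int, side: str) -> pd.DataFrame:
    if size == len(atlas):
        return atlas
    # reduced synthetic runs keep a leading slice of the atlas
    if size < len(atlas):
        return atlas.iloc[:size]
    raise ValidationError(
        f"{side} size {size} exceeds the default atlas ({len(atlas)})")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort; deterministic given ``spec.seed``."""
    spec.validate()
    streams = {name: np.random.default_rng(s) for name, s in zip(
        _STREAMS, np.random.SeedSequence(spec.seed).spawn(len(_STREAMS)))}

    n = 2 * spec.n_per_group
    k = spec.k_true
    strengths = np.asarray(spec.factor_strengths, dtype=float)
    ids = [f"sub-{i + 1:06d}" for i in range(n)]

    # group labels: fixed counts, randomized order
    labels = np.zeros(n, dtype=int)
    labels[streams["labels"].permutation(n)[: spec.n_per_group]] = 1
    group_labels = pd.Series(labels, index=pd.Index(ids, name="participant_id"),
                             name="low_support")

    # genotypes and effect sizes (drawn before factors so the PRS can be
    # mixed into a latent factor)
    g_rng = streams["genotypes"]
    maf = g_rng.uniform(*spec.maf_range, size=spec.n_snps)
    beta = g_rng.normal(0.0, 0.1, size=spec.n_snps)
    info = g_rng.uniform(0.85, 1.0, size=spec.n_snps)
    genotypes = g_rng.binomial(2, maf, size=(n, spec.n_snps)).astype(np.int64)
    effect_allele = g_rng.choice(_BASES, size=spec.n_snps)
    other_allele = np.array([
        g_rng.choice([b for b in _BASES
                      if b != a and b != _COMPLEMENT[a]])
        for a in effect_allele])
    snp_ids = [f"rs{i + 1:07d}" for i in range(spec.n_snps)]
    snp_effects = pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "beta": beta,
        "maf": maf,
        "info": info,
    }).set_index("snp_id")
    prs_true = genotypes @ beta

    # latent factors, optionally coupled to the standardized PRS
    z = streams["factors"].normal(size=(n, k))
    if spec.prs_mode_coupling:
        c = spec.prs_mode_coupling
        prs_z = (prs_true - prs_true.mean()) / prs_true.std()
        z[:, spec.coupled_mode] = (
            c * prs_z + np.sqrt(1 - c ** 2) * z[:, spec.coupled_mode])
    z_scaled = z * strengths

    # loadings and group-specific perturbation
    l_rng = streams["loadings"]
    a = _sparse_unit_loadings(l_rng, k, spec.p_dn, spec.loading_sparsity)
    b = _sparse_unit_loadings(l_rng, k, spec.q_hc, spec.loading_sparsity)
    a_low, b_low = a.copy(), b.copy()
    for mode, side, idx in spec.perturbed_entries:
        if side == "dn":
            a_low[mode, idx] += spec.delta
        else:
            b_low[mode, idx] += spec.delta

    e_rng = streams["noise"]
    dn = z_scaled @ a + spec.noise_sd * e_rng.normal(size=(n, spec.p_dn))
    hc = z_scaled @ b + spec.noise_sd * e_rng.normal(size=(n, spec.q_hc))
    low = labels == 1
    if spec.delta != 0 and spec.perturbed_entries:
        dn[low] += z_scaled[low] @ (a_low - a)
        hc[low] += z_scaled[low] @ (b_low - b)

    # confounds with known linear contributions
    c_rng = streams["confounds"]
    age = np.clip(c_rng.normal(55.0, 7.5, size=n), 40.0, 70.0)
    sex = c_rng.integers(0, 2, size=n)
    conf = pd.DataFrame({
        "age": age,
        "sex": sex,
        "age2": age ** 2,
        "sex_age": sex * age,
        "sex_age2": sex * age ** 2,
        "scanner_x": c_rng.normal(size=n),
        "scanner_y": c_rng.normal(size=n),
        "scanner_z": c_rng.normal(size=n),
    }, index=pd.Index(ids, name="participant_id"))
    # contributions built on standardized columns so effect sizes are
    # comparable across confounds; coefficients are stored via the
    # contribution matrices themselves
    c_std = (conf - conf.mean()) / conf.std(ddof=1)
    gamma_dn = c_rng.normal(0.0, 0.5, size=(conf.shape[1], spec.p_dn))
    gamma_hc = c_rng.normal(0.0, 0.5, size=(conf.shape[1], spec.q_hc))
    contrib_dn = c_std.to_numpy() @ gamma_dn
    contrib_hc = c_std.to_numpy() @ gamma_hc
    dn += contrib_dn
    hc += contrib_hc

    dn_meta = _atlas_slice(default_network_atlas(), spec.p_dn, "DN")
    hc_meta = _atlas_slice(hippocampus_atlas(), spec.q_hc, "HC")
    idx = pd.Index(ids, name="participant_id")
    cohort = SyntheticCohort(
        dn_volumes=VolumeMatrix(
            values=pd.DataFrame(dn, index=idx, columns=dn_meta.index),
            meta=dn_meta),
        hc_volumes=VolumeMatrix(
            values=pd.DataFrame(hc, index=idx, columns=hc_meta.index),
            meta=hc_meta),
        confounds=ConfoundTable(values=conf),
        group_labels=group_labels,
        genotypes=pd.DataFrame(genotypes, index=idx, columns=snp_ids),
        snp_effects=snp_effects,
        truth=CohortTruth(
            loadings_dn=a, loadings_hc=b,
            factor_strengths=strengths, factors=z_scaled,
            confound_contrib_dn=contrib_dn, confound_contrib_hc=contrib_hc,
            perturbed_entries=tuple(spec.perturbed_entries),
            delta=spec.delta, prs_true=prs_true,
            prs_mode_coupling=spec.prs_mode_coupling,
            coupled_mode=spec.coupled_mode,
        ),
    )
    return cohort


def population_joint_covariance(spec: CohortSpec
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population (Sxx, Syy, Sxy) implied by a spec's generative model.

    Uses the *expected* loadings (no perturbation, no confounds), i.e. the
    covariance of ``Z A^T + noise`` vs ``Z B^T + noise``.  The loadings are
    redrawn exactly as ``generate_cohort`` draws them, so the result matches
    the cohort generated from the same seed.
    """
    spec.validate()
    streams = dict(zip(_STREAMS, np.random.SeedSequence(spec.seed).spawn(
        len(_STREAMS))))
    l_rng = np.random.default_rng(streams["loadings"])
    a = _sparse_unit_loadings(l_rng, spec.k_true, spec.p_dn,
                              spec.loading_sparsity)
    b = _sparse_unit_loadings(l_rng, spec.k_true, spec.q_hc,
                              spec.loading_sparsity)
    d = np.diag(np.asarray(spec.factor_strengths, dtype=float) ** 2)
    sxx = a.T @ d @ a + spec.noise_sd ** 2 * np.eye(spec.p_dn)
    syy = b.T @ d @ b + spec.noise_sd ** 2 * np.eye(spec.q_hc)
    sxy = a.T @ d @ b
    return sxx, syy, sxy


# -- cohort I/O ----------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write all tables as TSV plus a JSON truth sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.dn_volumes.to_tsv(path / "dn_volumes.tsv")
    cohort.hc_volumes.to_tsv(path / "hc_volumes.tsv")
    cohort.confounds.to_tsv(path / "confounds.tsv")
    cohort.group_labels.to_frame().to_csv(path / "phenotype.tsv", sep="\t")
    cohort.genotypes.to_csv(path / "genotypes.tsv", sep="\t")
    cohort.snp_effects.to_csv(path / "snp_effects.tsv", sep="\t",
                              float_format="%.17g")
    cohort.truth.to_json(path / "truth.json")


def read_cohort(path: str | Path) -> SyntheticCohort:
    path = Path(path)
    truth_raw = json.loads((path / "truth.json").read_text())
    truth = CohortTruth(
        loadings_dn=np.asarray(truth_raw["loadings_dn"]),
        loadings_hc=np.asarray(truth_raw["loadings_hc"]),
        factor_strengths=np.asarray(truth_raw["factor_strengths"]),
        factors=np.asarray(truth_raw["factors"]),
        confound_contrib_dn=np.asarray(truth_raw["confound_contrib_dn"]),
        confound_contrib_hc=np.asarray(truth_raw["confound_contrib_hc"]),
        perturbed_entries=tuple(
            (int(m), str(s), int(i))
            for m, s, i in truth_raw["perturbed_entries"]),
        delta=float(truth_raw["delta"]),
        prs_true=np.asarray(truth_raw["prs_true"]),
        prs_mode_coupling=float(truth_raw["prs_mode_coupling"]),
        coupled_mode=int(truth_raw["coupled_mode"]),
    )
    return SyntheticCohort(
        dn_volumes=VolumeMatrix.from_tsv(path / "dn_volumes.tsv"),
        hc_volumes=VolumeMatrix.from_tsv(path / "hc_volumes.tsv"),
        confounds=ConfoundTable.from_tsv(path / "confounds.tsv"),
        group_labels=pd.read_csv(path / "phenotype.tsv", sep="\t",
                                 index_col="participant_id")["low_support"],
        genotypes=pd.read_csv(path / "genotypes.tsv", sep="\t",
                              index_col="participant_id"),
        snp_effects=pd.read_csv(path / "snp_effects.tsv", sep="\t",
                                index_col="snp_id"),
        truth=truth,
    )
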