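"""Polygenic scoring and Bayesian association with mode expressions.

The polygenic risk score (PRS) for low social support is the weighted sum of
allele dosages, ``prs_j = sum_i g_ij * beta_i``, over SNPs surviving quality
control (minor allele frequency >= 1%, imputation info score >= 0.8, no
duplicate ids, no strand-ambiguous alleles).  Effect sizes are consumed as
given — upstream GWAS and clumping/threshold optimization are out of scope.

Participants in the top and bottom 5% of the score form an extreme-group
binary outcome, which is regressed on the 25 per-participant mode
expressions (canonical variates) in a Bayesian logistic model:

    logit P(y=1) = sum_j x_j beta_mode_j
                   + alpha_men + alpha_women            (sex-specific)
                   + alpha_men_age * age + alpha_women_age * age

with independent N(0, 1) priors on every coefficient and z-scored age.  The
posterior is sampled with emcee's affine-invariant ensemble sampler, run as
three or more independent chains; convergence is checked with split-R-hat
(<= 1.01) and effective sample size (>= 400) per coefficient.  A mode
coefficient is *flagged* as relevant when at least 95% of its posterior mass
lies on one side of zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import NumericalError, ValidationError

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

MAF_MIN = 0.01          # exclude SNPs with minor allele frequency < 1%
INFO_MIN = 0.8          # exclude SNPs with imputation info score < 0.8


@dataclass
class PrsModel:
    """Per-SNP effect sizes with QC metadata.

    ``table`` is indexed by snp_id with columns ``beta``, ``maf``, ``info``
    and optionally ``effect_allele`` / ``other_allele``.  After
    :func:`snp_qc`, ``qc_pass``/``qc_reasons`` columns and per-reason
    ``exclusion_counts`` are populated.
    """

    table: pd.DataFrame
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"beta", "maf", "info"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"PRS model lacks QC columns: {sorted(missing)}")
        if not np.isfinite(self.table["beta"]).all():
            raise ValidationError("effect sizes contain non-finite values")
        if ((self.table["maf"] < 0) | (self.table["maf"] > 0.5)).any():
            raise ValidationError("maf outside [0, 0.5]")
        if ((self.table["info"] < 0) | (self.table["info"] > 1)).any():
            raise ValidationError("info score outside [0, 1]")

    @property
    def passing_snps(self) -> pd.Index:
        if "qc_pass" not in self.table.columns:
            raise ValidationError("run snp_qc before using the model for scoring")
        return self.table.index[self.table["qc_pass"]]


@dataclass
class PrsScores:
    """Per-participant weighted genotype sums."""

    scores: pd.Series  # index participant_id, name "prs"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores).all():
            raise ValidationError("PRS scores contain non-finite values")


def snp_qc(model: PrsModel) -> PrsModel:
    """Flag and exclude SNPs failing the stated quality-control thresholds.

    Thresholds are strict inequalities as printed: a SNP with maf exactly
    0.01 or info exactly 0.8 is retained.  Strand-ambiguous (A/T, C/G) SNPs
    are excluded only when both allele columns are present.
    """
    t = model.table.copy()
    counts = {"maf": 0, "info": 0, "duplicate": 0, "ambiguous": 0}
    low_maf = t["maf"] < MAF_MIN
    low_info = t["info"] < INFO_MIN
    dup = t.index.duplicated(keep=False)
    # positional bookkeeping: reasons must survive duplicated snp ids
    reason_lists: list[list[str]] = [[] for _ in range(len(t))]
    for pos in range(len(t)):
        if low_maf.iloc[pos]:
            reason_lists[pos].append("maf")
        if low_info.iloc[pos]:
            reason_lists[pos].append("info")
        if dup[pos]:
            reason_lists[pos].append("duplicate")
    if {"effect_allele", "other_allele"} <= set(t.columns):
        amb = [frozenset({a, b}) in _AMBIGUOUS
               for a, b in zip(t["effect_allele"], t["other_allele"])]
        counts["ambiguous"] = int(np.sum(amb))
        for pos, is_amb in enumerate(amb):
            if is_amb:
                reason_lists[pos].append("ambiguous")
    counts["maf"] = int(low_maf.sum())
    counts["info"] = int(low_info.sum())
    counts["duplicate"] = int(dup.sum())
    t["qc_pass"] = [not r for r in reason_lists]
    t["qc_reasons"] = [",".join(r) for r in reason_lists]
    return PrsModel(table=t, exclusion_counts=counts)


def compute_prs(genotypes: pd.DataFrame, model: PrsModel) -> PrsScores:
    """prs = sum_i g_i * beta_i over QC-passing SNPs.

    ``genotypes`` holds allele dosages in {0, 1, 2}, one column per SNP.
    """
    snps = model.passing_snps
    missing = snps.difference(genotypes.columns)
    if len(missing):
        raise ValidationError(
            f"genotype table lacks QC-passing SNPs: {list(missing[:5])}...")
    g = genotypes[snps].to_numpy()
    if not np.isin(g, (0, 1, 2)).all():
        bad = np.unique(g[~np.isin(g, (0, 1, 2))])
        raise ValidationError(f"dosages outside {{0,1,2}} found: {bad[:5]}")
    beta = model.table.loc[snps, "beta"].to_numpy()
    prs = pd.Series(g @ beta, index=genotypes.index, name="prs")
    return PrsScores(scores=prs)


def select_extremes(scores: PrsScores, q: float = 0.05) -> pd.Series:
    """Label the top-q fraction 1 and the bottom-q fraction 0.

    Returns a binary outcome series covering only the kept participants;
    the middle of the distribution is excluded from the regression sample.
    Ties are broken by a stable sort on (score, participant_id).
    """
    if not 0 < q < 0.5:
        raise ValidationError(f"extreme fraction q={q} must be in (0, 0.5)")
    s = scores.scores
    if s.nunique() == 1:
        raise ValidationError("all PRS estimates are tied; extremes undefined")
    n_ext = int(np.floor(q * len(s)))
    if n_ext < 1:
        raise ValidationError(
            f"cohort of {len(s)} too small for nonempty {q:.0%} extremes")
    order = s.reset_index().sort_values(
        ["prs", "participant_id"], kind="stable")["participant_id"]
    bottom = order.iloc[:n_ext]
    top = order.iloc[-n_ext:]
    outcome = pd.concat([
        pd.Series(0, index=bottom), pd.Series(1, index=top)])
    outcome.name = "extreme_group"
    outcome.index.name = "participant_id"
    return outcome


# -- Bayesian logistic regression ----------------------------------------

@dataclass
class BayesianModelSpec:
    """Sampler and model settings for the extreme-group regression."""

    n_chains: int = 3
    n_steps: int = 1000         # ensemble steps per chain
    n_burn: int = 400
    thin: int = 4
    n_walkers: int = 64
    seed: int = 0
    standardize_predictors: bool = True
    family: str = "logistic"    # or "linear" (score as continuous outcome)
    flag_level: float = 0.95
    rhat_max: float = 1.01
    ess_min: float = 400.0


@dataclass
class PosteriorSummary:
    """Posterior draws and per-coefficient relevance flags."""

    draws: np.ndarray          # chains x draws x n_coef
    names: list[str]
    summary: pd.DataFrame      # mean, sd, bounds, exclusion_prob, flag, rhat, ess
    converged: bool

    @property
    def exclusion_prob(self) -> pd.Series:
        return self.summary["exclusion_prob"]

    @property
    def flags(self) -> pd.Series:
        """True where >=95% of posterior mass excludes zero."""
        return self.summary["flagged"]


def _design(predictors: pd.DataFrame, sex: np.ndarray, age_z: np.ndarray,
            standardize: bool) -> tuple[np.ndarray, list[str]]:
    x = predictors.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("constant predictor column cannot be z-scored")
        x = (x - x.mean(axis=0)) / sd
    men = (sex == 0).astype(float)
    women = (sex == 1).astype(float)
    design = np.column_stack([x, men, women, men * age_z, women * age_z])
    names = [f"beta_{c}" for c in predictors.columns] + [
        "alpha_men", "alpha_women", "alpha_men_age", "alpha_women_age"]
    return design, names


def _log_posterior_logistic(theta: np.ndarray, design: np.ndarray,
                            y: np.ndarray) -> np.ndarray | float:
    """Bernoulli-logit log-posterior; accepts a single theta or a batch."""
    theta = np.atleast_2d(theta)
    eta = theta @ design.T                      # batch x n
    ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    out = ll - 0.5 * (theta * theta).sum(axis=1)
    return out if out.size > 1 else float(out[0])


def _log_posterior_linear(theta: np.ndarray, design: np.ndarray,
                          y: np.ndarray) -> np.ndarray | float:
    """Gaussian likelihood (unit variance) on a standardized outcome."""
    theta = np.atleast_2d(theta)
    resid = y - theta @ design.T
    out = -0.5 * (resid * resid).sum(axis=1) - 0.5 * (theta * theta).sum(axis=1)
    return out if out.size > 1 else float(out[0])


def fit_bayesian_logistic(predictors: pd.DataFrame, outcome: pd.Series,
                          sex: pd.Series, age: pd.Series,
                          spec: BayesianModelSpec | None = None
                          ) -> PosteriorSummary:
    """Sample the posterior of the extreme-group model.

    ``predictors`` are the per-participant mode expressions (one column per
    mode); ``outcome`` is the binary extreme-group indicator from
    :func:`select_extremes`.  All inputs are aligned on ``outcome``'s index.
    Age is z-scored internally; predictors are z-scored by default.
    """
    import emcee  # deferred: slow import

    spec = spec or BayesianModelSpec()
    ids = outcome.index
    for frame, name in ((predictors, "predictors"), (sex, "sex"), (age, "age")):
        if not ids.isin(frame.index).all():
            raise ValidationError(f"{name} table does not cover the outcome sample")
    x = predictors.loc[ids]
    sex_v = sex.loc[ids].to_numpy()
    if not np.isin(sex_v, (0, 1)).all():
        raise ValidationError("sex must be coded {0, 1}")
    age_v = age.loc[ids].to_numpy(dtype=float)
    age_z = (age_v - age_v.mean()) / age_v.std(ddof=1)
    y = outcome.to_numpy(dtype=float)

    design, names = _design(x, sex_v, age_z, spec.standardize_predictors)
    if spec.family == "logistic":
        log_post = _log_posterior_logistic
    elif spec.family == "linear":
        y = (y - y.mean()) / y.std(ddof=1)
        log_post = _log_posterior_linear
    else:
        raise ValidationError(f"unknown family {spec.family!r}")

    dim = design.shape[1]
    n_walkers = max(spec.n_walkers, 2 * dim + 2)

    # MAP start (convex for both families) shared by all chains
    res = scipy.optimize.minimize(
        lambda t: -log_post(t, design, y), np.zeros(dim), method="L-BFGS-B")
    if not res.success:
        raise NumericalError(f"MAP optimization failed: {res.message}")

    # Laplace covariance at the MAP: walkers start correctly dispersed, so
    # the ensemble does not need long burn-in to reach the posterior spread
    if spec.family == "logistic":
        prob = 1.0 / (1.0 + np.exp(-(design @ res.x)))
        hess = design.T @ (design * (prob * (1 - prob))[:, None]) + np.eye(dim)
    else:
        hess = design.T @ design + np.eye(dim)
    chol_h = scipy.linalg.cholesky(hess, lower=False)  # H = R^T R

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    kept = (spec.n_steps - spec.n_burn) // spec.thin
    chains = np.empty((spec.n_chains, kept * n_walkers, dim))
    for c, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        p0 = res.x + scipy.linalg.solve_triangular(
            chol_h, rng.normal(size=(dim, n_walkers))).T
        # differential-evolution moves mix much faster than the default
        # stretch move on this correlated ~30-dimensional posterior
        sampler = emcee.EnsembleSampler(
            n_walkers, dim, log_post, args=(design, y), vectorize=True,
            moves=emcee.moves.DEMove())
        sampler.random_state = np.random.RandomState(
            int(seq.generate_state(1)[0]) % (2 ** 32 - 1)).get_state()
        sampler.run_mcmc(p0, spec.n_steps, progress=False)
        chains[c] = sampler.get_chain(
            discard=spec.n_burn, thin=spec.thin, flat=True)

    return _summarize(chains, names, spec)


def _summarize(chains: np.ndarray, names: list[str],
               spec: BayesianModelSpec) -> PosteriorSummary:
    import arviz as az

    idata = az.from_dict(posterior={"theta": chains})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)["theta"].to_numpy()
        ess = az.ess(idata)["theta"].to_numpy()
    flat = chains.reshape(-1, chains.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    p_pos = (flat > 0).mean(axis=0)
    exclusion = np.maximum(p_pos, 1 - p_pos)
    flagged = exclusion >= spec.flag_level
    converged = bool(np.all(rhat <= spec.rhat_max) and np.all(ess >= spec.ess_min))
    if not converged:
        warnings.warn(
            "MCMC convergence diagnostics failed (rhat/ess); treat this "
            "posterior summary as unreliable", stacklevel=2)
    summary = pd.DataFrame({
        "mean": mean, "sd": sd, "ci_2.5%": lo, "ci_97.5%": hi,
        "exclusion_prob": exclusion, "flagged": flagged,
        "rhat": rhat, "ess": ess,
    }, index=pd.Index(names, name="coefficient"))
    return PosteriorSummary(draws=chains, names=names, summary=summary,
                            converged=converged)
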