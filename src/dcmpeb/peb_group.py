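"""Group-level inference: parametric empirical Bayes, Bayesian model
reduction, model averaging and Bayesian contrasts.

The second level places a linear model over subjects' first-level
posterior parameter estimates,

    theta_i = (x_i kron I) beta + eps_i,   eps_i ~ N(0, Sigma_b),

with design row ``x_i`` holding an intercept (group commonalities) and
mean-centered covariates (sex, performance, age).  Given the
between-subject precision, the model is linear-Gaussian and the
posterior over ``beta`` and the model evidence are exact; the single
between-subject log-precision hyperparameter is optimized numerically.

Bayesian model reduction (BMR) scores any model that differs from the
full one only by shrunk prior variances, in closed form, without
refitting; a greedy search prunes group parameters that do not
contribute to the free energy and the surviving uncertain parameters
(at most eight) are evaluated exhaustively — 256 models when exactly
eight remain in play — and averaged into a Bayesian model average (BMA)
weighted by posterior model probability.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg as sla, optimize, special, stats

from .variational_inversion import PosteriorEstimate, PriorSpec

__all__ = [
    "PEBDesign",
    "PEBResult",
    "BMAResult",
    "make_peb_design",
    "fit_peb",
    "bmr_evidence",
    "greedy_search",
    "posterior_probability",
    "bayesian_contrast",
    "bayes_factor_null",
]

#: prior variance used to represent a switched-off parameter in BMR
OFF_VARIANCE = 1e-8


@dataclass
class PEBDesign:
    """Between-subject design matrix and the first-level parameter block.

    The first column of ``X`` must be a constant 1 (commonalities);
    remaining columns are mean-centered covariates.  ``parameter_indices``
    selects which first-level parameters (by index into the subject
    posterior vector) enter the second level.
    """

    X: np.ndarray
    covariate_names: tuple
    parameter_indices: np.ndarray
    parameter_labels: tuple = ()

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the constant 1")
        if self.X.shape[1] > 1:
            means = self.X[:, 1:].mean(axis=0)
            if np.any(np.abs(means) > 1e-6):
                raise ValueError("covariate columns must be mean-centered")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.parameter_indices = np.asarray(self.parameter_indices, dtype=int)


def make_peb_design(behavior: "pd.DataFrame", param_map, matrix: str = "B",
                    include_sex: bool = True, include_performance: bool = True,
                    include_age: bool = False) -> PEBDesign:
    """Design from a behavioral summary table (one row per subject).

    Sex is coded female +0.5 / male -0.5 and, like the performance
    (NoGo accuracy) and age columns, mean-centered so the intercept is
    the group mean.  The parameter block selects all entries of one
    first-level matrix ("A", "B" or "C").
    """
    cols = [np.ones(len(behavior))]
    names = ["mean"]
    if include_sex:
        sex = np.where(behavior["sex"].to_numpy() == "F", 0.5, -0.5)
        cols.append(sex - sex.mean())
        names.append("sex")
    if include_performance:
        acc = behavior["nogo_accuracy"].to_numpy(dtype=float)
        cols.append(acc - acc.mean())
        names.append("nogo_accuracy")
    if include_age:
        age = behavior["age"].to_numpy(dtype=float)
        cols.append(age - age.mean())
        names.append("age")
    idx = np.array([k for k, a in enumerate(param_map.addresses)
                    if a[0] == matrix])
    labels = tuple(param_map.addresses[k] for k in idx)
    return PEBDesign(np.column_stack(cols), tuple(names), idx, labels)


@dataclass
class PEBResult:
    """Posterior over group-level effects, one row block per covariate."""

    beta_mean: np.ndarray       # (n_cov, p)
    beta_cov: np.ndarray        # (n_cov*p, n_cov*p), covariate-major
    prior_mean: np.ndarray      # (n_cov*p,)
    prior_variance: np.ndarray  # (n_cov*p,)
    free_energy: float
    gamma: float                # between-subject log precision scale
    between_variance: np.ndarray  # diag of Sigma_b (p,)
    design: PEBDesign
    covariate_names: tuple
    parameter_labels: tuple

    @property
    def n_cov(self) -> int:
        return self.beta_mean.shape[0]

    @property
    def n_params(self) -> int:
        return self.beta_mean.shape[1]

    def effect_z(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.beta_cov)).reshape(self.beta_mean.shape)
        return self.beta_mean / sd

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        sd = np.sqrt(np.diag(self.beta_cov)).reshape(self.beta_mean.shape)
        rows = []
        for c, cov in enumerate(self.covariate_names):
            for j, lab in enumerate(self.parameter_labels):
                rows.append({"covariate": cov, "parameter": str(lab),
                             "estimate": self.beta_mean[c, j],
                             "sd": sd[c, j]})
        return pd.DataFrame(rows)


def _subject_blocks(posteriors: list[PosteriorEstimate], idx: np.ndarray):
    means, covs = [], []
    for post in posteriors:
        means.append(post.mean[idx])
        covs.append(post.cov[np.ix_(idx, idx)])
    return np.asarray(means), np.asarray(covs)


def fit_peb(posteriors: list[PosteriorEstimate], design: PEBDesign,
            beta_prior_variance: np.ndarray | None = None,
            gamma_prior_variance: float = 1.0 / 16.0,
            between_scale: float = 16.0) -> PEBResult:
    """Estimate group effects from first-level posteriors.

    The between-subject covariance is ``exp(-gamma) * V`` with
    ``V = (first-level prior variance) / between_scale``; ``gamma`` has a
    N(0, gamma_prior_variance) hyperprior and is optimized by maximizing
    the (exact, given gamma) log evidence.  The beta prior is zero-mean
    with, by default, the first-level prior variance replicated per
    covariate.
    """
    if len(posteriors) < 2:
        raise ValueError("PEB needs at least two subjects")
    idx = design.parameter_indices
    m, S = _subject_blocks(posteriors, idx)
    n, p = m.shape
    X = design.X
    if X.shape[0] != n:
        raise ValueError("design rows must match number of subjects")
    n_cov = X.shape[1]

    prior = posteriors[0].prior
    if prior is not None:
        v_first = prior.variance[idx]
    else:
        v_first = np.full(p, 1.0 / 16.0)
    if np.any(v_first <= 0):
        raise ValueError("selected parameters include switched-off entries")
    V = v_first / between_scale
    if beta_prior_variance is None:
        beta_prior_variance = np.tile(v_first, n_cov)
    beta_prior_variance = np.asarray(beta_prior_variance, dtype=float)
    P0b = 1.0 / beta_prior_variance

    def evidence(gamma: float):
        Sb = np.exp(-gamma) * V
        Pi = np.linalg.inv(S + np.diag(Sb)[None])        # (n, p, p)
        # beta precision: sum_i (x_i x_i') kron P_i  (covariate-major)
        Lam = (np.einsum("ia,ib,ijk->ajbk", X, X, Pi)
               .reshape(n_cov * p, n_cov * p)) + np.diag(P0b)
        b = np.einsum("ia,ijk,ik->aj", X, Pi, m).reshape(n_cov * p)
        cF = sla.cho_factor(Lam)
        mu = sla.cho_solve(cF, b)
        logdetLam = 2.0 * np.sum(np.log(np.diag(cF[0])))
        sgn, logdetD = np.linalg.slogdet(S + np.diag(Sb)[None])
        quad = np.einsum("ijk,ij,ik->", Pi, m, m) - b @ mu
        F = (-0.5 * n * p * np.log(2 * np.pi)
             - 0.5 * (np.sum(logdetD) + np.sum(np.log(beta_prior_variance))
                      + logdetLam)
             - 0.5 * quad
             - 0.5 * gamma ** 2 / gamma_prior_variance)
        return F, mu, Lam, cF, Sb

    res = optimize.minimize_scalar(lambda g: -evidence(g)[0],
                                   bounds=(-8.0, 8.0), method="bounded",
                                   options={"xatol": 1e-4})
    gamma = float(res.x)
    F, mu, Lam, cF, Sb = evidence(gamma)
    beta_cov = sla.cho_solve(cF, np.eye(n_cov * p))
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    return PEBResult(
        beta_mean=mu.reshape(n_cov, p),
        beta_cov=beta_cov,
        prior_mean=np.zeros(n_cov * p),
        prior_variance=beta_prior_variance,
        free_energy=float(F),
        gamma=gamma,
        between_variance=Sb,
        design=design,
        covariate_names=design.covariate_names,
        parameter_labels=design.parameter_labels,
    )


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def bmr_evidence(prior_mean, prior_cov, post_mean, post_cov,
                 reduced_prior_mean, reduced_prior_cov):
    """Change in log evidence and the posterior implied by a reduced prior.

    Closed-form Gaussian identity: with full prior (mu0, S0), full
    posterior (mu, S) and reduced prior (mu0r, S0r) differing only in
    (shrunk) variances, the reduced posterior has precision
    P_r = P + P0r - P0 and the evidence changes by

        dF = 0.5 [ ln|P0| - ln|P0r| + ln|P_r^-1 stuff| ... ]

    evaluated below in precision form.  No refitting is involved.
    """
    mu0 = np.asarray(prior_mean, float)
    mu = np.asarray(post_mean, float)
    S0 = np.atleast_2d(prior_cov)
    S = np.atleast_2d(post_cov)
    mu0r = np.asarray(reduced_prior_mean, float)
    S0r = np.atleast_2d(reduced_prior_cov)

    P0 = np.linalg.inv(S0)
    P = np.linalg.inv(S)
    P0r = np.linalg.inv(S0r)
    Pr = P + P0r - P0
    Sr = np.linalg.inv(Pr)
    Sr = 0.5 * (Sr + Sr.T)
    h = P @ mu + P0r @ mu0r - P0 @ mu0
    mur = Sr @ h

    def logdet(Mat):
        s, v = np.linalg.slogdet(Mat)
        if s <= 0:
            raise np.linalg.LinAlgError("non-PD matrix in BMR")
        return v

    dF = 0.5 * (logdet(P) + logdet(P0r) - logdet(Pr) - logdet(P0)) \
        + 0.5 * (mur @ Pr @ mur + mu0 @ (P0 @ mu0)
                 - mu @ (P @ mu) - mu0r @ (P0r @ mu0r))
    return float(dF), mur, Sr


def _reduced_prior(prior_variance, off_mask):
    v = np.asarray(prior_variance, float).copy()
    v[off_mask] = OFF_VARIANCE
    return v


@dataclass
class BMAResult:
    """Bayesian model average over the final exhaustive model set."""

    model_masks: np.ndarray        # (n_models, k) on/off over in-play params
    model_free_energies: np.ndarray
    model_probabilities: np.ndarray
    in_play: np.ndarray            # indices (into beta vector) searched
    pruned: np.ndarray             # indices switched off during greedy sweeps
    mean: np.ndarray               # BMA posterior mean over beta
    cov: np.ndarray
    pp: np.ndarray                 # per-beta posterior probability of presence
    prior_mean: np.ndarray
    prior_variance: np.ndarray
    covariate_names: tuple
    parameter_labels: tuple
    threshold: float = 0.95

    @property
    def n_models(self) -> int:
        return self.model_masks.shape[0]

    def strong_evidence(self) -> np.ndarray:
        return self.pp > self.threshold

    def marginal(self, index: int) -> tuple[float, float]:
        return float(self.mean[index]), float(self.cov[index, index])

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        n_cov = len(self.covariate_names)
        p = len(self.parameter_labels)
        sd = np.sqrt(np.diag(self.cov))
        rows = []
        for c in range(n_cov):
            for j in range(p):
                k = c * p + j
                rows.append({
                    "covariate": self.covariate_names[c],
                    "parameter": str(self.parameter_labels[j]),
                    "estimate": self.mean[k], "sd": sd[k],
                    "pp": self.pp[k],
                    "strong_evidence": bool(self.pp[k] > self.threshold),
                })
        return pd.DataFrame(rows)


def greedy_search(peb: PEBResult, candidates: np.ndarray | None = None,
                  max_in_play: int = 8, max_sweeps: int = 32) -> BMAResult:
    """Prune group parameters that do not contribute to free energy.

    Sweeps switch off (via BMR) every parameter whose removal does not
    decrease the free energy, re-scoring against the progressively
    reduced model.  The surviving parameters with the least decisive
    contributions — at most ``max_in_play`` — are then evaluated
    exhaustively over all on/off combinations (2**8 = 256 models when
    eight remain in play) and averaged, weighted by the softmax of model
    free energies.
    """
    nb = peb.beta_mean.size
    mu = peb.beta_mean.reshape(nb)
    S = peb.beta_cov
    mu0 = peb.prior_mean
    v0 = peb.prior_variance
    if candidates is None:
        candidates = np.arange(nb)
    candidates = np.asarray(candidates, dtype=int)

    off = np.zeros(nb, dtype=bool)
    for _ in range(max_sweeps):
        active = [j for j in candidates if not off[j]]
        if not active:
            break
        base_v = _reduced_prior(v0, off)
        dFs = {}
        for j in active:
            vj = base_v.copy()
            vj[j] = OFF_VARIANCE
            dF, _, _ = bmr_evidence(mu0, np.diag(v0), mu, S, mu0, np.diag(vj))
            dF0, _, _ = bmr_evidence(mu0, np.diag(v0), mu, S, mu0,
                                     np.diag(base_v))
            dFs[j] = dF - dF0
        prune = [j for j, d in dFs.items() if d >= 0]
        if not prune:
            break
        for j in prune:
            off[j] = True

    survivors = np.array([j for j in candidates if not off[j]], dtype=int)
    base_v = _reduced_prior(v0, off)
    if survivors.size > max_in_play:
        # keep the least decisive parameters in play; the rest stay on
        order = np.argsort([abs(dFs[j]) for j in survivors])
        in_play = survivors[order[:max_in_play]]
    else:
        in_play = survivors
    in_play = np.sort(in_play)

    k = in_play.size
    masks = np.array(list(itertools.product([1, 0], repeat=k)), dtype=int)
    Fs = np.empty(len(masks))
    reduced = []
    for i, mask in enumerate(masks):
        vi = base_v.copy()
        vi[in_play[mask == 0]] = OFF_VARIANCE
        dF, mur, Sr = bmr_evidence(mu0, np.diag(v0), mu, S, mu0, np.diag(vi))
        Fs[i] = dF
        reduced.append((mur, Sr))
    probs = special.softmax(Fs)

    mean = np.zeros(nb)
    cov = np.zeros((nb, nb))
    for w, (mur, Sr) in zip(probs, reduced):
        mean += w * mur
        cov += w * (Sr + np.outer(mur, mur))
    cov -= np.outer(mean, mean)
    cov = 0.5 * (cov + cov.T)

    pp = np.ones(nb)
    pp[off] = 0.0
    for pos, j in enumerate(in_play):
        pp[j] = float(np.sum(probs[masks[:, pos] == 1]))
    return BMAResult(
        model_masks=masks, model_free_energies=Fs,
        model_probabilities=probs, in_play=in_play,
        pruned=np.flatnonzero(off), mean=mean, cov=cov, pp=pp,
        prior_mean=mu0, prior_variance=v0,
        covariate_names=peb.covariate_names,
        parameter_labels=peb.parameter_labels)


def posterior_probability(bma: BMAResult, index) -> float:
    """Summed probability of the models in which a parameter is present.

    ``index`` is either a flat beta index or a (covariate, parameter
    label) pair matching the BMA's bookkeeping.
    """
    if not np.isscalar(index):
        cov, lab = index
        c = bma.covariate_names.index(cov)
        j = [str(x) for x in bma.parameter_labels].index(str(lab))
        index = c * len(bma.parameter_labels) + j
    return float(bma.pp[int(index)])


def bayesian_contrast(bma: BMAResult, weights: np.ndarray) -> dict:
    """Gaussian posterior of a linear contrast of BMA parameters.

    Returns the contrast mean, variance, and the posterior probability
    that the contrast is positive (and negative).  A zero contrast or a
    zero-variance contrast is flagged as degenerate.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != bma.mean.shape:
        raise ValueError("contrast weight dimension mismatch")
    if np.all(w == 0):
        raise ValueError("degenerate contrast: all weights zero")
    mean = float(w @ bma.mean)
    var = float(w @ bma.cov @ w)
    if var <= 0:
        raise ValueError("degenerate contrast: zero posterior variance")
    sd = np.sqrt(var)
    return {
        "mean": mean,
        "variance": var,
        "pp_positive": float(stats.norm.sf(0.0, loc=mean, scale=sd)),
        "pp_negative": float(stats.norm.cdf(0.0, loc=mean, scale=sd)),
    }


def bayes_factor_null(bma: BMAResult, index) -> float:
    """Savage-Dickey Bayes factor against the point null (parameter = 0):
    prior density at zero over posterior density at zero."""
    if not np.isscalar(index):
        cov, lab = index
        c = bma.covariate_names.index(cov)
        j = [str(x) for x in bma.parameter_labels].index(str(lab))
        index = c * len(bma.parameter_labels) + j
    index = int(index)
    v0 = bma.prior_variance[index]
    if v0 <= 0:
        raise ValueError("parameter has zero prior density everywhere")
    prior0 = stats.norm.pdf(0.0, loc=bma.prior_mean[index], scale=np.sqrt(v0))
    m, v = bma.marginal(index)
    post0 = stats.norm.pdf(0.0, loc=m, scale=np.sqrt(v))
    if post0 == 0:
        return np.inf
    return float(prior0 / post0)


def save_peb_tables(bma: BMAResult, directory: str | Path,
                    stem: str = "peb") -> None:
    """Per-connection estimates, Pp and threshold flags as TSV + JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = bma.to_frame()
    df.to_csv(directory / f"{stem}_bma.tsv", sep="\t", index=False)
    summary = {
        "n_models": int(bma.n_models),
        "n_in_play": int(bma.in_play.size),
        "n_pruned": int(bma.pruned.size),
        "threshold": bma.threshold,
        "strong_evidence": df.loc[df.strong_evidence, "parameter"].tolist(),
    }
    (directory / f"{stem}_summary.json").write_text(json.dumps(summary, indent=1))
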