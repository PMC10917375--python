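"""Variational-Laplace inversion of the generative model.

The estimation scheme maximizes the Laplace free energy

    F = accuracy - complexity
      = E_q[ln p(y | theta, lambda)] - KL[q(theta) || p(theta)] - KL-terms(lambda)

under a fixed-form Gaussian posterior q(theta) = N(m, S).  Parameters
are updated by damped Gauss-Newton steps using finite-difference
sensitivities of the forward model (obtained in a single batched
integration per iteration); observation-noise log-precisions — one iid
component per region — are updated by Newton fixed-point steps.  A step
is accepted only if it increases F, so the accepted free-energy trace
is non-decreasing by construction; Levenberg-style damping is halved on
acceptance and doubled on rejection.

The engine (:func:`variational_laplace`) is generic over any batched
forward map and is also used directly on linear problems, where the
free-energy expression is the exact log model evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _integrate
from .model_core import (
    DCMParameters,
    ExperimentDesign,
    RegionTimeSeries,
    _hemo_arrays,
)

__all__ = [
    "ParameterMap",
    "PriorSpec",
    "PosteriorEstimate",
    "variational_laplace",
    "invert_dcm",
    "explained_variance",
    "apply_inclusion_rule",
    "save_posterior",
    "load_posterior",
]

LN2PI = np.log(2.0 * np.pi)


class ParameterMap:
    """Mapping between a flat parameter vector and DCM structures.

    Addresses are tuples: ("A", i, j), ("B", k, i, j), ("C", i, k),
    ("hemo_decay", i) or ("hemo_transit", i).  The hemodynamic entries
    are log deviations: kappa_i = kappa0 exp(d), tau_i = tau0 exp(d).
    """

    def __init__(self, addresses: list[tuple]):
        self.addresses = [tuple(a) for a in addresses]
        self.index = {a: k for k, a in enumerate(self.addresses)}

    def __len__(self) -> int:
        return len(self.addresses)

    @classmethod
    def full(cls, n_nodes: int = 4, n_modulatory: int = 2,
             n_driving: int = 2, include_hemo: bool = True) -> "ParameterMap":
        addr: list[tuple] = []
        addr += [("A", i, j) for i in range(n_nodes) for j in range(n_nodes)
                 if i != j]
        addr += [("A", i, i) for i in range(n_nodes)]
        addr += [("B", k, i, j) for k in range(n_modulatory)
                 for i in range(n_nodes) for j in range(n_nodes)]
        addr += [("C", i, k) for i in range(n_nodes) for k in range(n_driving)]
        if include_hemo:
            addr += [("hemo_decay", i) for i in range(n_nodes)]
            addr += [("hemo_transit", i) for i in range(n_nodes)]
        return cls(addr)

    def pack(self, params: DCMParameters) -> np.ndarray:
        theta = np.zeros(len(self))
        for k, a in enumerate(self.addresses):
            if a[0] == "A":
                theta[k] = params.A[a[1], a[2]]
            elif a[0] == "B":
                theta[k] = params.B[a[1], a[2], a[3]]
            elif a[0] == "C":
                theta[k] = params.C[a[1], a[2]]
            # hemo deviations pack as zero by convention
        return theta

    def build_batch(self, template: DCMParameters, theta: np.ndarray):
        """Expand (K, p) parameter rows into batched A/B/C/hemo arrays."""
        theta = np.atleast_2d(theta)
        K = theta.shape[0]
        A = np.repeat(template.A[None], K, axis=0)
        B = np.repeat(template.B[None], K, axis=0)
        C = np.repeat(template.C[None], K, axis=0)
        hemo = {k: np.repeat(v[None], K, axis=0)
                for k, v in _hemo_arrays(template.hemo).items()}
        for k, a in enumerate(self.addresses):
            if a[0] == "A":
                A[:, a[1], a[2]] = theta[:, k]
            elif a[0] == "B":
                B[:, a[1], a[2], a[3]] = theta[:, k]
            elif a[0] == "C":
                C[:, a[1], a[2]] = theta[:, k]
            elif a[0] == "hemo_decay":
                hemo["kappa"][:, a[1]] = (
                    np.asarray(template.hemo.kappa)[a[1]] * np.exp(theta[:, k]))
            elif a[0] == "hemo_transit":
                hemo["tau"][:, a[1]] = (
                    np.asarray(template.hemo.tau)[a[1]] * np.exp(theta[:, k]))
            else:
                raise ValueError(f"unknown address {a!r}")
        return A, B, C, hemo

    def unpack(self, template: DCMParameters, theta: np.ndarray) -> DCMParameters:
        A, B, C, hemo = self.build_batch(template, theta[None])
        from .model_core import HemodynamicParameters
        h0 = template.hemo
        h = HemodynamicParameters(
            kappa=hemo["kappa"][0], gamma=hemo["gamma"][0], tau=hemo["tau"][0],
            alpha=hemo["alpha"][0], E0=hemo["E0"][0], V0=hemo["V0"][0],
            TE=h0.TE, nu0=h0.nu0, r0=h0.r0, epsilon=h0.epsilon)
        return DCMParameters(A=A[0], B=B[0], C=C[0], hemo=h,
                             node_labels=template.node_labels)


@dataclass
class PriorSpec:
    """Gaussian priors over the flat parameter vector.

    A zero prior variance switches a parameter off: it stays at its
    prior mean with zero posterior variance.  ``noise_*`` entries are the
    hyperprior on per-region observation-noise log-precisions.
    """

    param_map: ParameterMap
    mean: np.ndarray
    variance: np.ndarray
    noise_log_precision_mean: float = 4.0
    noise_log_precision_variance: float = 16.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != (len(self.param_map),) or \
                self.variance.shape != (len(self.param_map),):
            raise ValueError("prior mean/variance must match the parameter map")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be non-negative")

    @classmethod
    def default(cls, n_nodes: int = 4, n_modulatory: int = 2,
                n_driving: int = 2, include_hemo: bool = True,
                **kwargs) -> "PriorSpec":
        """Canonical shrinkage priors: N(0, 1/16) on coupling (A off-diagonal,
        B, C), N(0, 1/256) on self-connection log-scalings and hemodynamic
        log deviations."""
        pm = ParameterMap.full(n_nodes, n_modulatory, n_driving, include_hemo)
        var = np.empty(len(pm))
        for k, a in enumerate(pm.addresses):
            if a[0] == "A" and a[1] == a[2]:
                var[k] = 1.0 / 256.0
            elif a[0] in ("hemo_decay", "hemo_transit"):
                var[k] = 1.0 / 256.0
            else:
                var[k] = 1.0 / 16.0
        return cls(pm, np.zeros(len(pm)), var, **kwargs)

    def switched_off(self, addresses: list[tuple]) -> "PriorSpec":
        """Copy of the priors with the given parameters switched off."""
        var = self.variance.copy()
        for a in addresses:
            var[self.param_map.index[tuple(a)]] = 0.0
        return PriorSpec(self.param_map, self.mean.copy(), var,
                         self.noise_log_precision_mean,
                         self.noise_log_precision_variance)


@dataclass
class PosteriorEstimate:
    """Gaussian posterior over the flat parameter vector after inversion."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    f_trace: np.ndarray
    converged: bool
    noise_log_precisions: np.ndarray
    explained_variance: float | None = None
    param_map: ParameterMap | None = None
    prior: PriorSpec | None = None
    diagnostics: dict = field(default_factory=dict)


def variational_laplace(forward, y, prior_mean, prior_variance, noise_group,
                        hyper_mean=4.0, hyper_variance=16.0,
                        max_iter=128, tol=1e-4, n_converged=4,
                        fd_scale=1e-3, max_rejects=16, init_damping=0.25,
                        stall_tol=0.5):
    """Gaussian fixed-form variational inference for y = g(theta) + noise.

    ``forward`` maps a (K, p) batch of parameter rows to (K, N)
    predictions (rows of NaN flag unstable evaluations).  ``noise_group``
    assigns each of the N data points to one iid noise component whose
    log precision carries the hyperprior N(hyper_mean, hyper_variance).
    Returns (m, S, F, trace, lambda, converged, diagnostics) over the
    *free* parameters (prior variance > 0); fixed parameters never move.
    """
    y = np.asarray(y, dtype=float).ravel()
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_variance = np.asarray(prior_variance, dtype=float)
    noise_group = np.asarray(noise_group)
    groups = np.unique(noise_group)
    n_g = np.array([(noise_group == g).sum() for g in groups], dtype=float)
    N = y.size

    free = prior_variance > 0
    pf = int(free.sum())
    mu0 = prior_mean[free]
    P0 = 1.0 / prior_variance[free]          # diagonal precision
    logdetP0 = float(np.sum(np.log(P0)))
    h_fd = fd_scale * np.sqrt(prior_variance[free])

    def expand(mf):
        full = prior_mean.copy()
        full[free] = mf
        return full

    def eval_forward(mf_rows):
        rows = np.stack([expand(m) for m in np.atleast_2d(mf_rows)])
        return forward(rows)

    def residual_terms(r, lam):
        w = np.exp(lam)[np.searchsorted(groups, noise_group)]
        return w, np.array([np.sum(r[noise_group == g] ** 2) for g in groups])

    def update_lambda(lam, G_tot):
        lam = lam.copy()
        for _ in range(8):
            e = np.exp(lam)
            grad = 0.5 * (n_g - e * G_tot) - (lam - hyper_mean) / hyper_variance
            hess = -0.5 * e * G_tot - 1.0 / hyper_variance
            step = grad / -hess
            step = np.clip(step, -4.0, 4.0)
            lam = lam + step
            if np.max(np.abs(step)) < 1e-8:
                break
        s_lam = 1.0 / (0.5 * np.exp(lam) * G_tot + 1.0 / hyper_variance)
        return lam, s_lam

    def free_energy(r, lam, s_lam, logdetS, mf):
        w = np.exp(lam)[np.searchsorted(groups, noise_group)]
        acc = -0.5 * np.sum(w * r ** 2) + 0.5 * np.sum(n_g * lam) - 0.5 * N * LN2PI
        e = mf - mu0
        comp = -0.5 * np.sum(P0 * e ** 2) + 0.5 * logdetP0 + 0.5 * logdetS
        hyp = (-0.5 * np.sum((lam - hyper_mean) ** 2) / hyper_variance
               - 0.5 * len(groups) * np.log(hyper_variance)
               + 0.5 * np.sum(np.log(s_lam)))
        return float(acc + comp + hyp)

    # --- initialization ----------------------------------------------------
    m = mu0.copy()
    g0 = eval_forward(m)[0]
    if not np.all(np.isfinite(g0)):
        raise FloatingPointError("forward model unstable at the prior mean")
    r = y - g0
    lam = np.full(len(groups), float(hyper_mean))
    _, G = residual_terms(r, lam)
    lam, s_lam = update_lambda(lam, G)

    damping = init_damping
    J = None
    S = np.diag(1.0 / P0) if pf else np.zeros((0, 0))
    logdetS = float(-np.sum(np.log(P0))) if pf else 0.0
    F = free_energy(r, lam, s_lam, logdetS, m)
    trace = [F]
    converged = False
    n_small = 0
    status = "max_iter"

    for it in range(max_iter):
        # batched finite-difference Jacobian at the current mean
        batch = np.repeat(m[None], pf + 1, axis=0)
        batch[1:] += np.diag(h_fd)
        preds = eval_forward(batch)
        g0 = preds[0]
        if not np.all(np.isfinite(g0)):
            status = "unstable_mean"
            break
        J = (preds[1:] - g0[None]) / h_fd[:, None]
        J = np.where(np.isfinite(J), J, 0.0).T      # (N, pf)
        r = y - g0
        w = np.exp(lam)[np.searchsorted(groups, noise_group)]
        Jw = J * w[:, None]
        H = J.T @ Jw + np.diag(P0)
        b = Jw.T @ r - P0 * (m - mu0)
        # reference free energy under the current linearization: the
        # Laplace F depends on the point of linearization, so candidate
        # steps are judged against a reference computed with the same J
        sign, logdetH = np.linalg.slogdet(H)
        F_ref = free_energy(r, lam, s_lam, -logdetH, m)

        accepted = False
        F_new = np.nan
        for _ in range(max_rejects):
            Hd = H + damping * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(Hd, b)
            except np.linalg.LinAlgError:
                damping *= 2.0
                continue
            m_new = m + step
            g_new = eval_forward(m_new)[0]
            if not np.all(np.isfinite(g_new)):
                damping *= 2.0
                continue
            r_new = y - g_new
            # refresh noise precisions given the candidate residuals
            S_try = np.linalg.inv(H)
            diagJSJ = np.einsum("ij,jk,ik->i", J, S_try, J)
            G_tot = np.array([np.sum(r_new[noise_group == g] ** 2)
                              + np.sum(diagJSJ[noise_group == g])
                              for g in groups])
            lam_new, s_lam_new = update_lambda(lam, G_tot)
            w_new = np.exp(lam_new)[np.searchsorted(groups, noise_group)]
            H_new = J.T @ (J * w_new[:, None]) + np.diag(P0)
            sign, logdetH = np.linalg.slogdet(H_new)
            if sign <= 0:
                damping *= 2.0
                continue
            F_new = free_energy(r_new, lam_new, s_lam_new, -logdetH, m_new)
            # a precision update that lowers F is discarded (the Newton
            # fixed point optimizes a surrogate, not F itself)
            sign0, logdetH0 = np.linalg.slogdet(H)
            F_keep = free_energy(r_new, lam, s_lam, -logdetH0, m_new)
            if F_keep > F_new:
                F_new = F_keep
                lam_new, s_lam_new = lam, s_lam
            if F_new > F_ref:
                m, lam, s_lam = m_new, lam_new, s_lam_new
                dF = F_new - F_ref
                F = F_new
                if F_new > trace[-1]:
                    trace.append(F_new)
                damping = max(damping / 2.0, 1e-4)
                accepted = True
                n_small = n_small + 1 if dF < tol else 0
                break
            damping *= 2.0
        if not accepted:
            # no uphill step even against the current linearization:
            # converged if the shortfall is a numerical sliver, else a
            # genuine optimization failure
            converged = (np.isfinite(F_new)
                         and abs(F_new - F_ref) < stall_tol)
            status = "converged" if converged else "no_ascent"
            break
        if n_small >= n_converged:
            converged = True
            status = "converged"
            break

    # final posterior covariance at the accepted mean
    if J is not None:
        w = np.exp(lam)[np.searchsorted(groups, noise_group)]
        H = J.T @ (J * w[:, None]) + np.diag(P0)
        S = np.linalg.inv(H)
        S = 0.5 * (S + S.T)
    diagnostics = {"status": status, "n_iter": len(trace) - 1,
                   "damping": damping}
    return m, S, F, np.array(trace), lam, converged, diagnostics


def _run_mean_filter(values: np.ndarray, run_starts, n_volumes_total: int):
    """Remove per-run means (run-intercept confounds) from (..., V, n) data."""
    out = values.copy()
    bounds = list(run_starts) + [n_volumes_total]
    for a, b in zip(bounds[:-1], bounds[1:]):
        out[..., a:b, :] -= out[..., a:b, :].mean(axis=-2, keepdims=True)
    return out


def invert_dcm(data: RegionTimeSeries, design: ExperimentDesign,
               priors: PriorSpec | None = None,
               template: DCMParameters | None = None,
               **engine_kwargs) -> PosteriorEstimate:
    """Fit the full model to one subject's region time series.

    Per-run mean (baseline) confounds are removed from data and
    predictions alike; the two runs are otherwise handled by the design
    itself (independent integration from rest).  The returned posterior
    covers the flat parameter vector of ``priors.param_map``; switched
    off parameters (zero prior variance) stay at their prior mean.
    """
    if priors is None:
        priors = PriorSpec.default(n_nodes=data.n_nodes)
    if template is None:
        template = DCMParameters.zeros(
            data.n_nodes,
            n_modulatory=len(design.modulatory_input_ids),
            n_driving=len(design.driving_input_ids),
            node_labels=data.node_labels)
    pm = priors.param_map
    n = data.n_nodes
    nvol = data.n_volumes
    y = _run_mean_filter(data.values, data.run_starts, nvol).ravel()
    noise_group = np.tile(np.arange(n), nvol)

    def forward(theta_rows):
        A, B, C, hemo = pm.build_batch(template, theta_rows)
        pred, _ = _integrate.integrate_batch(A, B, C, hemo, design,
                                             nan_on_instability=True)
        pred = _run_mean_filter(pred, data.run_starts, nvol)
        return pred.reshape(theta_rows.shape[0], -1)

    m, S, F, trace, lam, conv, diag = variational_laplace(
        forward, y, priors.mean, priors.variance, noise_group,
        hyper_mean=priors.noise_log_precision_mean,
        hyper_variance=priors.noise_log_precision_variance,
        **engine_kwargs)

    p = len(pm)
    free = priors.variance > 0
    mean = priors.mean.copy()
    mean[free] = m
    cov = np.zeros((p, p))
    cov[np.ix_(free, free)] = S
    post = PosteriorEstimate(
        mean=mean, cov=cov, free_energy=F, f_trace=trace, converged=conv,
        noise_log_precisions=lam, param_map=pm, prior=priors,
        diagnostics=diag)
    post.explained_variance = explained_variance(post, data, design,
                                                 template=template)
    return post


def explained_variance(post: PosteriorEstimate, data: RegionTimeSeries,
                       design: ExperimentDesign,
                       template: DCMParameters | None = None) -> float:
    """Percent variance of the (confound-adjusted) data captured by the
    posterior-mean prediction, pooled over regions and volumes."""
    if template is None:
        template = DCMParameters.zeros(
            data.n_nodes,
            n_modulatory=len(design.modulatory_input_ids),
            n_driving=len(design.driving_input_ids),
            node_labels=data.node_labels)
    pm = post.param_map
    A, B, C, hemo = pm.build_batch(template, post.mean[None])
    pred, _ = _integrate.integrate_batch(A, B, C, hemo, design)
    yf = _run_mean_filter(data.values, data.run_starts, data.n_volumes)
    gf = _run_mean_filter(pred[0], data.run_starts, data.n_volumes)
    ss_tot = np.sum((yf - yf.mean()) ** 2)
    if ss_tot <= 0:
        raise ValueError("data has zero variance after confound adjustment")
    ss_res = np.sum((yf - gf) ** 2)
    return float(100.0 * (1.0 - ss_res / ss_tot))


@dataclass
class InclusionReport:
    """Partition of a cohort by the explained-variance inclusion rule."""

    included: list[int]
    excluded: list[int]
    threshold: float
    bias_tests: dict


def apply_inclusion_rule(explained: np.ndarray, threshold: float = 10.0,
                         behavior: "pd.DataFrame | None" = None) -> InclusionReport:
    """Partition subjects at the explained-variance threshold (percent).

    If a behavioral summary table (one row per subject, aligned with
    ``explained``) is supplied, included and excluded groups are
    compared on each numeric measure with Welch t-tests — a check that
    the rule does not select on behavior.
    """
    from scipy import stats

    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100) percent")
    ev = np.asarray(explained, dtype=float)
    included = np.flatnonzero(ev >= threshold)
    excluded = np.flatnonzero(ev < threshold)
    if included.size == 0:
        raise ValueError("inclusion rule excluded every subject")
    bias = {}
    if behavior is not None and excluded.size > 0:
        num = behavior.select_dtypes("number")
        for col in num.columns:
            a = num[col].to_numpy()[included]
            b = num[col].to_numpy()[excluded]
            t, p = stats.ttest_ind(a, b, equal_var=False)
            bias[col] = {"t": float(t), "p": float(p)}
    return InclusionReport(included.tolist(), excluded.tolist(),
                           threshold, bias)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_posterior(post: PosteriorEstimate, path: str | Path) -> None:
    """Posterior to HDF5 plus a JSON summary next to it."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5["mean"] = post.mean
        h5["cov"] = post.cov
        h5["f_trace"] = post.f_trace
        h5["noise_log_precisions"] = post.noise_log_precisions
        h5.attrs["free_energy"] = post.free_energy
        h5.attrs["converged"] = post.converged
        h5.attrs["explained_variance"] = (
            np.nan if post.explained_variance is None else post.explained_variance)
        if post.param_map is not None:
            h5.attrs["addresses"] = json.dumps(post.param_map.addresses)
        if post.prior is not None:
            h5["prior_mean"] = post.prior.mean
            h5["prior_variance"] = post.prior.variance
    summary = {
        "free_energy": post.free_energy,
        "explained_variance": post.explained_variance,
        "converged": bool(post.converged),
        "n_iter": post.diagnostics.get("n_iter"),
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=1))


def load_posterior(path: str | Path) -> PosteriorEstimate:
    import h5py

    with h5py.File(path, "r") as h5:
        pm = None
        prior = None
        if "addresses" in h5.attrs:
            pm = ParameterMap([tuple(a) for a in json.loads(h5.attrs["addresses"])])
        if "prior_mean" in h5 and pm is not None:
            prior = PriorSpec(pm, h5["prior_mean"][...], h5["prior_variance"][...])
        ev = float(h5.attrs["explained_variance"])
        return PosteriorEstimate(
            mean=h5["mean"][...], cov=h5["cov"][...],
            free_energy=float(h5.attrs["free_energy"]),
            f_trace=h5["f_trace"][...],
            converged=bool(h5.attrs["converged"]),
            noise_log_precisions=h5["noise_log_precisions"][...],
            explained_variance=None if np.isnan(ev) else ev,
            param_map=pm, prior=prior)
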