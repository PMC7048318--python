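"""Hierarchical Bayesian estimation of choice-model parameters by SVI.

Model (on the unconstrained scale, d free parameters per subject):

    mu_i    ~ Normal(m_i, s_i)          group means
    sigma_i ~ Half-Cauchy(0, 1)         group scales
    x^n_i   ~ Normal(mu_i, lam*sigma_i) subject parameters
    choices ~ logistic g2-choice model given x^n

The hyper-parameters eta = (m, s, lam) are optimised alongside the
posterior (empirical Bayes). The approximate posterior factorises between
hierarchy levels and subjects:

    Q(mu, sigma) = multivariate normal over z = (mu, ln sigma)
                   (a multivariate log-normal over sigma, carrying the
                   1/(sigma_1...sigma_d) change-of-variables factor)
    Q(x^n)       = multivariate normal per subject.

The evidence lower bound (negative variational free energy) is maximised
by stochastic gradient ascent (Adam) with reparameterised Monte-Carlo
gradients. All gradients are analytic: the logistic likelihood is
closed-form in (beta, theta), and the sensitivity of the planning signal
DEV to (gamma, kappa) is propagated through the backward-induction
recursion itself (envelope theorem at the argmax), with the dynamic
program re-run exactly, batched over all (subject, sample) pairs, at every
step. The state space is small enough that this exact recomputation is
cheaper than any interpolation scheme and introduces no approximation
error. When gamma and kappa are both fixed by the model variant the value
tables are computed once and the likelihood reduces to a plain logistic
regression per subject.

Model variants fix subsets of (beta, theta, gamma, kappa) and may
partition trials (by miniblock segment, condition, or experiment third)
with separate parameters per partition cell; variants are compared by
their ELBO averaged over the final optimisation steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, ndtr

from .task import TaskConfig
from .planner import values_batched
from .contexts import extract_contexts
from .choice import PARAM_NAMES

logger = logging.getLogger(__name__)

LN2PI = np.log(2 * np.pi)
#: default fixed values for parameters a variant does not estimate
DEFAULT_FIXED = {"beta": 1.0, "theta": 0.0, "gamma": 1.0, "kappa": 1.0}

PARTITIONS = ("none", "by-segment", "by-condition", "by-block")


@dataclass(frozen=True)
class ModelVariant:
    """Which parameters are free, what the rest are fixed to, and whether
    trials are partitioned into cells with separate parameters."""

    free_params: tuple[str, ...] = PARAM_NAMES
    fixed_values: dict = field(default_factory=dict)
    partition: str = "none"

    def __post_init__(self):
        free = tuple(p for p in PARAM_NAMES if p in self.free_params)
        if set(self.free_params) - set(PARAM_NAMES):
            raise ValueError(f"unknown parameters {set(self.free_params) - set(PARAM_NAMES)}")
        if not free:
            raise ValueError("at least one parameter must be free")
        object.__setattr__(self, "free_params", free)
        fixed = dict(DEFAULT_FIXED)
        fixed.update(self.fixed_values)
        object.__setattr__(self, "fixed_values",
                           {k: fixed[k] for k in PARAM_NAMES if k not in free})
        if self.partition not in PARTITIONS:
            raise ValueError(f"partition must be one of {PARTITIONS}")

    @property
    def name(self) -> str:
        prefix = {"none": "", "by-segment": "s_", "by-condition": "c_",
                  "by-block": "b_"}[self.partition]
        return prefix + "".join(p[0] for p in self.free_params)

    @property
    def gamma_kappa_fixed(self) -> bool:
        return "gamma" not in self.free_params and "kappa" not in self.free_params


@dataclass
class SVISettings:
    """Optimisation configuration (Adam-class stochastic gradients)."""

    lr: float = 5e-3
    steps: int = 10_000
    mc_samples: int = 10
    convergence_window: int = 500
    convergence_tol: float = 1e-4
    elbo_avg_window: int = 20
    init_scale: float = 0.1


def _part_index(records: pd.DataFrame, partition: str) -> tuple[np.ndarray, list[str]]:
    """Partition-cell index per record row plus cell labels."""
    if partition == "none":
        return np.zeros(len(records), dtype=np.intp), [""]
    if partition == "by-segment":
        t = records["trial"].to_numpy()
        idx = np.minimum((t - 1) // 5, 2)
        return idx.astype(np.intp), ["seg1-5", "seg6-10", "seg11-15"]
    if partition == "by-condition":
        labels = sorted(records["condition"].unique())
        lookup = {c: i for i, c in enumerate(labels)}
        return records["condition"].map(lookup).to_numpy(dtype=np.intp), list(labels)
    # by-block: experiment thirds by block rank
    blocks = np.sort(records["block"].unique())
    third = {b: min(2, 3 * i // len(blocks)) for i, b in enumerate(blocks)}
    return records["block"].map(third).to_numpy(dtype=np.intp), \
        ["blocks1", "blocks2", "blocks3"]


class LikelihoodData:
    """Flattened classifiable-trial contexts for a cohort, ready for
    batched DEV gathering and gradient scatter."""

    def __init__(self, records: pd.DataFrame, variant: ModelVariant,
                 config: TaskConfig = TaskConfig()):
        if len(records) == 0:
            raise ValueError("records must be non-empty")
        self.config = config
        self.variant = variant
        self.subjects = list(pd.unique(records["participant"]))
        sub_lookup = {p: i for i, p in enumerate(self.subjects)}
        ctx = extract_contexts(records, config)
        if ctx.basic_wait.any():
            logger.warning("dropping %d impossible basic-offer waits",
                           int(ctx.basic_wait.sum()))
        part_all, self.part_labels = _part_index(records, variant.partition)
        sel = ctx.defined
        self.subj = records["participant"].map(sub_lookup).to_numpy(dtype=np.intp)[sel]
        self.part = part_all[sel]
        self.trial = ctx.trial[sel]
        self.ia_g2, self.ib_g2 = ctx.ia_g2[sel], ctx.ib_g2[sel]
        self.ia_g1, self.ib_g1 = ctx.ia_g1[sel], ctx.ib_g1[sel]
        self.sign = np.where(ctx.y_g2[sel], 1.0, -1.0)
        self.y = ctx.y_g2[sel].astype(float)
        self.n_subjects = len(self.subjects)
        self.n_parts = len(self.part_labels)
        self.n_free = len(variant.free_params)
        self.d = self.n_free * self.n_parts
        self.param_labels = [
            p if variant.partition == "none" else f"{p}[{cell}]"
            for cell in self.part_labels for p in variant.free_params]

    # ---- mapping unconstrained coordinates to natural parameters -------
    def naturals(self, X: np.ndarray):
        """Map unconstrained X of shape (..., d) to natural-scale arrays
        beta, theta, gamma, kappa of shape (..., n_parts), together with
        the transform derivatives for gamma and kappa."""
        shape = X.shape[:-1] + (self.n_parts, self.n_free)
        Xp = X.reshape(shape)
        free = self.variant.free_params
        fixed = self.variant.fixed_values
        out = {}
        dgam = dkap = None
        for name in PARAM_NAMES:
            if name in free:
                col = Xp[..., free.index(name)]
                if name == "beta":
                    out[name] = np.exp(np.clip(col, -30.0, 30.0))
                elif name == "theta":
                    out[name] = col
                elif name == "gamma":
                    g = expit(col)
                    out[name] = np.clip(g, 1e-9, 1.0)
                    dgam = g * (1 - g)
                else:
                    k = 2 * expit(col)
                    out[name] = np.clip(k, 1e-9, 2.0)
                    dkap = out[name] * (2 - out[name]) / 2.0
            else:
                out[name] = np.broadcast_to(
                    np.asarray(fixed[name], dtype=float), shape[:-1])
        return out["beta"], out["theta"], out["gamma"], out["kappa"], dgam, dkap

    def loglik_and_grad(self, X: np.ndarray, want_grad: bool = True,
                        V_cache: dict | None = None):
        """Per-subject log-likelihood and its gradient w.r.t. X.

        ``X`` has shape (S, N, d). Returns ``ll`` of shape (S, N) and
        ``grad`` of shape (S, N, d) (or None).
        """
        S, N, d = X.shape
        P = self.n_parts
        beta, theta, gamma, kappa, dgam, dkap = self.naturals(X)
        free = self.variant.free_params
        need_dp = not self.variant.gamma_kappa_fixed
        M = len(self.trial)
        if need_dp:
            gv = np.broadcast_to(gamma, (S, N, P)).reshape(-1)
            kv = np.broadcast_to(kappa, (S, N, P)).reshape(-1)
            V, dVg, dVk = values_batched(gv, kv, self.config, derivatives=True)
            bidx = ((np.arange(S)[:, None] * N + self.subj[None, :]) * P
                    + self.part[None, :])                       # (S, M)
            tr = self.trial[None, :]
            v2 = V[bidx, tr, self.ia_g2, self.ib_g2]
            v1 = V[bidx, tr, self.ia_g1, self.ib_g1]
            vdiff = v2 - v1
            g_m = np.broadcast_to(gamma, (S, N, P))[:, self.subj, self.part]
            dev = g_m * vdiff
            if want_grad:
                dg2 = dVg[bidx, tr, self.ia_g2, self.ib_g2]
                dg1 = dVg[bidx, tr, self.ia_g1, self.ib_g1]
                dk2 = dVk[bidx, tr, self.ia_g2, self.ib_g2]
                dk1 = dVk[bidx, tr, self.ia_g1, self.ib_g1]
                ddev_dgam = vdiff + g_m * (dg2 - dg1)
                ddev_dkap = g_m * (dk2 - dk1)
        else:
            if V_cache is None or "dev" not in V_cache:
                gk = (float(np.ravel(gamma)[0]), float(np.ravel(kappa)[0]))
                V = values_batched([gk[0]], [gk[1]], self.config)[0]
                dev0 = gk[0] * (V[self.trial, self.ia_g2, self.ib_g2]
                                - V[self.trial, self.ia_g1, self.ib_g1])
                if V_cache is not None:
                    V_cache["dev"] = dev0
            else:
                dev0 = V_cache["dev"]
            dev = np.broadcast_to(dev0, (S, M))

        b_m = np.broadcast_to(beta, (S, N, P))[:, self.subj, self.part]
        t_m = np.broadcast_to(theta, (S, N, P))[:, self.subj, self.part]
        logit_g2 = b_m * dev + t_m
        ll_m = log_expit(self.sign * logit_g2)                  # (S, M)
        ll = np.stack([np.bincount(self.subj, weights=ll_m[s], minlength=N)
                       for s in range(S)])
        if not want_grad:
            return ll, None
        resid = self.y - expit(logit_g2)                        # (S, M)
        grad = np.zeros((S, N, d))
        flat_param = self.part * self.n_free
        for j, name in enumerate(free):
            if name == "beta":
                gm = resid * dev * b_m
            elif name == "theta":
                gm = resid
            elif name == "gamma":
                dgam_m = np.broadcast_to(dgam, (S, N, P))[:, self.subj, self.part]
                gm = resid * b_m * ddev_dgam * dgam_m
            else:
                dkap_m = np.broadcast_to(dkap, (S, N, P))[:, self.subj, self.part]
                gm = resid * b_m * ddev_dkap * dkap_m
            cols = flat_param + j                                # (M,)
            for s in range(S):
                np.add.at(grad[s], (self.subj, cols), gm[s])
        return ll, grad


def log_joint(records: pd.DataFrame, latents: dict, hyper: dict,
              variant: ModelVariant = ModelVariant(),
              config: TaskConfig = TaskConfig()) -> float:
    """Log-density of the hierarchical model at explicit latent values.

    ``latents`` holds ``x`` (N, d), ``mu`` (d,), ``sigma`` (d,);
    ``hyper`` holds ``m`` (d,), ``s`` (d,), ``lam`` (scalar). The density
    is over (mu, sigma, x) with sigma on its natural (positive) scale.
    """
    ld = LikelihoodData(records, variant, config)
    x = np.asarray(latents["x"], dtype=float)
    mu = np.asarray(latents["mu"], dtype=float)
    sigma = np.asarray(latents["sigma"], dtype=float)
    m = np.asarray(hyper["m"], dtype=float)
    s = np.asarray(hyper["s"], dtype=float)
    lam = float(hyper["lam"])
    if x.shape != (ld.n_subjects, ld.d) or mu.shape != (ld.d,) or sigma.shape != (ld.d,):
        raise ValueError("latent dimensions do not match the variant")
    lp = float(np.sum(-0.5 * ((mu - m) / s) ** 2 - np.log(s) - 0.5 * LN2PI))
    lp += float(np.sum(np.log(2 / np.pi) - np.log1p(sigma ** 2)))
    scale = lam * sigma
    lp += float(np.sum(-0.5 * ((x - mu) / scale) ** 2 - np.log(scale) - 0.5 * LN2PI))
    ll, _ = ld.loglik_and_grad(x[None], want_grad=False)
    return lp + float(ll.sum())


@dataclass
class PosteriorApprox:
    """Fitted variational posterior plus the optimisation trace."""

    variant: ModelVariant
    subjects: list
    param_labels: list
    group_mean: np.ndarray        # (2d,) location of Q(mu, ln sigma)
    group_cov: np.ndarray         # (2d, 2d)
    subject_means: np.ndarray     # (N, d)
    subject_covs: np.ndarray      # (N, d, d)
    elbo_trace: np.ndarray
    hyper: dict
    converged: bool

    @property
    def d(self) -> int:
        return self.subject_means.shape[1]

    def final_elbo(self, window: int = 20) -> float:
        return float(np.mean(self.elbo_trace[-window:]))

    def group_natural_medians(self) -> dict:
        """Posterior-median natural parameters implied by the group-mean
        location (monotone transforms map medians exactly)."""
        from .choice import inverse_transform
        out = {}
        free = self.variant.free_params
        for p_idx, label in enumerate(self.param_labels):
            name = label.split("[")[0]
            x = np.zeros(4)
            for j, nm in enumerate(PARAM_NAMES):
                if nm == name:
                    x[j] = self.group_mean[p_idx]
            nat = inverse_transform(x)
            out[label] = getattr(nat, name)
        return out

    def subject_summary(self) -> pd.DataFrame:
        """Per-subject posterior summaries: unconstrained mean and sd plus
        natural-scale 5/50/95 percentiles (monotone-transform quantiles)."""
        from scipy.special import ndtri
        rows = []
        zq = ndtri([0.05, 0.5, 0.95])
        transforms = {"beta": np.exp, "theta": lambda v: v,
                      "gamma": expit, "kappa": lambda v: 2 * expit(v)}
        for i, pid in enumerate(self.subjects):
            sd = np.sqrt(np.diag(self.subject_covs[i]))
            for j, label in enumerate(self.param_labels):
                name = label.split("[")[0]
                q = transforms[name](self.subject_means[i, j] + zq * sd[j])
                rows.append({"participant": pid, "param": label,
                             "mean_u": self.subject_means[i, j], "sd_u": sd[j],
                             "q05": q[0], "q50": q[1], "q95": q[2]})
        return pd.DataFrame(rows)


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict, grads: dict):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] += self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps)


def _tril_from_raw(W: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor from raw parameters (diagonal
    stored on log scale)."""
    L = np.tril(W, k=-1)
    idx = np.arange(W.shape[-1])
    if W.ndim == 2:
        L[idx, idx] = np.exp(W[idx, idx])
    else:
        L[:, idx, idx] = np.exp(W[:, idx, idx])
    return L


def fit_svi(records: pd.DataFrame, variant: ModelVariant = ModelVariant(),
            settings: SVISettings = SVISettings(), seed: int = 0,
            config: TaskConfig = TaskConfig()) -> PosteriorApprox:
    """Maximise the ELBO of the hierarchical model by stochastic gradient
    ascent with reparameterised Monte-Carlo gradients and empirical-Bayes
    hyper-parameter updates. Deterministic for fixed (data, seed, settings)."""
    ld = LikelihoodData(records, variant, config)
    N, d = ld.n_subjects, ld.d
    rng = np.random.default_rng(seed)
    sc = settings.init_scale
    params = {
        "mu_g": np.zeros(2 * d),
        "W_g": np.diag(np.full(2 * d, np.log(sc))),
        "mu_x": np.zeros((N, d)),
        "W_x": np.tile(np.diag(np.full(d, np.log(sc))), (N, 1, 1)),
        "m": np.zeros(d),
        "rho": np.zeros(d),     # ln s
        "ell": np.zeros(1),     # ln lam
    }
    opt = _Adam(params, settings.lr)
    S = settings.mc_samples
    V_cache: dict = {}
    elbo_trace = np.empty(settings.steps)
    idx2 = np.arange(2 * d)
    idx1 = np.arange(d)
    converged = False
    n_steps = settings.steps
    for step in range(settings.steps):
        L_g = _tril_from_raw(params["W_g"])
        L_x = _tril_from_raw(params["W_x"])
        m, s, lam = params["m"], np.exp(params["rho"]), float(np.exp(params["ell"][0]))
        eps_g = rng.standard_normal((S, 2 * d))
        eps_x = rng.standard_normal((S, N, d))
        z = params["mu_g"] + eps_g @ L_g.T                   # (S, 2d)
        mu = z[:, :d]
        zeta = z[:, d:]
        sigma = np.exp(np.clip(zeta, -20, 20))
        x = params["mu_x"] + np.einsum("nij,snj->sni", L_x, eps_x)  # (S,N,d)

        scale = lam * sigma                                   # (S, d)
        ll, g_lik = ld.loglik_and_grad(x, V_cache=V_cache)
        diff = x - mu[:, None, :]
        z_sc = diff / scale[:, None, :]
        lp = (np.sum(-0.5 * ((mu - m) / s) ** 2 - np.log(s) - 0.5 * LN2PI, axis=1)
              + np.sum(np.log(2 / np.pi) - np.log1p(sigma ** 2) + zeta, axis=1)
              + np.sum(-0.5 * z_sc ** 2 - np.log(scale)[:, None, :] - 0.5 * LN2PI,
                       axis=(1, 2))
              + ll.sum(axis=1))                               # (S,)
        H_g = d * (1 + LN2PI) + np.sum(np.diag(params["W_g"]))
        H_x = N * d / 2 * (1 + LN2PI) + np.sum(
            params["W_x"][:, idx1, idx1])
        elbo = float(lp.mean()) + H_g + H_x
        if not np.isfinite(elbo):
            raise RuntimeError(
                f"non-finite ELBO at step {step}: lp={lp}, "
                f"hyper=(m={m}, s={s}, lam={lam})")
        elbo_trace[step] = elbo

        # gradients of log p w.r.t. the latents
        g_mu = -(mu - m) / s ** 2 + np.sum(z_sc / scale[:, None, :], axis=1)
        g_zeta = (1 - 2 * sigma ** 2 / (1 + sigma ** 2)
                  + np.sum(z_sc ** 2 - 1, axis=1))
        g_z = np.concatenate([g_mu, g_zeta], axis=1)          # (S, 2d)
        g_x = -z_sc / scale[:, None, :] + g_lik               # (S, N, d)

        grads = {}
        grads["mu_g"] = g_z.mean(axis=0)
        GL = np.tril(np.einsum("si,sj->ij", g_z, eps_g) / S)
        GW = GL.copy()
        GW[idx2, idx2] = GL[idx2, idx2] * np.diag(L_g) + 1.0  # + entropy
        grads["W_g"] = GW
        grads["mu_x"] = g_x.mean(axis=0)
        GLx = np.tril(np.einsum("sni,snj->nij", g_x, eps_x) / S)
        GWx = GLx.copy()
        GWx[:, idx1, idx1] = GLx[:, idx1, idx1] * L_x[:, idx1, idx1] + 1.0
        grads["W_x"] = GWx
        grads["m"] = np.mean((mu - m) / s ** 2, axis=0)
        grads["rho"] = np.mean(((mu - m) / s) ** 2 - 1, axis=0)
        grads["ell"] = np.array([np.mean(np.sum(z_sc ** 2 - 1, axis=(1, 2)))])
        opt.step(params, grads)

        w = settings.convergence_window
        if step >= 2 * w and (step + 1) % w == 0:
            prev = elbo_trace[step + 1 - 2 * w:step + 1 - w].mean()
            curr = elbo_trace[step + 1 - w:step + 1].mean()
            if abs(curr - prev) / (abs(prev) + 1e-8) < settings.convergence_tol:
                converged = True
                n_steps = step + 1
                break
    if not converged and settings.steps >= 2 * settings.convergence_window:
        logger.warning("SVI stopped at the step cap without meeting the "
                       "convergence criterion (final ELBO %.2f)",
                       elbo_trace[n_steps - 1])
    L_g = _tril_from_raw(params["W_g"])
    L_x = _tril_from_raw(params["W_x"])
    return PosteriorApprox(
        variant=variant, subjects=ld.subjects, param_labels=ld.param_labels,
        group_mean=params["mu_g"].copy(), group_cov=L_g @ L_g.T,
        subject_means=params["mu_x"].copy(),
        subject_covs=np.einsum("nij,nkj->nik", L_x, L_x),
        elbo_trace=elbo_trace[:n_steps].copy(),
        hyper={"m": params["m"].copy(), "s": np.exp(params["rho"]),
               "lam": float(np.exp(params["ell"][0]))},
        converged=converged)


def compare_variants(records: pd.DataFrame, variants: list[ModelVariant],
                     settings: SVISettings = SVISettings(), seed: int = 0,
                     config: TaskConfig = TaskConfig()) -> pd.DataFrame:
    """Fit each variant under identical settings and rank by the ELBO
    averaged over the final optimisation steps. Individual fit failures
    are recorded as NaN and do not abort the comparison."""
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    rows = []
    fits = {}
    for variant in variants:
        try:
            post = fit_svi(records, variant, settings, seed=seed, config=config)
            elbo = post.final_elbo(settings.elbo_avg_window)
            fits[variant.name] = post
        except Exception as exc:   # noqa: BLE001 - comparison proceeds
            logger.warning("fit of variant %s failed: %s", variant.name, exc)
            elbo = np.nan
        rows.append({"variant": variant.name,
                     "free_params": ",".join(variant.free_params),
                     "partition": variant.partition, "elbo": elbo})
    table = pd.DataFrame(rows).sort_values("elbo", ascending=False,
                                           na_position="last")
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["fits"] = fits
    return table.reset_index(drop=True)


def recovery_report(truth: dict, posterior: PosteriorApprox) -> pd.DataFrame:
    """Parameter-recovery diagnostics against known ground truth.

    ``truth`` maps participant id to natural-scale parameters
    (SubjectParams or dict). Reports, per free parameter on the
    unconstrained scale: bias, RMSE, 90%-interval coverage, and the
    probability-integral-transform values whose histogram should be
    uniform for a calibrated posterior. Parameters whose group bias
    exceeds twice its standard error are flagged.
    """
    from .choice import SubjectParams, transform_params
    if posterior.variant.partition != "none":
        raise ValueError("recovery_report expects an unpartitioned variant")
    missing = set(posterior.subjects) - set(truth)
    if missing:
        raise ValueError(f"truth missing subjects: {sorted(missing)[:5]}")
    free = posterior.variant.free_params
    cols = [PARAM_NAMES.index(p) for p in free]
    truth_x = np.array([
        transform_params(t if isinstance(t := truth[pid], SubjectParams)
                         else SubjectParams(**t))[cols]
        for pid in posterior.subjects])
    means = posterior.subject_means
    sds = np.sqrt(np.array([np.diag(c) for c in posterior.subject_covs]))
    err = means - truth_x
    lo = means - 1.6448536269514722 * sds
    hi = means + 1.6448536269514722 * sds
    rows = []
    for j, name in enumerate(free):
        bias = err[:, j].mean()
        sem = err[:, j].std(ddof=1) / np.sqrt(len(err))
        pit = ndtr((truth_x[:, j] - means[:, j]) / sds[:, j])
        rows.append({
            "param": name, "bias": bias, "rmse": float(np.sqrt(np.mean(err[:, j] ** 2))),
            "coverage90": float(np.mean((truth_x[:, j] >= lo[:, j])
                                        & (truth_x[:, j] <= hi[:, j]))),
            "biased_flag": bool(abs(bias) > 2 * sem),
            "pit": pit,
        })
    return pd.DataFrame(rows)
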